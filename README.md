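# tiledc

Analysis of **Tiled-C / targeted chromosome-conformation-capture** contact
matrices over a single tiled genomic region, built for studies that follow
how a locus folds across cell states — for example a large developmental
gene such as *Runx1*, whose ~2.5 Mb regulatory landscape at 2 kb resolution
contains a ~1.1 Mb TAD with cell-type-specific sub-TADs, CTCF-anchored
boundaries, and dynamic enhancer–promoter (E-P) contacts across an
ESC → mesoderm → hematopoietic-progenitor differentiation course.

The package covers the full quantitative path from sparse binned count
matrices to statistics:

* **Matrix processing** — triplet I/O, replicate merging, ICE (iterative
  correction) balancing to equal bin marginals, scaling of all samples to
  their mean total interactions, subtraction maps, percentile capping for
  display, and rotated-triangle rendering.
* **Virtual Capture-C** — one-dimensional viewpoint profiles
  (per-million-cis normalized), replicate mean ± SD tracks, difference
  tracks, bedGraph export.
* **Domain statistics** — the intra-TAD interaction ratio (per-bin
  insulation score), boundary contacts between the *k* outermost CTCF
  bins at each TAD end, and E-P contact quantification over
  de-duplicated enhancer bins.
* **Statistics** — median-of-ratios size factors, log-normalized-count
  PCA of replicates, a Shapiro–Wilk normality gate, tie-corrected
  Kruskal–Wallis, Dunn's post hoc z tests, and Holm / Benjamini–Hochberg
  adjustment.
* **Synthetic data** — a generative contact-map model (power-law distance
  decay × domain boosts × Gaussian loop anchors, multinomial sequencing
  depth) with a preset that emulates the *Runx1* locus geometry, including
  boundary-weakened "CTCF-KO" variants, so every analysis is exercisable
  with no external data.

## The statistics in brief

A contact map is modeled on a fixed 2 kb bin grid. Balancing solves for
per-bin biases *b<sub>i</sub>* such that the corrected matrix
*x<sub>ij</sub> / (b<sub>i</sub>b<sub>j</sub>)* has equal row marginals
(ICE). The insulation score of a bin *b* inside a domain *D* is

&nbsp;&nbsp;&nbsp;&nbsp;ratio(b) = Σ<sub>j∈D, j≠b</sub> x<sub>bj</sub> / Σ<sub>j∉D</sub> x<sub>bj</sub>,

and the per-bin ratios across replicates form the per-state distributions
compared with the Kruskal–Wallis test,

&nbsp;&nbsp;&nbsp;&nbsp;H = [12/(N(N+1)) Σ n<sub>i</sub>(r̄<sub>i</sub> − (N+1)/2)²] / [1 − ΣT/(N³−N)],

followed by Dunn's pairwise z statistics on the pooled ranks with Holm or
Benjamini–Hochberg correction.

## Worked example

Simulate the three-state preset, balance and scale each replicate, and ask
whether the P1–P2 sub-TAD strengthens over differentiation:

```python
import numpy as np
from tiledc import (runx1_like_config, expected_matrix, sample_counts,
                    ice_balance, scale_to_mean_total, intra_tad_ratio, dunn_test)
from tiledc.simulate import replicate_seed

cfg = runx1_like_config(depth=500_000, seed=7, replicates_per_state=3)
sub = cfg.domain("P1_P2_subTAD")
balanced = []
for state in cfg.states:
    E = expected_matrix(cfg, state)
    for rep in (1, 2, 3):
        m = sample_counts(E, cfg.depth, replicate_seed(cfg.seed, state, rep), cfg.grid)
        balanced.append(ice_balance(m)[0])
groups = {}
for m, (state, rep) in zip(scale_to_mean_total(balanced),
                           [(s, r) for s in cfg.states for r in (1, 2, 3)]):
    groups.setdefault(state, []).extend(intra_tad_ratio(m, sub.bins).ratios)
for state, vals in groups.items():
    print(f"{state:9s} median intra/extra ratio: {np.median(vals):.3f}")
print(dunn_test(groups, adjust="holm").table.to_string(index=False))
```

prints

```
ESC       median intra/extra ratio: 1.040
mesoderm  median intra/extra ratio: 1.381
HPC       median intra/extra ratio: 2.174
 group_a  group_b          z            p        p_adj
     ESC mesoderm  -8.635767 5.833452e-18 5.833452e-18
     ESC      HPC -20.401980 1.605809e-92 4.817426e-92
mesoderm      HPC -11.766213 5.828243e-32 1.165649e-31
```

The median within/outside contact ratio of the sub-domain rises from ~1.0
(no enrichment beyond the surrounding TAD) through mesoderm to HPC, and
every pairwise comparison is significant after Holm adjustment —
the simulated sub-TAD reinforcement is recovered by the rank tests.

The same analysis is available from the shell:

```
tiledc simulate --preset runx1-like --depth 500000 --outdir sim/
tiledc balance sim/HPC_rep1.triplets.tsv --out hpc1.balanced.tsv
tiledc vcc --matrix hpc1.balanced.tsv --stage balanced \
       --viewpoint chr16:92695073 --out p2_profile.bedgraph
tiledc run pipeline.yaml          # full multi-sample pipeline
```

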