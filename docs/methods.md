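# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention). Published
intervals with inclusive end bases are converted on ingest by adding one
to the end (`GenomicInterval.from_inclusive`); whether a given printed
coordinate set was 0- or 1-based cannot be decided from the text, so the
conversion is a declared package convention, not a claim about any source.
A `BinGrid` partitions one tiled region into fixed-width bins
(`n_bins = ceil(length / bin_size)`); the last bin may be short and is a
full member of the grid. Grids are single-chromosome because a targeted-3C
tile covers one region.

## Contact matrices

Matrices are stored as canonical upper-triangle triplets (`i <= j`,
explicit zeros never stored); symmetric queries fold automatically.
**Total interactions** counts each unordered pair once, diagonal included
once — the text format and this definition make every scaling constant
reproducible.

### ICE balancing

Marginals are row sums of the symmetric matrix with the diagonal counted
once. Bins with zero marginal plus the lowest `low_cov_fraction`
(default 0.02, mirroring common Hi-C-normalization practice) of
positive-marginal bins are masked and their entries removed. Each
iteration divides entries by the outer product of relative marginals
(`m_i / mean`) and accumulates those factors into the bias vector;
iteration stops when every unmasked marginal is within `tol`
(default 1e-4) of the mean, or after `max_iter` (default 300) with a
warning and `converged=False`. The balanced matrix is rescaled to the
input total so that "total interactions" remains meaningful for the
subsequent mean-total scaling. The brute-force reference implementation
used in tests follows the identical update in plain Python, so agreement
checks the vectorization, masking, and rescaling rather than restating
one code path.

### Scaling, subtraction, capping

`scale_to_mean_total` multiplies each balanced matrix by one global
factor (mean input total / own total); within-matrix ratios are exactly
preserved and all totals agree to 1e-9 relative. Subtraction acts
entry-wise over the union of supports on scaled matrices and may be
negative; exact zeros are dropped. Display capping takes percentiles over
the **non-zero stored values** (sparse maps are dominated by structural
zeros, which would make an all-cells percentile degenerate); subtraction
maps are capped symmetrically — positives at the q-th percentile of
positives, negatives at minus the q-th percentile of magnitudes — with
numpy's linear order-statistic interpolation.

## Virtual Capture-C profiles

A profile is the matrix row at a viewpoint bin. The viewpoint's own bin
is always missing (self-ligation dominates it) and `exclusion_radius`
(default 0 extra bins) removes neighbors; masked bins are missing too.
Normalization is reporter counts per million cis contacts, using the
total of the same processed matrix the profile came from, which makes
tracks invariant to any global rescaling. Replicate aggregation uses the
sample SD (ddof = 1; defined as 0 for a single replicate) and a bin
missing in any replicate is missing in the aggregate and in difference
tracks.

## Domain statistics

Domains are inputs (named half-open bin ranges); the package does not
call TADs. For insulation, the self (diagonal) contact is excluded from
the intra sum — a self-ligation event is not an interaction — and bins
with zero extra-domain contact or masked bins are dropped and counted
rather than producing infinities, keeping rank tests defined. Ratios are
computed per replicate on scaled matrices by default (matching per-sample
distributions); raw/balanced inputs are also accepted and the stage
travels in the output metadata. "Outermost" CTCF sites are ranked by
feature start coordinate within the domain (a deterministic tie-break); a
site spanning two bins contributes both and duplicate bins are
de-duplicated. E-P totals sum over the de-duplicated union of enhancer
bins so overlapping annotations never double count, and the promoter's
own bin is excluded if an enhancer overlaps it.

## Statistical layer

Kruskal–Wallis uses midranks for ties with the tie term ΣT = Σ(t³−t)
computed over the pooled data; the fully tied degenerate case is defined
as H = 0, p = 1. Dunn's z uses the pooled-rank variance
N(N+1)/12 − ΣT/(12(N−1)) with two-sided normal p-values. Both are
implemented directly from the rank formulas (scipy supplies ranks and
tail probabilities); `scipy.stats.kruskal` and
`statsmodels.multipletests` serve as independent oracles in the tests,
never as the implementation. Holm (step-down) and Benjamini–Hochberg
(step-up) adjustments enforce monotonicity and cap at 1, preserving the
input order. Dunn's tests are computed unconditionally but flagged
"post hoc not warranted" when the omnibus p ≥ 0.05. The Shapiro–Wilk
gate wraps scipy's Royston implementation, restricted to
3 ≤ n ≤ 5000 and non-constant input, and is used only to justify the
rank-based route.

Size factors follow the median-of-ratios convention (geometric mean per
all-positive row; per-sample median of ratios); counts are transformed
as log2(count/factor + 1). PCA centers rows internally, computes the SVD
of the samples-by-rows matrix, and fixes each component's sign so its
largest-magnitude loading is positive (deterministic output). The
library-level default uses all rows with non-zero variance; the
**pipeline** pre-filters cells whose minimum per-sample count falls below
5 and restricts to the 500 most variable rows — the standard
log-normalized-count PCA procedure for count data — because at desk-scale
sequencing depth an unfiltered cell table is dominated by shot noise.

## Synthetic data model

The expected intensity of a cell (i ≤ j) is

    E_ij ∝ (1+|i−j|)^(−α) · Π_D γ_D(state) · Π_L (1 + λ_L(state)·exp(−((i−a)²+(j−b)²)/(2w²)))

normalized to sum 1 over the upper triangle, with diagonal distance term
(1+0)^(−α) = 1 standing in for self-bin ligation signal. Sequencing is a
single multinomial draw of `depth` read pairs (fixed total, matching the
total-interaction scaling downstream; preferred over independent Poisson
cells, either being defensible). Per-replicate seeds derive
deterministically from the base seed and a CRC of the (state, replicate)
label and are recorded in the truth manifest, so replicates are
independent yet every file reproduces byte-identically.

Defaults: α = 1.0, main-domain γ = 2, sub-domain γ = {1.0, 1.5, 3.0}
across the three states, loop λ ∈ [0, 5], loop width 1 bin, depth 5×10⁵
read pairs. No quantitative effect sizes for sub-TAD strengthening are
available to calibrate against, so these values were chosen once to
produce visually and statistically realistic structure at desk scale and
are all overridable.

The preset (`runx1_like_config`) reproduces the locus geometry: a
1268-bin, 2.5 Mb tile at 2 kb; a main TAD over bins [465, 1026)
(1.1 Mb, 561 bins); two nested sub-domains meeting at the proximal-
promoter (P2) bin whose boosts rise monotonically over
ESC → mesoderm → HPC; promoter viewpoints, ten enhancer loop anchors
named by their kb offset from the gene start codon, and convergent CTCF
sites at the TAD edges. The exact sub-domain coordinates are stand-ins
(published sub-TAD coordinates are not available). The `P2-CTCF-KO`
genotype removes every loop anchored at the P2 boundary bin and relaxes
the boost of the two sub-domains meeting there (3.0 → 2.0 in the HPC
state), emulating a weakened boundary; nothing else changes.

What the generator does **not** emulate: restriction-fragment-level
(non-uniform) binning, trans contacts, compartmentalization,
polymer/loop-extrusion dynamics, overdispersion beyond multinomial
sampling, and mapping artifacts. Passing tests therefore demonstrate
that the pipeline recovers planted domain/loop structure under clean
power-law backgrounds — not that it is robust to every artifact of real
sequencing data.

## Experiment problem sizes

The packaged experiments (`tiledc.experiments`) run the full
balance → scale → quantify → test chain:

* **Sub-TAD boost recovery** — two conditions differing only in one
  sub-domain boost (1.5 vs 3.0), 4 replicates each at depth 5×10⁵ on a
  compact 300-bin tile, 20 independent seeds; detection = Holm-adjusted
  Dunn p < 0.05 on pooled per-bin insulation ratios. The matched null
  (both boosts 1.5) measures the pipeline's false positive rate.
* **E-P loop detection** — one promoter–enhancer loop at λ = 0, 2, 5 and
  depth 5×10⁵ (the generator's default depth) on a 150-bin tile; a seed
  succeeds when balanced E-P totals increase strictly with λ.

The compact tiles keep the experiments at interactive speed while the
per-group sample sizes (hundreds of bin measurements) remain comparable
to per-domain bin counts on the full preset grid.

## Numerical notes and limitations

* Convergence is checked before each update, so an already-balanced
  matrix reports zero iterations.
* `merge` requires raw-stage inputs; balanced matrices are never summed
  (bias vectors are not additive).
* Boundary-contact lists include zeros for absent entries — absence of a
  contact is an observation, not missing data.
* Per-bin insulation ratios pooled across replicates treat bins as
  exchangeable observations within a state, as the per-sample
  distributions in this assay's figure conventions do; bins at a given
  distance share a replicate's multinomial total, a dependence that is
  negligible at the depths used but is not modeled.
* The asymptotic chi-square / normal tails of the rank tests are
  approximations; at very small group sizes an exact permutation test
  would differ (the suite checks agreement to 0.02 at n = 24).
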