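"""Generative model of targeted-3C contact maps.

The model composes three multiplicative layers on a bin grid:

* a power-law distance decay ``(1 + |i - j|)**(-alpha)``, the dominant
  feature of any chromosome-conformation contact map;
* multiplicative domain enrichment: every pair with both bins inside a
  domain D gains a state-dependent factor ``gamma_D(state) >= 1``,
  producing TAD/sub-TAD blocks;
* Gaussian loop anchors: a focal enrichment
  ``1 + lambda_L(state) * exp(-((i - a)^2 + (j - b)^2) / (2 w^2))``
  centered on an anchor pair ``(a, b)``, emulating CTCF-CTCF and
  enhancer-promoter loops.

The product over the upper triangle is normalized to a probability
distribution and sequencing is emulated by a single multinomial draw of
``depth`` read pairs (fixed total, matching the total-interaction
scaling used downstream).  Diagonal cells carry the distance term
``(1 + 0)**(-alpha) = 1``, standing in for self-bin ligation signal.

:func:`runx1_like_config` builds a preset emulating the geometry of a
2.5 Mb tile around a large developmental gene: a ~1.1 Mb main TAD, two
nested sub-TADs whose strength grows over a three-state differentiation
course (ESC -> mesoderm -> HPC), promoter viewpoints, enhancer loop
anchors, and boundary-weakened "CTCF-KO" variants.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import BinGrid, Feature, FeatureSet, GenomicInterval, write_bed
from .matrix import ContactMatrix, SampleMeta, write_triplets

__all__ = [
    "DomainSpec",
    "LoopSpec",
    "SimulationConfig",
    "TruthManifest",
    "expected_matrix",
    "sample_counts",
    "simulate_experiment",
    "runx1_like_config",
    "replicate_seed",
]


@dataclass(frozen=True)
class DomainSpec:
    """A self-interacting domain: half-open bin range with per-state boost."""

    name: str
    start: int
    stop: int
    boost_by_state: dict[str, float]

    def __post_init__(self) -> None:
        if self.stop <= self.start or self.start < 0:
            raise ValueError(f"bad domain range [{self.start}, {self.stop})")
        if any(g <= 0 for g in self.boost_by_state.values()):
            raise ValueError("domain boosts must be > 0")

    @property
    def bins(self) -> range:
        return range(self.start, self.stop)


@dataclass(frozen=True)
class LoopSpec:
    """Focal loop between two anchor bins with per-state strength."""

    name: str
    anchor_a: int
    anchor_b: int
    strength_by_state: dict[str, float]
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.anchor_a >= self.anchor_b:
            raise ValueError("anchor_a must be < anchor_b")
        if self.width <= 0:
            raise ValueError("loop width must be > 0")
        if any(s < 0 for s in self.strength_by_state.values()):
            raise ValueError("loop strengths must be >= 0")


@dataclass
class SimulationConfig:
    """Full generative model for one simulated experiment."""

    grid: BinGrid
    decay_exponent: float
    domains: list[DomainSpec]
    loops: list[LoopSpec]
    states: list[str]
    replicates_per_state: int
    depth: int
    seed: int
    features: FeatureSet | None = None

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not self.states:
            raise ValueError("need at least one state")
        if self.replicates_per_state < 1:
            raise ValueError("replicates_per_state must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        n = self.grid.n_bins
        for d in self.domains:
            if d.stop > n:
                raise ValueError(f"domain {d.name} exceeds grid ({n} bins)")
        for lp in self.loops:
            if lp.anchor_b >= n:
                raise ValueError(f"loop {lp.name} exceeds grid ({n} bins)")

    def domain(self, name: str) -> DomainSpec:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)


@dataclass
class TruthManifest:
    """What was simulated: config echo, per-file seeds, expected orderings."""

    config: dict
    entries: list[dict]
    expected_orderings: list[dict]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "entries": self.entries,
                "expected_orderings": self.expected_orderings,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(d["config"], d["entries"], d["expected_orderings"])


def _config_summary(config: SimulationConfig) -> dict:
    return {
        "grid": config.grid.to_dict(),
        "decay_exponent": config.decay_exponent,
        "states": list(config.states),
        "replicates_per_state": config.replicates_per_state,
        "depth": config.depth,
        "seed": config.seed,
        "domains": [
            {
                "name": d.name,
                "start": d.start,
                "stop": d.stop,
                "boost_by_state": d.boost_by_state,
            }
            for d in config.domains
        ],
        "loops": [
            {
                "name": lp.name,
                "anchor_a": lp.anchor_a,
                "anchor_b": lp.anchor_b,
                "strength_by_state": lp.strength_by_state,
                "width": lp.width,
            }
            for lp in config.loops
        ],
    }


def expected_matrix(config: SimulationConfig, state: str) -> np.ndarray:
    """Noise-free expected-intensity matrix for one state.

    Returns the full symmetric dense array whose upper triangle
    (``i <= j``, diagonal included) sums to 1.
    """
    if state not in config.states:
        raise KeyError(f"unknown state {state!r}; states are {config.states}")
    n = config.grid.n_bins
    iu, ju = np.triu_indices(n)
    e = (1.0 + (ju - iu)) ** (-config.decay_exponent)
    for d in config.domains:
        gamma = d.boost_by_state.get(state, 1.0)
        if gamma != 1.0:
            inside = (iu >= d.start) & (iu < d.stop) & (ju >= d.start) & (ju < d.stop)
            e[inside] *= gamma
    for lp in config.loops:
        lam = lp.strength_by_state.get(state, 0.0)
        if lam > 0:
            g = np.exp(
                -((iu - lp.anchor_a) ** 2 + (ju - lp.anchor_b) ** 2)
                / (2.0 * lp.width**2)
            )
            e *= 1.0 + lam * g
    e /= e.sum()
    dense = np.zeros((n, n), dtype=np.float64)
    dense[iu, ju] = e
    dense[ju, iu] = e
    return dense


def sample_counts(
    expected: np.ndarray,
    depth: int,
    seed: int,
    grid: BinGrid,
    meta: SampleMeta | None = None,
) -> ContactMatrix:
    """Multinomial draw of ``depth`` read pairs over the upper triangle.

    The total of the resulting raw matrix equals ``depth`` exactly;
    identical (expected, depth, seed) reproduce identical matrices.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = grid.n_bins
    if expected.shape != (n, n):
        raise ValueError(f"expected matrix shape {expected.shape} != ({n}, {n})")
    iu, ju = np.triu_indices(n)
    p = expected[iu, ju]
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, p)
    keep = counts > 0
    return ContactMatrix(
        grid, iu[keep], ju[keep], counts[keep].astype(np.float64),
        stage="raw", meta=meta,
    )


def replicate_seed(base_seed: int, state: str, replicate: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    h = zlib.crc32(f"{state}:{replicate}".encode())
    return (base_seed + h) % (2**31 - 1)


def simulate_experiment(config: SimulationConfig, outdir: str | Path) -> TruthManifest:
    """Write one triplet file per (state, replicate) plus a truth manifest.

    Re-running with the same config reproduces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.grid.write_sidecar(outdir / "grid.json")
    if config.features is not None:
        for category in ("enhancer", "ctcf", "promoter"):
            sub = config.features.of_category(category)
            if len(sub):
                write_bed(sub, outdir / f"features.{category}.bed")

    entries: list[dict] = []
    for state in config.states:
        dense = expected_matrix(config, state)
        for rep in range(1, config.replicates_per_state + 1):
            seed = replicate_seed(config.seed, state, rep)
            meta = SampleMeta(state=state, replicate=str(rep))
            m = sample_counts(dense, config.depth, seed, config.grid, meta)
            fname = f"{state}_rep{rep}.triplets.tsv"
            write_triplets(m, outdir / fname, sidecar=False)
            entries.append(
                {"state": state, "replicate": rep, "seed": seed, "path": fname}
            )

    orderings = []
    for d in config.domains:
        order = sorted(
            (s for s in config.states if s in d.boost_by_state),
            key=lambda s: d.boost_by_state[s],
        )
        orderings.append({"domain": d.name, "states_by_increasing_boost": order})

    manifest = TruthManifest(_config_summary(config), entries, orderings)
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


# -- preset -------------------------------------------------------------------

#: printed tile and main-TAD coordinates (mm9, inclusive ends as published)
TILE_CHROM = "chr16"
TILE_START = 91_566_000
TILE_END_INCLUSIVE = 94_101_999
MAIN_TAD_START = 92_496_000
MAIN_TAD_END_INCLUSIVE = 93_617_999
BIN_SIZE = 2000


def runx1_like_config(
    depth: int = 500_000,
    seed: int = 0,
    replicates_per_state: int = 3,
    genotype: str = "WT",
) -> SimulationConfig:
    """Preset emulating the Runx1-locus tile geometry.

    A 2.5 Mb tile at 2 kb resolution (1268 bins) holding a 1.1 Mb main
    TAD (bins [465, 1026)) and two nested sub-TADs that share an
    internal boundary bin at the proximal (P2) promoter and strengthen
    monotonically over ESC -> mesoderm -> HPC.  Viewpoint promoters,
    enhancer loop anchors, and boundary CTCF sites are recorded as a
    :class:`FeatureSet` on the config.

    ``genotype="P2-CTCF-KO"`` removes every loop anchored at the P2
    boundary bin and relaxes the boost of the two sub-domains that meet
    at that boundary; nothing else changes, emulating a weakened
    boundary after deletion of the promoter-proximal CTCF site.
    """
    if genotype not in ("WT", "P2-CTCF-KO"):
        raise ValueError(f"unknown genotype {genotype!r}")
    region = GenomicInterval.from_inclusive(TILE_CHROM, TILE_START, TILE_END_INCLUSIVE)
    grid = BinGrid(region, BIN_SIZE)
    main_tad = grid.bins_for_interval(
        GenomicInterval.from_inclusive(TILE_CHROM, MAIN_TAD_START, MAIN_TAD_END_INCLUSIVE)
    )

    states = ["ESC", "mesoderm", "HPC"]
    # proximal promoter (P2) sits at the shared internal sub-TAD boundary
    p2_bin = grid.coord_to_bin(92_695_073)   # 564
    p1_bin = grid.coord_to_bin(92_823_811)   # 628
    sub_gamma = {"ESC": 1.0, "mesoderm": 1.5, "HPC": 3.0}
    if genotype == "P2-CTCF-KO":
        # weakened boundary: both sub-domains touch the P2 boundary bin
        sub_gamma = {"ESC": 1.0, "mesoderm": 1.25, "HPC": 2.0}
    domains = [
        DomainSpec("main_TAD", main_tad.start, main_tad.stop,
                   {s: 2.0 for s in states}),
        DomainSpec("P2_3prime_subTAD", 500, p2_bin, dict(sub_gamma)),
        DomainSpec("P1_P2_subTAD", p2_bin, p1_bin + 1, dict(sub_gamma)),
    ]

    # enhancers named by distance (kb) from the gene start codon; negative
    # labels lie in the upstream gene desert, positive in the gene body
    start_codon = 92_826_000
    enhancer_offsets_kb = [-327, -322, -303, -181, -171, -59, 3, 23, 48, 110]
    features = []
    enhancer_bins: dict[str, int] = {}
    for off in enhancer_offsets_kb:
        # the gene runs from the start codon toward lower coordinates, so
        # gene-body enhancers (+) sit below it and desert enhancers (-) above
        pos = start_codon - off * 1000
        name = f"{off:+d}"
        features.append(
            Feature(name, GenomicInterval(TILE_CHROM, pos, pos + 1000), "enhancer")
        )
        enhancer_bins[name] = grid.coord_to_bin(pos)

    features.append(
        Feature("P2", grid.bin_interval(p2_bin), "promoter")
    )
    features.append(
        Feature("P1", grid.bin_interval(p1_bin), "promoter")
    )

    # convergent CTCF sites: forward motifs at the centromeric TAD edge,
    # reverse at the telomeric edge, plus the promoter-proximal sites
    ctcf_fwd_bins = [465, 468, 472, 478, 490]
    ctcf_rev_bins = [1000, 1008, 1015, 1020, 1025]
    for b in ctcf_fwd_bins:
        features.append(
            Feature(f"CTCF_c{b}", grid.bin_interval(b), "ctcf", "forward")
        )
    for b in ctcf_rev_bins:
        features.append(
            Feature(f"CTCF_t{b}", grid.bin_interval(b), "ctcf", "reverse")
        )
    features.append(Feature("P2-CTCF", grid.bin_interval(p2_bin), "ctcf", "reverse"))
    features.append(Feature("P1-CTCF", grid.bin_interval(p1_bin), "ctcf", "reverse"))

    # loops: TAD-corner CTCF-CTCF loop, plus promoter-anchored E-P loops
    # that strengthen over differentiation
    loops = [
        LoopSpec("TAD_corner", 465, 1025,
                 {"ESC": 1.0, "mesoderm": 2.0, "HPC": 2.0}, width=2.0),
    ]
    desert = {"-327", "-322", "-303", "-181", "-171"}
    for name, ebin in enhancer_bins.items():
        a, b = sorted((p2_bin, ebin))
        if name in desert:
            strength = {"ESC": 0.0, "mesoderm": 2.0, "HPC": 1.0}
        else:
            strength = {"ESC": 0.0, "mesoderm": 1.0, "HPC": 3.0}
        loops.append(LoopSpec(f"P2:{name}", a, b, strength, width=1.0))
    for name in ("+23", "+48", "+110"):
        a, b = sorted((p1_bin, enhancer_bins[name]))
        loops.append(
            LoopSpec(f"P1:{name}", a, b,
                     {"ESC": 0.0, "mesoderm": 0.5, "HPC": 2.0}, width=1.0)
        )
    if genotype == "P2-CTCF-KO":
        loops = [lp for lp in loops if p2_bin not in (lp.anchor_a, lp.anchor_b)]

    return SimulationConfig(
        grid=grid,
        decay_exponent=1.0,
        domains=domains,
        loops=loops,
        states=states,
        replicates_per_state=replicates_per_state,
        depth=depth,
        seed=seed,
        features=FeatureSet(features, provenance=f"runx1-like preset ({genotype})"),
    )
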