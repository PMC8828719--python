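"""Domain, boundary, and enhancer-promoter quantification statistics.

Domains (TADs and sub-TADs) are inputs here, not called de novo: the
analysis quantifies, per sample, how strongly a given domain insulates
and how specific bin sets interact.

* Insulation ("intra-TAD interaction ratio"): for each bin inside the
  domain, the ratio of its summed contacts with other domain bins to
  its summed contacts with bins outside the domain.  The self (diagonal)
  contact is excluded from the intra sum.  Bins with no extra-domain
  contact (or masked bins) are dropped and counted, so downstream rank
  tests stay defined.
* Boundary contacts: all pairwise values between two bin sets, e.g. the
  bins of the k outermost CTCF sites at either end of a TAD.
* E-P contacts: contact values between a promoter viewpoint bin and the
  bins overlapping a set of enhancers; the total is taken over the
  de-duplicated union of enhancer bins so overlapping annotations are
  not double counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid, Feature, FeatureSet
from .matrix import ContactMatrix

__all__ = [
    "DomainSet",
    "InsulationResult",
    "EPResult",
    "intra_tad_ratio",
    "insulation_table",
    "boundary_bin_sets",
    "boundary_contacts",
    "ep_contacts",
]


@dataclass
class DomainSet:
    """Named half-open bin ranges on a grid (e.g. main_TAD, sub-TADs)."""

    grid: BinGrid
    ranges: dict[str, range]

    def __post_init__(self) -> None:
        for name, r in self.ranges.items():
            if len(r) == 0:
                raise ValueError(f"domain {name!r} is empty")
            if r.start < 0 or r.stop > self.grid.n_bins:
                raise ValueError(f"domain {name!r} outside grid")

    def __getitem__(self, name: str) -> range:
        return self.ranges[name]


@dataclass
class InsulationResult:
    """Per-bin intra/extra ratios for one domain in one sample."""

    domain: str
    ratios: np.ndarray
    bins: np.ndarray
    dropped: int
    state: str | None = None
    replicate: str | None = None


@dataclass
class EPResult:
    """Promoter-viewpoint contact values with a set of enhancers."""

    promoter: str
    promoter_bin: int
    per_enhancer: dict[str, float]
    per_bin: dict[int, float]
    total: float
    state: str | None = None
    replicate: str | None = None


def intra_tad_ratio(m: ContactMatrix, domain_bins: range) -> InsulationResult:
    """Intra/extra interaction ratio for each unmasked bin of a domain."""
    if len(domain_bins) == 0:
        raise ValueError("empty domain")
    if m.stage not in ("balanced", "scaled"):
        raise ValueError(
            f"intra_tad_ratio expects a balanced or scaled matrix, got {m.stage!r}"
        )
    dense = m.to_dense()
    n = m.grid.n_bins
    inside = np.zeros(n, dtype=bool)
    inside[domain_bins.start:domain_bins.stop] = True
    row_sums = dense.sum(axis=1)            # diagonal counted once
    intra_sums = dense[:, inside].sum(axis=1)

    ratios: list[float] = []
    kept: list[int] = []
    dropped = 0
    for b in domain_bins:
        if b in m.masked_bins:
            dropped += 1
            continue
        intra = intra_sums[b] - dense[b, b]  # self contact is not an interaction
        extra = row_sums[b] - intra_sums[b]
        if extra <= 0:
            dropped += 1
            continue
        ratios.append(intra / extra)
        kept.append(b)
    return InsulationResult(
        domain="",
        ratios=np.asarray(ratios, dtype=np.float64),
        bins=np.asarray(kept, dtype=np.int64),
        dropped=dropped,
        state=m.meta.state,
        replicate=m.meta.replicate,
    )


def insulation_table(
    matrices: list[ContactMatrix], domains: DomainSet
) -> pd.DataFrame:
    """Tidy per-bin insulation ratios for every (sample, domain).

    Columns: state, replicate, domain, bin, ratio.
    """
    rows = []
    for m in matrices:
        for name, r in domains.ranges.items():
            res = intra_tad_ratio(m, r)
            for b, v in zip(res.bins, res.ratios):
                rows.append(
                    {
                        "state": m.meta.state,
                        "replicate": m.meta.replicate,
                        "domain": name,
                        "bin": int(b),
                        "ratio": float(v),
                    }
                )
    return pd.DataFrame(rows, columns=["state", "replicate", "domain", "bin", "ratio"])


def boundary_bin_sets(
    features: FeatureSet | list[Feature],
    domain_bins: range,
    grid: BinGrid,
    k: int = 4,
) -> tuple[list[int], list[int]]:
    """Bins of the k outermost CTCF sites at each end of a domain.

    Sites are ranked by start coordinate among CTCF features whose bins
    lie inside the domain; set A takes the k smallest-start sites, set B
    the k largest.  A feature spanning several bins contributes all of
    them; duplicate bins are de-duplicated (order preserved).
    """
    feats = list(features)
    ctcf = []
    for f in feats:
        if f.category != "ctcf":
            continue
        try:
            bins = grid.bins_for_interval(f.interval)
        except ValueError:
            continue
        if all(domain_bins.start <= b < domain_bins.stop for b in bins):
            ctcf.append((f.interval.start, list(bins)))
    ctcf.sort(key=lambda t: t[0])
    if len(ctcf) < k:
        raise ValueError(
            f"need at least {k} CTCF sites inside the domain on each side, "
            f"found {len(ctcf)} in total"
        )

    def dedup(seq: list[int]) -> list[int]:
        seen: set[int] = set()
        out = []
        for b in seq:
            if b not in seen:
                seen.add(b)
                out.append(b)
        return out

    a = dedup([b for _, bins in ctcf[:k] for b in bins])
    b_set = dedup([b for _, bins in ctcf[-k:] for b in bins])
    return a, b_set


def boundary_contacts(
    m: ContactMatrix, a: list[int], b: list[int]
) -> np.ndarray:
    """All |A| x |B| contact values between two disjoint bin sets."""
    if not a or not b:
        raise ValueError("bin sets must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"bin sets overlap: {sorted(set(a) & set(b))}")
    dense = m.to_dense()
    return dense[np.ix_(a, b)].ravel()


def ep_contacts(
    m: ContactMatrix,
    promoter_bin: int,
    enhancers: FeatureSet | list[Feature],
    grid: BinGrid,
    promoter_name: str = "",
) -> EPResult:
    """Contacts between a promoter bin and enhancer-overlapping bins.

    Per-enhancer values sum the contact over that enhancer's bins; the
    total sums over the de-duplicated union of all enhancer bins, so a
    bin shared by two enhancers is counted once.  The promoter's own
    bin is excluded should an enhancer overlap it.
    """
    if not 0 <= promoter_bin < grid.n_bins:
        raise ValueError(f"promoter bin {promoter_bin} not on grid")
    if promoter_bin in m.masked_bins:
        raise ValueError(f"promoter bin {promoter_bin} was masked during balancing")
    feats = [f for f in enhancers if f.category == "enhancer"]
    if not feats:
        raise ValueError("no enhancer features supplied")
    per_enhancer: dict[str, float] = {}
    union: dict[int, float] = {}
    for f in feats:
        bins = [
            b for b in grid.bins_for_interval(f.interval) if b != promoter_bin
        ]
        per_enhancer[f.name] = float(
            sum(m.get(promoter_bin, b) for b in bins)
        )
        for b in bins:
            union.setdefault(b, float(m.get(promoter_bin, b)))
    return EPResult(
        promoter=promoter_name,
        promoter_bin=promoter_bin,
        per_enhancer=per_enhancer,
        per_bin=union,
        total=float(sum(union.values())),
        state=m.meta.state,
        replicate=m.meta.replicate,
    )
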