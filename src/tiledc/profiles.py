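"""Virtual Capture-C: one-dimensional viewpoint profiles from contact
matrices, cis normalization, replicate aggregation, and bedGraph export.

A viewpoint profile is the row of the symmetric contact matrix at a
single anchor bin (for instance a gene promoter).  The viewpoint's own
bin is always excluded (self-ligation dominates it) and an optional
exclusion radius removes adjacent bins as well.  Missing bins are
carried as NaN.

Normalization is "per million cis contacts": each value is scaled by
1e6 over the total interactions of the matrix the profile came from, so
tracks are comparable across samples and invariant to any global
rescaling of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import BinGrid
from .matrix import ContactMatrix, total_interactions

__all__ = [
    "ViewpointProfile",
    "ProfileAggregate",
    "virtual_capture",
    "normalize_profile",
    "aggregate_replicates",
    "subtract_profiles",
    "write_bedgraph",
]


@dataclass
class ViewpointProfile:
    """Per-bin contact values from one viewpoint (NaN where missing)."""

    viewpoint_bin: int
    values: np.ndarray
    normalization: str  # "raw" or "per-million-cis"
    grid: BinGrid
    state: str | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"profile length {self.values.size} != n_bins {self.grid.n_bins}"
            )

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class ProfileAggregate:
    """Per-bin mean and sample SD over replicate profiles of one state."""

    viewpoint_bin: int
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    normalization: str
    grid: BinGrid
    state: str | None = None


def virtual_capture(
    m: ContactMatrix, viewpoint_bin: int, exclusion_radius: int = 0
) -> ViewpointProfile:
    """Extract the raw profile of ``viewpoint_bin`` from a matrix.

    The value at bin k is the matrix entry (min(v, k), max(v, k)); bins
    within ``exclusion_radius`` of the viewpoint, and the viewpoint
    itself, are set to NaN, as are bins masked during balancing.
    """
    n = m.grid.n_bins
    if not 0 <= viewpoint_bin < n:
        raise ValueError(f"viewpoint bin {viewpoint_bin} not in [0, {n})")
    if viewpoint_bin in m.masked_bins:
        raise ValueError(
            f"viewpoint bin {viewpoint_bin} was masked during balancing"
        )
    if m.stage == "subtraction":
        raise ValueError("virtual_capture is undefined on subtraction matrices")
    values = m.to_dense()[viewpoint_bin].astype(np.float64)
    lo = max(0, viewpoint_bin - exclusion_radius)
    hi = min(n, viewpoint_bin + exclusion_radius + 1)
    values[lo:hi] = np.nan
    if m.masked_bins:
        values[list(m.masked_bins)] = np.nan
    return ViewpointProfile(
        viewpoint_bin, values, "raw", m.grid,
        state=m.meta.state, replicate=m.meta.replicate,
    )


def normalize_profile(p: ViewpointProfile, m: ContactMatrix) -> ViewpointProfile:
    """Scale a raw profile to reporter counts per million cis contacts."""
    if p.normalization != "raw":
        raise ValueError("profile is already normalized")
    total = total_interactions(m)
    if total == 0:
        raise ValueError("cannot normalize against a zero-total matrix")
    return ViewpointProfile(
        p.viewpoint_bin, p.values * (1e6 / total), "per-million-cis",
        p.grid, state=p.state, replicate=p.replicate,
    )


def aggregate_replicates(profiles: list[ViewpointProfile]) -> ProfileAggregate:
    """Per-bin mean and sample SD (ddof=1; SD 0 for a single replicate).

    Bins missing in any replicate are missing in the aggregate.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if p.viewpoint_bin != first.viewpoint_bin:
            raise ValueError("viewpoint mismatch across replicates")
        if p.grid != first.grid:
            raise ValueError("grid mismatch across replicates")
        if p.normalization != first.normalization:
            raise ValueError("normalization mismatch across replicates")
    stack = np.vstack([p.values for p in profiles])
    missing = np.isnan(stack).any(axis=0)
    mean = stack.mean(axis=0)
    if len(profiles) > 1:
        sd = stack.std(axis=0, ddof=1)
    else:
        sd = np.zeros_like(mean)
    mean[missing] = np.nan
    sd[missing] = np.nan
    return ProfileAggregate(
        first.viewpoint_bin, mean, sd, len(profiles),
        first.normalization, first.grid, state=first.state,
    )


def subtract_profiles(a: ProfileAggregate, b: ProfileAggregate) -> np.ndarray:
    """Per-bin difference of mean tracks (NaN where either is missing)."""
    if a.viewpoint_bin != b.viewpoint_bin:
        raise ValueError("viewpoint mismatch")
    if a.grid != b.grid:
        raise ValueError("grid mismatch")
    if a.normalization != b.normalization:
        raise ValueError("normalization mismatch")
    return a.mean - b.mean


def write_bedgraph(track: np.ndarray, grid: BinGrid, path: str | Path) -> int:
    """Write one bedGraph line per non-missing bin; returns line count."""
    track = np.asarray(track, dtype=np.float64)
    if track.shape != (grid.n_bins,):
        raise ValueError(f"track length {track.size} != n_bins {grid.n_bins}")
    n_written = 0
    with Path(path).open("w") as fh:
        for b, v in enumerate(track):
            if np.isnan(v):
                continue
            iv = grid.bin_interval(b)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.10g}\n")
            n_written += 1
    return n_written
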