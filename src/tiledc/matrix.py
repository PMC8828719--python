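"""Sparse symmetric contact matrices: triplet I/O, merging, ICE
balancing, cross-sample scaling, subtraction, and display capping.

Storage is canonical upper triangle: every unordered bin pair ``(i, j)``
with ``i <= j`` appears at most once and a query for ``(j, i)`` returns
the ``(i, j)`` value.  "Total interactions" counts each unordered pair
once and includes the diagonal once; this is the quantity preserved by
balancing and equalized by :func:`scale_to_mean_total`.

ICE (iterative correction) removes per-bin coverage bias by scaling the
matrix until all unmasked bin marginals are equal.  The marginal of bin
``i`` is the row sum of the symmetric matrix with the diagonal counted
once.  Bins with zero coverage, plus the lowest-coverage fraction of the
remaining bins, are masked before correction, mirroring the sparsity
filter of standard Hi-C normalization tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import BinGrid

__all__ = [
    "STAGES",
    "SampleMeta",
    "ContactMatrix",
    "BalancingResult",
    "read_triplets",
    "write_triplets",
    "total_interactions",
    "merge",
    "ice_balance",
    "scale_to_mean_total",
    "subtract",
    "percentile_cap",
]

STAGES = frozenset({"raw", "balanced", "scaled", "merged", "subtraction"})


@dataclass(frozen=True)
class SampleMeta:
    """Sample provenance carried with a matrix through the pipeline."""

    state: str | None = None
    replicate: str | None = None
    genotype: str | None = None
    note: str = ""


class ContactMatrix:
    """Symmetric sparse contact matrix on a :class:`BinGrid`.

    Parameters
    ----------
    grid :
        The bin grid indexing both axes.
    bins1, bins2, values :
        Parallel arrays of canonical entries (``bins1 <= bins2``),
        sorted lexicographically.  Use :meth:`from_entries` to build
        from arbitrary (possibly duplicated, lower-triangle) triplets.
    stage :
        One of ``raw``, ``balanced``, ``scaled``, ``merged``,
        ``subtraction``.
    masked_bins :
        Bins removed by balancing; propagated through scaling and
        subtraction.
    """

    def __init__(
        self,
        grid: BinGrid,
        bins1: np.ndarray,
        bins2: np.ndarray,
        values: np.ndarray,
        stage: str,
        meta: SampleMeta | None = None,
        masked_bins: frozenset[int] = frozenset(),
    ):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        bins1 = np.asarray(bins1, dtype=np.int64)
        bins2 = np.asarray(bins2, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if not (bins1.shape == bins2.shape == values.shape):
            raise ValueError("bins1, bins2, values must have equal length")
        if bins1.size and (bins1.min() < 0 or bins2.max() >= grid.n_bins):
            raise ValueError("bin index outside grid")
        if np.any(bins1 > bins2):
            raise ValueError("entries must be canonical (i <= j)")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if stage != "subtraction" and bins1.size and values.min() < 0:
            raise ValueError(f"negative value in {stage}-stage matrix")
        nonzero = values != 0  # explicit zeros are never stored
        if not nonzero.all():
            bins1, bins2, values = bins1[nonzero], bins2[nonzero], values[nonzero]
        self.grid = grid
        self.bins1 = bins1
        self.bins2 = bins2
        self.values = values
        self.stage = stage
        self.meta = meta or SampleMeta()
        self.masked_bins = frozenset(masked_bins)
        self._lookup: dict[tuple[int, int], float] | None = None

    # -- constructors ---------------------------------------------------------

    @classmethod
    def from_entries(
        cls,
        grid: BinGrid,
        bins1: Iterable[int],
        bins2: Iterable[int],
        values: Iterable[float],
        stage: str = "raw",
        meta: SampleMeta | None = None,
        masked_bins: frozenset[int] = frozenset(),
    ) -> "ContactMatrix":
        """Fold arbitrary triplets to canonical form, summing duplicates."""
        i = np.asarray(list(bins1) if not isinstance(bins1, np.ndarray) else bins1, dtype=np.int64)
        j = np.asarray(list(bins2) if not isinstance(bins2, np.ndarray) else bins2, dtype=np.int64)
        v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=np.float64)
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        if lo.size:
            if lo.min() < 0 or hi.max() >= grid.n_bins:
                raise ValueError("bin index outside grid")
            lin = lo * grid.n_bins + hi
            uniq, inv = np.unique(lin, return_inverse=True)
            summed = np.zeros(uniq.size, dtype=np.float64)
            np.add.at(summed, inv, v)
            keep = summed != 0
            uniq, summed = uniq[keep], summed[keep]
            lo = uniq // grid.n_bins
            hi = uniq % grid.n_bins
            v = summed
        return cls(grid, lo, hi, v, stage, meta, masked_bins)

    @classmethod
    def from_dense(
        cls,
        grid: BinGrid,
        dense: np.ndarray,
        stage: str,
        meta: SampleMeta | None = None,
        masked_bins: frozenset[int] = frozenset(),
    ) -> "ContactMatrix":
        """Extract the non-zero upper triangle of a symmetric dense array."""
        n = grid.n_bins
        if dense.shape != (n, n):
            raise ValueError(f"dense shape {dense.shape} != ({n}, {n})")
        iu, ju = np.triu_indices(n)
        vals = dense[iu, ju]
        keep = vals != 0
        return cls(grid, iu[keep], ju[keep], vals[keep], stage, meta, masked_bins)

    # -- basic access ---------------------------------------------------------

    @property
    def n_entries(self) -> int:
        return int(self.values.size)

    def get(self, i: int, j: int) -> float:
        """Value at (i, j); symmetric; 0 if absent."""
        if self._lookup is None:
            self._lookup = {
                (int(a), int(b)): float(x)
                for a, b, x in zip(self.bins1, self.bins2, self.values)
            }
        a, b = (i, j) if i <= j else (j, i)
        return self._lookup.get((a, b), 0.0)

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense array (diagonal stored once)."""
        n = self.grid.n_bins
        dense = np.zeros((n, n), dtype=np.float64)
        dense[self.bins1, self.bins2] = self.values
        dense[self.bins2, self.bins1] = self.values
        return dense

    def scaled_by(self, factor: float, stage: str | None = None) -> "ContactMatrix":
        return ContactMatrix(
            self.grid, self.bins1, self.bins2, self.values * factor,
            stage or self.stage, self.meta, self.masked_bins,
        )

    def with_meta(self, meta: SampleMeta) -> "ContactMatrix":
        return ContactMatrix(
            self.grid, self.bins1, self.bins2, self.values,
            self.stage, meta, self.masked_bins,
        )

    def equals(self, other: "ContactMatrix", atol: float = 0.0) -> bool:
        return (
            self.grid == other.grid
            and self.stage == other.stage
            and self.bins1.shape == other.bins1.shape
            and bool(np.array_equal(self.bins1, other.bins1))
            and bool(np.array_equal(self.bins2, other.bins2))
            and bool(np.allclose(self.values, other.values, rtol=0, atol=atol))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ContactMatrix {self.stage} {self.grid.n_bins} bins, "
            f"{self.n_entries} entries, total={total_interactions(self) if self.stage != 'subtraction' else 'n/a'}>"
        )


@dataclass
class BalancingResult:
    """Outcome of ICE balancing: per-bin bias factors and diagnostics.

    ``bias`` is NaN for masked bins.  ``final_marginal_spread`` is the
    maximum relative deviation of unmasked marginals from their mean.
    """

    bias: np.ndarray
    masked_bins: frozenset[int]
    iterations: int
    converged: bool
    final_marginal_spread: float


# -- triplet I/O --------------------------------------------------------------


def read_triplets(path: str | Path, grid: BinGrid, stage: str = "raw") -> ContactMatrix:
    """Read a ``i<TAB>j<TAB>value`` triplet file.

    Entries are folded to the canonical upper triangle (duplicates and
    transposed pairs summed).  Raw-stage values must be non-negative
    integers.
    """
    path = Path(path)
    ii: list[int] = []
    jj: list[int] = []
    vv: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'i<TAB>j<TAB>value'")
        try:
            i, j = int(cols[0]), int(cols[1])
            v = float(cols[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unparsable triplet {line!r}") from None
        if i < 0 or j < 0 or i >= grid.n_bins or j >= grid.n_bins:
            raise ValueError(
                f"{path}:{lineno}: bin index out of range for grid with "
                f"{grid.n_bins} bins"
            )
        if stage == "raw" and (v < 0 or v != int(v)):
            raise ValueError(
                f"{path}:{lineno}: raw-stage value must be a non-negative "
                f"integer, got {cols[2]!r}"
            )
        ii.append(i)
        jj.append(j)
        vv.append(v)
    return ContactMatrix.from_entries(grid, ii, jj, vv, stage=stage)


def write_triplets(m: ContactMatrix, path: str | Path, sidecar: bool = True) -> None:
    """Write canonical entries sorted by (i, j); optional grid sidecar.

    The sidecar is ``<path>.grid.json`` describing chrom/start/end/
    bin_size so the file is self-describing.
    """
    path = Path(path)
    with path.open("w") as fh:
        for i, j, v in zip(m.bins1, m.bins2, m.values):
            # integers print bare; floats use shortest exact representation
            text = str(int(v)) if v == int(v) else repr(float(v))
            fh.write(f"{i}\t{j}\t{text}\n")
    if sidecar:
        m.grid.write_sidecar(str(path) + ".grid.json")


# -- arithmetic ---------------------------------------------------------------


def total_interactions(m: ContactMatrix) -> float:
    """Sum over canonical entries: each unordered pair once, diagonal once."""
    if m.stage == "subtraction":
        raise ValueError("total_interactions is undefined for subtraction matrices")
    return float(m.values.sum())


def merge(matrices: Sequence[ContactMatrix]) -> ContactMatrix:
    """Element-wise sum of raw replicate matrices (stage ``merged``)."""
    if not matrices:
        raise ValueError("need at least one matrix to merge")
    grid = matrices[0].grid
    for m in matrices:
        if m.grid != grid:
            raise ValueError("grid mismatch in merge")
        if m.stage != "raw":
            raise ValueError(f"merge requires raw matrices, got {m.stage!r}")
    reps = ",".join(str(m.meta.replicate) for m in matrices)
    meta = SampleMeta(
        state=matrices[0].meta.state,
        replicate=None,
        genotype=matrices[0].meta.genotype,
        note=f"merge of replicates [{reps}]",
    )
    return ContactMatrix.from_entries(
        grid,
        np.concatenate([m.bins1 for m in matrices]),
        np.concatenate([m.bins2 for m in matrices]),
        np.concatenate([m.values for m in matrices]),
        stage="merged",
        meta=meta,
    )


def _marginals(dense: np.ndarray) -> np.ndarray:
    # symmetric dense with diagonal stored once -> row sum counts it once
    return dense.sum(axis=1)


def ice_balance(
    m: ContactMatrix,
    low_cov_fraction: float = 0.02,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> tuple[ContactMatrix, BalancingResult]:
    """Iterative correction to equal marginals.

    Bins with zero marginal plus the lowest ``low_cov_fraction`` of the
    positive-marginal bins are masked (their entries removed).  Each
    round divides entries by the outer product of relative marginals and
    stops when every unmasked marginal is within ``tol`` of the mean.
    The result is rescaled so its total equals the input total, keeping
    "total interactions" meaningful for downstream mean-total scaling.
    """
    if m.stage not in ("raw", "merged"):
        raise ValueError(f"ice_balance requires raw or merged stage, got {m.stage!r}")
    n = m.grid.n_bins
    dense = m.to_dense()
    input_total = total_interactions(m)

    marg = _marginals(dense)
    masked = marg <= 0
    positive = np.flatnonzero(~masked)
    n_low = int(np.floor(low_cov_fraction * positive.size))
    if n_low > 0:
        order = positive[np.argsort(marg[positive], kind="stable")]
        masked[order[:n_low]] = True
    if masked.all():
        raise ValueError("all bins masked during balancing")
    dense[masked, :] = 0.0
    dense[:, masked] = 0.0
    unmasked = ~masked

    bias = np.ones(n, dtype=np.float64)
    converged = False
    iterations = 0
    spread = np.inf
    for _ in range(max_iter):
        marg = _marginals(dense)
        mean_marg = marg[unmasked].mean()
        if mean_marg <= 0:
            raise ValueError("all unmasked marginals vanished during balancing")
        rel = marg / mean_marg
        spread = float(np.abs(rel[unmasked] - 1.0).max())
        if spread <= tol:
            converged = True
            break
        ratio = np.where(unmasked, rel, 1.0)
        dense /= ratio[:, None]
        dense /= ratio[None, :]
        bias *= ratio
        iterations += 1
    else:
        marg = _marginals(dense)
        mean_marg = marg[unmasked].mean()
        spread = float(np.abs(marg[unmasked] / mean_marg - 1.0).max())
        converged = spread <= tol
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations "
            f"(marginal spread {spread:.3g})",
            RuntimeWarning,
        )

    # restore the original total
    current_total = (dense.sum() + np.trace(dense)) / 2.0
    if current_total > 0:
        dense *= input_total / current_total

    bias_out = np.where(unmasked, bias, np.nan)
    balanced = ContactMatrix.from_dense(
        m.grid, dense, stage="balanced", meta=m.meta,
        masked_bins=frozenset(int(b) for b in np.flatnonzero(masked)),
    )
    result = BalancingResult(
        bias=bias_out,
        masked_bins=balanced.masked_bins,
        iterations=iterations,
        converged=converged,
        final_marginal_spread=spread,
    )
    return balanced, result


def scale_to_mean_total(matrices: Sequence[ContactMatrix]) -> list[ContactMatrix]:
    """Scale each matrix to the mean total interactions across samples.

    Every within-matrix ratio is preserved exactly (one global factor
    per matrix); afterwards all totals equal the input mean.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    for m in matrices:
        if m.stage not in ("balanced", "merged"):
            raise ValueError(
                f"scale_to_mean_total requires balanced (or merged) matrices, "
                f"got {m.stage!r}"
            )
    totals = np.array([total_interactions(m) for m in matrices])
    if np.any(totals == 0):
        raise ValueError("cannot scale a zero-total matrix")
    mean_total = totals.mean()
    return [
        m.scaled_by(mean_total / t, stage="scaled") for m, t in zip(matrices, totals)
    ]


def subtract(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Entry-wise ``a - b`` over the union of supports (stage ``subtraction``)."""
    if a.grid != b.grid:
        raise ValueError("grid mismatch in subtract")
    if a.stage != "scaled" or b.stage != "scaled":
        raise ValueError(
            f"subtract requires scaled matrices, got {a.stage!r} and {b.stage!r}"
        )
    meta = SampleMeta(note=f"subtraction ({a.meta.state}) - ({b.meta.state})")
    return ContactMatrix.from_entries(
        a.grid,
        np.concatenate([a.bins1, b.bins1]),
        np.concatenate([a.bins2, b.bins2]),
        np.concatenate([a.values, -b.values]),
        stage="subtraction",
        meta=meta,
        masked_bins=a.masked_bins | b.masked_bins,
    )


def percentile_cap(m: ContactMatrix, q: float) -> ContactMatrix:
    """Cap values at the q-th percentile for display.

    Percentiles are taken over the non-zero stored values (sparse
    matrices are dominated by structural zeros, which would make a
    percentile over all cells degenerate).  For subtraction matrices the
    positive and negative values are capped symmetrically: positives at
    the q-th percentile of positives, negatives at minus the q-th
    percentile of their magnitudes.
    """
    if not 0 < q <= 100:
        raise ValueError(f"q must be in (0, 100], got {q}")
    if m.n_entries == 0:
        raise ValueError("cannot cap an empty matrix")
    vals = m.values.copy()
    if m.stage == "subtraction":
        pos = vals[vals > 0]
        neg = -vals[vals < 0]
        if pos.size:
            cap = np.percentile(pos, q)
            vals[vals > 0] = np.minimum(vals[vals > 0], cap)
        if neg.size:
            floor = np.percentile(neg, q)
            vals[vals < 0] = np.maximum(vals[vals < 0], -floor)
    else:
        nz = vals[vals != 0]
        cap = np.percentile(nz, q)
        vals = np.minimum(vals, cap)
    return ContactMatrix(
        m.grid, m.bins1, m.bins2, vals, m.stage, m.meta, m.masked_bins
    )
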