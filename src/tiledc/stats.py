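"""Statistical layer: count normalization, PCA ordination, a normality
gate, Kruskal-Wallis with tie correction, Dunn's post hoc z tests, and
Holm / Benjamini-Hochberg p-value adjustment.

Contact counts are heavily non-normal, so group comparisons are rank
based: the omnibus Kruskal-Wallis test (chi-square approximation with
midrank tie handling) followed by Dunn's pairwise z statistics on the
pooled ranks.  Post hoc tests are computed unconditionally but flagged
as unwarranted when the omnibus p is not significant.

Sample ordination uses median-of-ratios size factors (the DESeq2
convention) and log2(count/factor + 1) before principal components.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KWResult",
    "DunnResult",
    "PCAResult",
    "size_factors",
    "log_normalize",
    "pca",
    "normality_check",
    "kruskal_wallis",
    "dunn_test",
    "adjust_p",
]


# -- count normalization and ordination ---------------------------------------


def size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample column.

    Rows (matrix cells) containing any zero are excluded from the
    medians; at least one all-positive row is required.
    """
    values = table.to_numpy(dtype=np.float64)
    allpos = (values > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no row with all-positive values; cannot form size factors")
    sub = values[allpos]
    log_geomean = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=table.columns, name="size_factor")


def log_normalize(table: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1) per sample column."""
    if (factors <= 0).any():
        raise ValueError("size factors must be > 0")
    return np.log2(table.div(factors, axis="columns") + 1.0)


@dataclass
class PCAResult:
    """Sample coordinates and variance-explained fractions."""

    coordinates: pd.DataFrame  # samples x components
    explained: np.ndarray      # variance fractions, non-increasing
    loadings: np.ndarray       # rows x components


def pca(table: pd.DataFrame, top_n: int | None = None) -> PCAResult:
    """Principal components of samples over matrix-cell rows.

    Rows are centered internally; rows with zero variance (and, when
    ``top_n`` is given, all but the ``top_n`` most variable rows) are
    excluded.  Each component's sign is fixed so that its
    largest-magnitude loading is positive, making outputs deterministic.
    """
    if table.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = table.to_numpy(dtype=np.float64)
    row_var = x.var(axis=1)
    keep = row_var > 0
    if not keep.any():
        raise ValueError("constant table: no variable rows")
    if top_n is not None:
        order = np.argsort(row_var)[::-1]
        chosen = order[:top_n]
        keep = np.zeros_like(keep)
        keep[chosen] = row_var[chosen] > 0
    x = x[keep]
    x = x - x.mean(axis=1, keepdims=True)

    # samples are observations: SVD of the samples-by-rows matrix
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    n_comp = min(x.shape[0], x.shape[1])
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    loadings = vt.T  # rows x components
    for c in range(n_comp):
        peak = np.argmax(np.abs(loadings[:, c]))
        if loadings[peak, c] < 0:
            loadings[:, c] *= -1
            u[:, c] *= -1
    coords = u * s
    total_var = (x**2).sum()
    explained = (s**2) / total_var if total_var > 0 else np.zeros(n_comp)
    frame = pd.DataFrame(
        coords,
        index=table.columns,
        columns=[f"PC{c + 1}" for c in range(n_comp)],
    )
    return PCAResult(frame, explained, loadings)


# -- normality gate -----------------------------------------------------------


def normality_check(values: Sequence[float]) -> float:
    """Shapiro-Wilk p-value, used as a gate before rank-based tests."""
    v = np.asarray(values, dtype=np.float64)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={v.size}")
    if np.ptp(v) == 0:
        raise ValueError("constant input: normality is undefined")
    return float(sps.shapiro(v).pvalue)


# -- rank-based group tests ---------------------------------------------------


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis omnibus result."""

    H: float
    df: int
    p: float
    mean_ranks: dict[str, float]
    group_sizes: dict[str, int]
    n_total: int
    tie_term: float  # sum of t^3 - t over tied groups


@dataclass
class DunnResult:
    """Dunn's pairwise post hoc comparisons on pooled ranks."""

    table: pd.DataFrame  # columns: group_a, group_b, z, p, p_adj
    adjust: str
    posthoc_warranted: bool


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        items = list(groups.items())
    else:
        items = [(f"group{i + 1}", g) for i, g in enumerate(groups)]
    out = {}
    for name, g in items:
        arr = np.asarray(g, dtype=np.float64)
        if arr.size:
            out[str(name)] = arr
    return out


def _pooled_ranks(gdict: dict[str, np.ndarray]):
    pooled = np.concatenate(list(gdict.values()))
    ranks = sps.rankdata(pooled)  # midranks for ties
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    mean_ranks = {}
    start = 0
    for name, g in gdict.items():
        mean_ranks[name] = float(ranks[start:start + g.size].mean())
        start += g.size
    return n, tie_term, mean_ranks


def kruskal_wallis(groups) -> KWResult:
    """Kruskal-Wallis H test with midrank tie correction.

    ``groups`` is a mapping name -> values or a sequence of arrays.
    The fully tied degenerate case is defined as H = 0, p = 1.
    """
    gdict = _as_groups(groups)
    if len(gdict) < 2:
        raise ValueError("need at least 2 non-empty groups")
    n, tie_term, mean_ranks = _pooled_ranks(gdict)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    sizes = {name: int(g.size) for name, g in gdict.items()}
    df = len(gdict) - 1
    correction = 1.0 - tie_term / (n**3 - n)
    if correction <= 0:  # every observation tied
        return KWResult(0.0, df, 1.0, mean_ranks, sizes, n, tie_term)
    num = (12.0 / (n * (n + 1))) * sum(
        sizes[name] * (mean_ranks[name] - (n + 1) / 2.0) ** 2 for name in gdict
    )
    h = num / correction
    p = float(sps.chi2.sf(h, df))
    return KWResult(float(h), df, p, mean_ranks, sizes, n, tie_term)


def dunn_test(groups, adjust: str = "holm") -> DunnResult:
    """Dunn's z tests for all group pairs on the pooled ranks.

    z_ij = (rbar_i - rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]
    with two-sided normal p-values, adjusted across the k(k-1)/2 pairs.
    """
    if adjust not in ("holm", "bh", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    gdict = _as_groups(groups)
    if len(gdict) < 2:
        raise ValueError("need at least 2 non-empty groups")
    n, tie_term, mean_ranks = _pooled_ranks(gdict)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    sizes = {name: g.size for name, g in gdict.items()}
    var_term = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    kw = kruskal_wallis(gdict)
    rows = []
    for a, b in combinations(gdict, 2):
        if var_term <= 0:  # all observations tied
            z, p = 0.0, 1.0
        else:
            se = np.sqrt(var_term * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p": p})
    frame = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    if adjust == "none":
        frame["p_adj"] = frame["p"]
    else:
        frame["p_adj"] = adjust_p(frame["p"].tolist(), method=adjust)
    return DunnResult(frame, adjust, posthoc_warranted=kw.p < 0.05)


def adjust_p(ps: Sequence[float], method: str) -> list[float]:
    """Holm (step-down) or Benjamini-Hochberg (step-up) adjustment.

    Input order is preserved; adjusted values are monotone and capped
    at 1.
    """
    p = np.asarray(ps, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    adj = np.empty(m, dtype=np.float64)
    if method == "holm":
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
    elif method == "bh":
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, m / (rank + 1) * p[idx])
            adj[idx] = min(1.0, running)
    else:
        raise ValueError(f"unknown method {method!r}")
    return adj.tolist()
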