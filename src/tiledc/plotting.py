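"""Triangular contact-map rendering.

Contact matrices are drawn as 45-degree-rotated triangles (genomic axis
horizontal, interaction distance vertical), capped at a display
percentile.  Subtraction matrices use a diverging palette with
symmetric color limits.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering

import matplotlib.pyplot as plt
import numpy as np

from .matrix import ContactMatrix, percentile_cap

__all__ = ["render_matrix"]


def render_matrix(
    m: ContactMatrix,
    q: float,
    path: str | Path,
    max_distance_bins: int | None = None,
) -> Path:
    """Render a rotated-triangle heatmap capped at percentile ``q``.

    ``max_distance_bins`` limits the plotted interaction distance; by
    default the full triangle is drawn.
    """
    capped = percentile_cap(m, q)
    i, j, v = capped.bins1, capped.bins2, capped.values
    if max_distance_bins is not None:
        keep = (j - i) <= max_distance_bins
        i, j, v = i[keep], j[keep], v[keep]

    # rotate: x = midpoint along the genome, y = half the distance
    x = (i + j) / 2.0
    y = (j - i) / 2.0

    fig, ax = plt.subplots(figsize=(8, 3.2))
    if m.stage == "subtraction":
        lim = float(np.abs(v).max()) if v.size else 1.0
        sc = ax.scatter(x, y, c=v, s=2, marker="s", cmap="RdBu_r",
                        vmin=-lim, vmax=lim, linewidths=0)
        label = "subtracted interactions"
    else:
        sc = ax.scatter(x, y, c=v, s=2, marker="s", cmap="Reds",
                        vmin=0, linewidths=0)
        label = "interactions"
    ax.set_xlim(0, m.grid.n_bins)
    ax.set_ylim(0, (max_distance_bins or m.grid.n_bins) / 2.0)
    ax.set_xlabel(f"{m.grid.chrom} bin ({m.grid.bin_size} bp)")
    ax.set_ylabel("distance / 2 (bins)")
    title = f"{m.stage}"
    if m.meta.state:
        title += f" | {m.meta.state}"
    ax.set_title(f"{title} (cap: {q:g}th percentile)")
    fig.colorbar(sc, ax=ax, label=label, shrink=0.8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
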