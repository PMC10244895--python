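"""Figure writers: normalized Tresca color maps and principal-stress tensor
glyph plots.

Color scales are fixed to ``[0, reference_max]`` so simulations of different
models share one scale and can be compared directly; values above the
reference maximum are clipped and flagged in the caption.  Tensor glyphs
draw, per (subsampled) element, an arrow pair along each principal
direction: blue for the maximum principal stress, green for the minimum,
arrowheads pointing outward for tension and inward for compression, length
proportional to the normalized magnitude.

Figures carry no numbers that tests assert on; the numeric layer behind each
figure (per-element colors, per-glyph vectors) is exported as a CSV sidecar.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import matplotlib.tri as mtri
import numpy as np
import pandas as pd

from .fem import StressField
from .meshing import Mesh

logger = logging.getLogger(__name__)


def render_colormap(field: StressField, mesh: Mesh, reference_max: float,
                    path: str, title: str = "") -> Path:
    """Tresca color map with the scale fixed to [0, reference_max] MPa."""
    if reference_max <= 0:
        raise ValueError("reference_max must be positive")
    path = Path(path)
    vals = np.minimum(field.tresca, reference_max)
    n_clipped = int((field.tresca > reference_max).sum())
    tri = mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1],
                             mesh.elements[:, :3])
    fig, ax = plt.subplots(figsize=(5, 5))
    tpc = ax.tripcolor(tri, facecolors=vals, vmin=0.0, vmax=reference_max,
                       cmap="viridis")
    fig.colorbar(tpc, ax=ax, label="Tresca equivalent stress (MPa)")
    caption = title or "Tresca color map"
    if n_clipped:
        caption += f" ({n_clipped} elements above the reference maximum, clipped)"
    ax.set_title(caption, fontsize=9)
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    pd.DataFrame({"element_id": np.arange(1, len(vals) + 1),
                  "tresca": field.tresca, "color_value": vals,
                  "clipped": field.tresca > reference_max}).to_csv(
        path.with_suffix(".csv"), index=False)
    return path


def render_tensor_plot(field: StressField, mesh: Mesh, path: str,
                       subsample: int = 50, title: str = "") -> Path:
    """Principal-stress glyph plot on a subsample of ``subsample`` elements.

    Elements are picked deterministically (evenly spaced by element index).
    """
    path = Path(path)
    ne = mesh.n_elements
    take = np.linspace(0, ne - 1, min(subsample, ne)).astype(int)
    take = np.unique(take)
    cent = mesh.element_centroids()
    scale_ref = np.abs(np.concatenate([field.sigma1, field.sigma2])).max() or 1.0
    glyph_len = 0.8 * np.sqrt(mesh.element_areas().mean())

    rows = []
    fig, ax = plt.subplots(figsize=(5, 5))
    for e in take:
        ang = field.principal_angle[e]
        for which, s, color in (("sigma1", field.sigma1[e], "tab:blue"),
                                ("sigma2", field.sigma2[e], "tab:green")):
            a = ang if which == "sigma1" else ang + np.pi / 2
            d = np.array([np.cos(a), np.sin(a)])
            mag = abs(s) / scale_ref
            tip = glyph_len * mag * d
            # tension: arrowheads outward (pivot tail); compression: inward
            pivot = "tail" if s >= 0 else "tip"
            ax.quiver(*np.repeat(cent[e][None, :], 2, axis=0).T,
                      *(np.array([tip, -tip]).T), color=color, pivot=pivot,
                      angles="xy", scale_units="xy", scale=1.0, width=0.003)
            rows.append({"element_id": int(e + 1), "which": which,
                         "cx": cent[e][0], "cy": cent[e][1],
                         "dir_x": d[0], "dir_y": d[1], "stress": s,
                         "normalized_magnitude": mag,
                         "sense": "tension" if s >= 0 else "compression"})
    ax.triplot(mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1],
                                  mesh.elements[:, :3]),
               color="0.85", lw=0.3, zorder=0)
    ax.set_title(title or "Principal stress tensor plot", fontsize=9)
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)
    return path
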