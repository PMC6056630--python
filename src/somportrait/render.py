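"""PNG rendering of portraits, variance maps, segmentations, and the
prognostic map.  Presentation only — never used in correctness checks."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .prognosis import PrognosticMap
from .spots import SpotSegmentation

__all__ = ["render_portrait", "render_variance_map", "render_segmentation", "render_prognostic_map"]


def _save(fig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def render_portrait(portrait: np.ndarray, path, title: str = "") -> None:
    """Symmetric diverging color scale: maroon = high, blue = low."""
    lim = max(float(np.abs(portrait).max()), 1e-12)
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    im = ax.imshow(portrait, cmap="RdBu_r", vmin=-lim, vmax=lim, interpolation="nearest")
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8)
    _save(fig, path)


def render_variance_map(vmap: np.ndarray, path, title: str = "expression variance") -> None:
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    im = ax.imshow(vmap, cmap="YlOrBr", interpolation="nearest")
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8)
    _save(fig, path)


def render_segmentation(vmap: np.ndarray, seg: SpotSegmentation, path) -> None:
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.imshow(vmap, cmap="YlOrBr", interpolation="nearest")
    lab = seg.label_map()
    ax.contour(lab > 0, levels=[0.5], colors="k", linewidths=0.8)
    for s in seg:
        rr = np.mean([p[0] for p in s.pixels])
        cc = np.mean([p[1] for p in s.pixels])
        ax.text(cc, rr, s.label, ha="center", va="center", fontsize=8, color="navy")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("spot segmentation", fontsize=9)
    _save(fig, path)


def render_prognostic_map(pmap: PrognosticMap, path) -> None:
    """Masked metagenes (insufficient support) render white."""
    data = np.ma.masked_invalid(pmap.survivor_pct)
    cmap = matplotlib.colormaps["RdYlGn"].copy()
    cmap.set_bad("white")
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    im = ax.imshow(data, cmap=cmap, vmin=0, vmax=100, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("28-day survivor % by metagene", fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    _save(fig, path)
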