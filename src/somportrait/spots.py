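"""Spot-module segmentation of the metagene map.

Spots are connected regions of high expression variance on the SOM; the
genes whose BMU falls inside a spot form a module of co-expressed genes.
Segmentation thresholds the variance map at a percentile and takes
8-connected components; optionally, components are further split along
U-matrix ridges (large codebook distance between neighboring pixels marks
a border between distinct co-expression clusters that happen to touch on
the grid).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .som import SOMModel, umatrix

__all__ = [
    "Spot",
    "SpotSegmentation",
    "segment_spots",
    "sample_spot_activation",
    "spot_expression_profile",
    "spot_frequency_distribution",
]

_STRUCTURE8 = np.ones((3, 3), dtype=int)


def _spot_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... in order."""
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        if i < 26:
            out.append(letters[i])
        else:
            out.append(letters[i // 26 - 1] + letters[i % 26])
    return out


@dataclass
class Spot:
    label: str
    pixels: list[tuple[int, int]]
    genes: list[str]
    total_variance: float


@dataclass
class SpotSegmentation:
    spots: list[Spot]
    rows: int
    cols: int
    percentile: float
    split_umap: bool
    umap_h_rel: float = 0.25

    def __iter__(self):
        return iter(self.spots)

    def __len__(self) -> int:
        return len(self.spots)

    def __getitem__(self, label: str) -> Spot:
        for s in self.spots:
            if s.label == label:
                return s
        raise KeyError(f"no spot labeled {label!r}")

    def labels(self) -> list[str]:
        return [s.label for s in self.spots]

    def label_map(self) -> np.ndarray:
        """Integer map: 0 = background, i = spot self.spots[i-1]."""
        lab = np.zeros((self.rows, self.cols), dtype=int)
        for i, s in enumerate(self.spots, start=1):
            for r, c in s.pixels:
                lab[r, c] = i
        return lab

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [s.label for s in self.spots],
                "n_pixels": [len(s.pixels) for s in self.spots],
                "n_genes": [len(s.genes) for s in self.spots],
                "total_variance": [s.total_variance for s in self.spots],
                "pixels": [";".join(f"{r},{c}" for r, c in s.pixels) for s in self.spots],
                "genes": [";".join(s.genes) for s in self.spots],
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, rows: int, cols: int,
        percentile: float = float("nan"), split_umap: bool = False,
    ) -> "SpotSegmentation":
        spots = []
        for _, row in frame.iterrows():
            pixels = [
                tuple(int(x) for x in p.split(","))
                for p in str(row["pixels"]).split(";")
                if p
            ]
            genes = [g for g in str(row.get("genes", "")).split(";") if g]
            spots.append(
                Spot(
                    label=str(row["label"]),
                    pixels=pixels,
                    genes=genes,
                    total_variance=float(row.get("total_variance", 0.0)),
                )
            )
        return cls(spots=spots, rows=rows, cols=cols, percentile=percentile, split_umap=split_umap)


def _watershed_split(component: np.ndarray, vmap: np.ndarray, u: np.ndarray, h_rel: float) -> np.ndarray:
    """Split one boolean component along U-matrix ridges.

    Markers are the h-maxima of the variance map inside the component
    (prominence >= h_rel * component variance range); the component is then
    partitioned by watershed on the U-matrix, so basin borders coincide
    with ridges of large neighboring-codebook distance.  Returns an integer
    label image over the component (0 outside).
    """
    from skimage.morphology import h_maxima
    from skimage.segmentation import watershed

    # prominence on the log scale: modules differ in variance by orders of
    # magnitude, so a marker must stand a fixed *factor* above its
    # surrounding dip rather than a fixed fraction of the component range
    floor = vmap[component].min()
    logv = np.where(component, np.log(np.maximum(vmap, floor * 1e-3) + 1e-12), -np.inf)
    finite_min = logv[component].min()
    logv = np.where(component, logv, finite_min - 10.0)
    peaks = h_maxima(logv, h_rel) & component
    markers, n_markers = ndimage.label(peaks, structure=_STRUCTURE8)
    if n_markers <= 1:
        lab, _ = ndimage.label(component, structure=_STRUCTURE8)
        return lab
    return watershed(np.where(component, u, u.max() + 1.0), markers=markers, mask=component)


def segment_spots(
    model: SOMModel,
    vmap: np.ndarray,
    percentile: float = 90.0,
    split_umap: bool = False,
    umap_h_rel: float = 0.25,
) -> SpotSegmentation:
    """Segment the variance map into spot modules.

    Pixels with variance strictly above the given percentile of the map
    form the candidate region (strict, so a flat background tied with the
    threshold never floods the map); its 8-connected components become
    spots, optionally split along U-matrix ridges.  Spot labels are letters
    in descending order of total spot variance.  Member genes are the genes
    whose BMU pixel lies in the spot.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie in (0, 100)")
    vmap = np.asarray(vmap, dtype=float)
    if vmap.shape != (model.rows, model.cols):
        raise ValueError("variance map shape does not match model grid")
    threshold = np.percentile(vmap, percentile)
    mask = vmap > threshold
    labeled, n_comp = ndimage.label(mask, structure=_STRUCTURE8)

    if split_umap and n_comp > 0:
        u = umatrix(model)
        out = np.zeros_like(labeled)
        nxt = 1
        for i in range(1, n_comp + 1):
            comp = labeled == i
            sub = _watershed_split(comp, vmap, u, umap_h_rel)
            for s in np.unique(sub[sub > 0]):
                out[sub == s] = nxt
                nxt += 1
        labeled, n_comp = out, nxt - 1

    gene_ids = np.asarray(model.gene_ids)
    bmu_rc = np.column_stack(np.unravel_index(model.bmu, (model.rows, model.cols)))
    bmu_comp = labeled[bmu_rc[:, 0], bmu_rc[:, 1]]

    spots = []
    for i in range(1, n_comp + 1):
        pix = [tuple(p) for p in np.argwhere(labeled == i)]
        genes = list(gene_ids[bmu_comp == i])
        tv = float(vmap[labeled == i].sum())
        spots.append(Spot(label="", pixels=pix, genes=genes, total_variance=tv))
    spots.sort(key=lambda s: -s.total_variance)
    for s, lab in zip(spots, _spot_labels(len(spots))):
        s.label = lab
    return SpotSegmentation(
        spots=spots,
        rows=model.rows,
        cols=model.cols,
        percentile=percentile,
        split_umap=split_umap,
        umap_h_rel=umap_h_rel,
    )


def sample_spot_activation(portrait: np.ndarray, seg: SpotSegmentation, q: float = 0.98) -> set[str]:
    """Spots over-expressed in one sample portrait.

    A spot is *active* iff the mean portrait value over its pixels strictly
    exceeds the q-quantile of the whole portrait and is positive.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    if len(seg) == 0:
        raise ValueError("empty segmentation")
    portrait = np.asarray(portrait, dtype=float)
    cutoff = np.quantile(portrait, q)
    active = set()
    for s in seg:
        vals = [portrait[r, c] for r, c in s.pixels]
        mu = float(np.mean(vals))
        if mu > cutoff and mu > 0:
            active.add(s.label)
    return active


def spot_expression_profile(seg: SpotSegmentation, label: str, m: pd.DataFrame) -> pd.Series:
    """Per-sample mean expression of a spot's member genes."""
    spot = seg[label]
    if not spot.genes:
        raise ValueError(f"spot {label!r} has no member genes")
    missing = [g for g in spot.genes if g not in m.index]
    if missing:
        raise KeyError(f"spot genes absent from matrix: {missing[:5]}")
    profile = m.loc[spot.genes].mean(axis=0)
    profile.name = f"spot_{label}"
    return profile


def spot_frequency_distribution(
    portraits: dict[str, np.ndarray],
    seg: SpotSegmentation,
    q: float = 0.98,
    groups: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Active-spot counts per sample and their histogram per group.

    Returns ``(counts, histogram)`` where ``counts`` maps sample -> number
    of active spots and ``histogram`` has one row per group and one column
    per observed count (cells sum to the number of samples).
    """
    counts = pd.Series(
        {sid: len(sample_spot_activation(p, seg, q)) for sid, p in portraits.items()},
        name="n_active_spots",
    )
    if groups is None:
        groups = pd.Series("all", index=counts.index)
    groups = groups.reindex(counts.index)
    hist = (
        pd.crosstab(groups, counts)
        .reindex(columns=range(0, int(counts.max()) + 1), fill_value=0)
    )
    hist.index.name = "group"
    hist.columns.name = "n_active_spots"
    return counts, hist
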