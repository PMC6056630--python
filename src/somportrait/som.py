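"""Metagene self-organizing map and expression portraits.

Genes are data points in sample space; the SOM codebook vectors are
*metagenes*, consensus expression profiles over the samples.  A sample's
*portrait* is its column of the codebook arranged on the 2-D grid: a compact
image of that sample's transcriptome state in which connected regions of
co-varying metagenes ("spots") stand out.

Training is batch SOM: every epoch all genes are assigned to their best
matching unit (BMU, Euclidean distance), then every codebook vector is
replaced by the neighborhood-weighted mean of the gene profiles.  Batch
training is deterministic given the initialization, which is linear along
the first two principal directions of the gene cloud; the seed only enters
through a random fallback used when the data are too degenerate for PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SOMModel",
    "train_som",
    "sample_portrait",
    "group_mean_portrait",
    "difference_portrait",
    "variance_map",
    "umatrix",
    "som_energy",
    "batch_epoch",
]


@dataclass
class SOMModel:
    """Trained metagene SOM.

    Attributes
    ----------
    rows, cols:
        Grid dimensions; the map has ``rows * cols`` metagenes.  Grid
        coordinates are 0-based and row-major throughout.
    codebook:
        Array of shape ``(rows * cols, n_samples)``; row k is metagene k's
        profile over the samples.
    bmu:
        Array of shape ``(n_genes,)``; flat (row-major) metagene index of
        each gene's best matching unit.
    gene_ids, sample_ids:
        Identifier lists matching ``bmu`` and the codebook columns.
    """

    rows: int
    cols: int
    codebook: np.ndarray
    bmu: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    epochs: int = 0
    seed: int = 0
    radius_schedule: list[float] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def grid(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _neighborhood(rows: int, cols: int, sigma: float) -> np.ndarray:
    """Gaussian neighborhood matrix H[k, l] over grid Euclidean distance."""
    g = _grid_coords(rows, cols)
    d2 = ((g[:, None, :] - g[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sigma * sigma))


def _bmu_assign(x: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Nearest codebook row for each row of x (squared Euclidean)."""
    # ||x - c||^2 = ||x||^2 + ||c||^2 - 2 x.c ; the ||x||^2 term is constant per gene
    cross = x @ codebook.T
    c2 = (codebook**2).sum(axis=1)
    return np.argmin(c2[None, :] - 2.0 * cross, axis=1)


def som_energy(x: np.ndarray, codebook: np.ndarray, h: np.ndarray, bmu: np.ndarray) -> float:
    """Batch-SOM energy: sum_j sum_k H[bmu_j, k] ||x_j - c_k||^2."""
    d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return float((h[bmu, :] * d2).sum())


def batch_epoch(x: np.ndarray, codebook: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One batch-SOM epoch at a fixed neighborhood: BMU assignment followed
    by the neighborhood-weighted mean update.  Nodes with negligible
    neighborhood mass keep their codebook vector.  Returns (new codebook,
    bmu used for the update)."""
    n_nodes = codebook.shape[0]
    bmu = _bmu_assign(x, codebook)
    counts = np.bincount(bmu, minlength=n_nodes).astype(float)
    sums = np.zeros_like(codebook)
    np.add.at(sums, bmu, x)
    num = h @ sums
    den = h @ counts
    new = codebook.copy()
    nonzero = den > 1e-12
    new[nonzero] = num[nonzero] / den[nonzero, None]
    return new, bmu


def _linear_init(x: np.ndarray, rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """PCA-plane initialization of the codebook (deterministic for full-rank data)."""
    n_samples = x.shape[1]
    mean = x.mean(axis=0)
    xc = x - mean
    try:
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover - extremely rare
        s = np.zeros(min(xc.shape))
        vt = np.zeros((min(xc.shape), n_samples))
    g = _grid_coords(rows, cols)
    # grid axes scaled to [-1, 1]
    span = np.maximum(np.array([rows - 1, cols - 1], dtype=float), 1.0)
    a = 2.0 * g[:, 0] / span[0] - (1.0 if rows > 1 else 0.0)
    b = 2.0 * g[:, 1] / span[1] - (1.0 if cols > 1 else 0.0)
    scale = s / max(np.sqrt(x.shape[0]), 1.0)
    codebook = np.tile(mean, (rows * cols, 1))
    directions = []
    for comp in range(min(2, vt.shape[0])):
        v = vt[comp]
        # deterministic sign: largest-magnitude entry positive
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        directions.append(scale[comp] * v)
    if directions and scale[0] > 1e-12:
        codebook = codebook + np.outer(a, directions[0])
        if len(directions) > 1 and scale[1] > 1e-12:
            codebook = codebook + np.outer(b, directions[1])
    else:
        # degenerate cloud (e.g. all genes identical): tiny random jitter
        codebook = codebook + 1e-6 * rng.standard_normal(codebook.shape)
    return codebook


def train_som(
    m: pd.DataFrame,
    grid: tuple[int, int] = (50, 50),
    epochs: int = 30,
    seed: int = 0,
    radius_final: float = 0.5,
) -> SOMModel:
    """Train a batch SOM of metagenes on a preprocessed expression matrix.

    The neighborhood radius decays linearly from ``max(rows, cols) / 2`` to
    ``radius_final`` over the epochs.  Empty metagenes (nodes attracting no
    genes and negligible neighborhood mass) keep their previous codebook
    vector.

    Parameters
    ----------
    m:
        Genes x samples DataFrame (centralized expression).
    grid:
        (rows, cols) of the metagene map; ``rows * cols`` may exceed the
        gene count (empty metagenes are allowed).
    """
    rows, cols = int(grid[0]), int(grid[1])
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    x = m.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in expression matrix")
    n_genes, n_samples = x.shape
    n_nodes = rows * cols
    rng = np.random.default_rng(seed)

    codebook = _linear_init(x, rows, cols, rng)
    r0 = max(rows, cols) / 2.0
    if epochs == 1:
        radii = [radius_final]
    else:
        radii = list(np.linspace(r0, radius_final, epochs))

    for sigma in radii:
        h = _neighborhood(rows, cols, sigma)
        codebook, _ = batch_epoch(x, codebook, h)
    bmu = _bmu_assign(x, codebook)

    return SOMModel(
        rows=rows,
        cols=cols,
        codebook=codebook,
        bmu=bmu,
        gene_ids=list(map(str, m.index)),
        sample_ids=list(map(str, m.columns)),
        epochs=epochs,
        seed=seed,
        radius_schedule=[float(r) for r in radii],
    )


def sample_portrait(model: SOMModel, sample_id: str) -> np.ndarray:
    """The sample's codebook column arranged on the grid (rows x cols)."""
    j = model.sample_index(sample_id)
    return model.codebook[:, j].reshape(model.rows, model.cols).copy()


def group_mean_portrait(model: SOMModel, sample_ids) -> np.ndarray:
    """Entrywise mean of the member samples' portraits."""
    ids = list(sample_ids)
    if not ids:
        raise ValueError("empty sample id list")
    idx = [model.sample_index(s) for s in ids]
    return model.codebook[:, idx].mean(axis=1).reshape(model.rows, model.cols)


def difference_portrait(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Entrywise difference a - b of two portraits on the same grid."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"portrait shapes differ: {a.shape} vs {b.shape}")
    return a - b


def variance_map(model: SOMModel) -> np.ndarray:
    """Per-metagene variance of codebook values across samples (ddof=1)."""
    if model.codebook.shape[1] < 2:
        raise ValueError("variance map needs >= 2 samples")
    return model.codebook.var(axis=1, ddof=1).reshape(model.rows, model.cols)


def umatrix(model: SOMModel) -> np.ndarray:
    """U-matrix: per pixel, mean Euclidean distance of its codebook vector
    to the codebook vectors of its 8-neighborhood grid neighbors."""
    rows, cols = model.rows, model.cols
    cb = model.codebook.reshape(rows, cols, -1)
    u = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            dists = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        dists.append(np.linalg.norm(cb[r, c] - cb[rr, cc]))
            u[r, c] = np.mean(dists) if dists else 0.0
    return u
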