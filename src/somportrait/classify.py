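"""Class discovery on sample portraits.

Samples are compared by the Pearson correlation of their metagene portraits.
Discovery seeds class labels with k-means on the rows of the correlation
matrix, then maximizes a correlation silhouette score S by iteratively
moving misfit samples:

    S_i = r(i, own centroid) - max_{c != own} r(i, centroid_c)

where a centroid is the mean portrait of a class and r is Pearson
correlation between portrait vectors.  S_i > 0 means sample i best fits its
own class.  Each refinement iteration moves every negative-S sample to its
best-matching class at once; a batch of moves that would lower the mean S
is rolled back and refinement stops, which makes the mean S non-decreasing
over iterations and guarantees termination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .som import SOMModel

__all__ = [
    "ClassAssignment",
    "portrait_correlation_matrix",
    "discover_classes",
    "silhouette_scores",
    "bootstrap_stability",
    "correlation_network",
]

logger = logging.getLogger(__name__)


@dataclass
class ClassAssignment:
    labels: pd.Series  # sample id -> class index (0..K-1)
    silhouette: pd.Series  # sample id -> S
    centroids: np.ndarray  # K x n_metagenes mean portraits
    k: int
    iterations: int
    seed: int
    stability_pct: float | None = None
    events: list[str] = field(default_factory=list)
    mean_s_trace: list[float] = field(default_factory=list)

    def class_members(self, c: int) -> list[str]:
        return list(self.labels.index[self.labels == c])


def _portraits_matrix(model: SOMModel, sample_ids=None) -> tuple[np.ndarray, list[str]]:
    if sample_ids is None:
        ids = list(model.sample_ids)
        return model.codebook.T.copy(), ids
    ids = list(sample_ids)
    idx = [model.sample_index(s) for s in ids]
    return model.codebook[:, idx].T.copy(), ids


def portrait_correlation_matrix(model: SOMModel, sample_ids=None) -> pd.DataFrame:
    """Pearson correlations of all pairwise combinations of sample portraits."""
    p, ids = _portraits_matrix(model, sample_ids)
    if p.shape[0] < 2:
        raise ValueError("need >= 2 samples for a correlation matrix")
    r = np.corrcoef(p)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ids, columns=ids)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of a and every row of b."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(az, axis=1)
    bn = np.linalg.norm(bz, axis=1)
    denom = np.outer(an, bn)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / denom
    return np.where(denom > 0, r, 0.0)


def _lloyd(x: np.ndarray, centers: list[int], k: int, max_iter: int) -> tuple[np.ndarray, float]:
    c = x[centers].copy()
    n = x.shape[0]
    labels = np.full(n, -1, dtype=int)
    for _it in range(max_iter):
        dist = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist.argmin(axis=1)
        for j in range(k):  # keep emptied clusters alive on their worst fit
            if not (new_labels == j).any():
                worst = int(dist[np.arange(n), new_labels].argmax())
                new_labels[worst] = j
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            c[j] = x[labels == j].mean(axis=0)
    dist = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    inertia = float(dist[np.arange(n), labels].sum())
    return labels, inertia


def _kmeans_furthest_first(
    x: np.ndarray, k: int, seed: int, max_iter: int = 100, n_init: int = 20
) -> np.ndarray:
    """Deterministic Lloyd k-means, furthest-first seeding, multiple
    restarts (different random first centers), best inertia kept."""
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _rep in range(n_init):
        centers = [int(rng.integers(n))]
        d2 = ((x - x[centers[0]]) ** 2).sum(axis=1)
        for _ in range(1, k):
            nxt = int(np.argmax(d2))
            centers.append(nxt)
            d2 = np.minimum(d2, ((x - x[nxt]) ** 2).sum(axis=1))
        labels, inertia = _lloyd(x, centers, k, max_iter)
        if inertia < best_inertia:
            best_labels, best_inertia = labels, inertia
    return best_labels


def _class_centroids(p: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    cents = np.zeros((k, p.shape[1]))
    for c in range(k):
        members = labels == c
        if members.any():
            cents[c] = p[members].mean(axis=0)
    return cents


def _s_scores(p: np.ndarray, labels: np.ndarray, cents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample S and each sample's best class by centroid correlation."""
    r = _rowwise_pearson(p, cents)
    k = cents.shape[0]
    own = r[np.arange(len(labels)), labels]
    masked = r.copy()
    masked[np.arange(len(labels)), labels] = -np.inf
    best_other = masked.max(axis=1)
    s = own - best_other
    best = r.argmax(axis=1)  # ties -> lowest class index (argmax convention)
    return s, best


def discover_classes(
    r: pd.DataFrame,
    model: SOMModel,
    k: int = 6,
    seed: int = 0,
    sample_ids=None,
    max_iter: int = 100,
) -> ClassAssignment:
    """K-means seeding on the correlation-matrix rows followed by iterative
    silhouette maximization.

    Parameters
    ----------
    r:
        Pairwise portrait correlation matrix (as from
        :func:`portrait_correlation_matrix`); its index defines the sample
        set unless ``sample_ids`` narrows it.
    model:
        Trained SOM providing the portraits for centroid computation.
    """
    ids = list(sample_ids) if sample_ids is not None else list(r.index)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds sample count {len(ids)}")
    rmat = r.loc[ids, ids].to_numpy(dtype=float)
    p, ids = _portraits_matrix(model, ids)
    events: list[str] = []

    labels = _kmeans_furthest_first(rmat, k, seed)
    cents = _class_centroids(p, labels, k)
    s, best = _s_scores(p, labels, cents)
    trace = [float(s.mean())]
    iterations = 0
    for iterations in range(1, max_iter + 1):
        movers = np.flatnonzero(s < 0)
        movers = movers[best[movers] != labels[movers]]
        if movers.size == 0:
            break
        prev_labels = labels.copy()
        prev_mean = s.mean()
        labels = labels.copy()
        labels[movers] = best[movers]
        # restart any emptied class on the worst-fitting sample
        for c in range(k):
            if not (labels == c).any():
                worst = int(np.argmin(s))
                labels[worst] = c
                events.append(f"iteration {iterations}: class {c} emptied; restarted on sample {ids[worst]}")
                logger.info(events[-1])
        cents = _class_centroids(p, labels, k)
        s_new, best_new = _s_scores(p, labels, cents)
        if s_new.mean() < prev_mean:
            # batch overshoot: retry with only the single worst-fitting mover
            labels = prev_labels.copy()
            worst = movers[np.argmin(s[movers])]
            labels[worst] = best[worst]
            for c in range(k):
                if not (labels == c).any():
                    labels[int(np.argmin(s))] = c
            cents = _class_centroids(p, labels, k)
            s_new, best_new = _s_scores(p, labels, cents)
            if s_new.mean() < prev_mean:
                labels = prev_labels
                cents = _class_centroids(p, labels, k)
                s, best = _s_scores(p, labels, cents)
                events.append(
                    f"iteration {iterations}: moves lowered mean S; reverted and stopped"
                )
                break
        s, best = s_new, best_new
        trace.append(float(s.mean()))
    return ClassAssignment(
        labels=pd.Series(labels, index=ids, name="class"),
        silhouette=pd.Series(s, index=ids, name="S"),
        centroids=cents,
        k=k,
        iterations=iterations,
        seed=seed,
        events=events,
        mean_s_trace=trace,
    )


def silhouette_scores(
    model: SOMModel,
    labels: pd.Series,
    centroids: np.ndarray | None = None,
    sample_ids=None,
) -> pd.Series:
    """Correlation silhouette S for given labels.

    S_i = r(i, own centroid) - max over other classes of r(i, their
    centroid); centroids default to the class-mean portraits implied by the
    labels.
    """
    ids = list(sample_ids) if sample_ids is not None else list(labels.index)
    p, ids = _portraits_matrix(model, ids)
    lab = labels.loc[ids].to_numpy()
    classes = np.unique(lab)
    if len(classes) < 2:
        raise ValueError("silhouette needs >= 2 classes")
    remap = {c: i for i, c in enumerate(classes)}
    lab_idx = np.array([remap[c] for c in lab])
    if centroids is None:
        centroids = _class_centroids(p, lab_idx, len(classes))
    s, _ = _s_scores(p, lab_idx, centroids)
    return pd.Series(s, index=ids, name="S")


def _match_classes(cents_a: np.ndarray, cents_b: np.ndarray) -> dict[int, int]:
    """Greedy one-to-one matching of class centroids by maximal correlation."""
    r = _rowwise_pearson(cents_a, cents_b)
    pairs = sorted(
        ((r[i, j], i, j) for i in range(r.shape[0]) for j in range(r.shape[1])),
        key=lambda t: -t[0],
    )
    used_a, used_b, mapping = set(), set(), {}
    for _, i, j in pairs:
        if i not in used_a and j not in used_b:
            mapping[i] = j
            used_a.add(i)
            used_b.add(j)
    return mapping


def bootstrap_stability(
    model: SOMModel,
    k: int = 6,
    b: int = 100,
    seed: int = 0,
    sample_ids=None,
    r: pd.DataFrame | None = None,
) -> float:
    """Mean percentage of samples keeping their class label under
    bootstrap resampling of the sample set.

    Each replicate redraws samples with replacement, re-runs class
    discovery, matches replicate classes to the reference classes by
    maximal centroid correlation (one-to-one, greedy), and scores the
    fraction of in-bag samples whose matched label equals their reference
    label.
    """
    if b < 2:
        raise ValueError("b must be >= 2")
    ids = list(sample_ids) if sample_ids is not None else list(model.sample_ids)
    if r is None:
        r = portrait_correlation_matrix(model, ids)
    reference = discover_classes(r, model, k=k, seed=seed, sample_ids=ids)
    rng = np.random.default_rng(seed)
    fractions = []
    for rep in range(b):
        draw = rng.integers(0, len(ids), size=len(ids))
        in_bag = sorted(set(draw))
        bag_ids = [ids[i] for i in in_bag]
        if len(bag_ids) < k:
            logger.warning("bootstrap replicate %d skipped: only %d unique samples", rep, len(bag_ids))
            continue
        rep_seed = int(rng.integers(0, 2**31 - 1))
        try:
            repl = discover_classes(r, model, k=k, seed=rep_seed, sample_ids=bag_ids)
        except ValueError:
            logger.warning("bootstrap replicate %d skipped", rep)
            continue
        mapping = _match_classes(repl.centroids, reference.centroids)
        matched = [
            mapping.get(repl.labels[sid], -1) == reference.labels[sid] for sid in bag_ids
        ]
        fractions.append(np.mean(matched))
    if not fractions:
        raise ValueError("no valid bootstrap replicates")
    return float(np.mean(fractions) * 100.0)


def correlation_network(r: pd.DataFrame, rule: str = "threshold", param: float = 0.5) -> nx.Graph:
    """Sample similarity network from the portrait correlation matrix.

    ``rule="threshold"``: edge (i, j) iff r_ij >= param.
    ``rule="knn"``: j among i's ``param`` nearest neighbors by r, edges
    symmetrized by union.
    """
    ids = list(r.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    rm = r.to_numpy(dtype=float)
    n = len(ids)
    if rule == "threshold":
        for i in range(n):
            for j in range(i + 1, n):
                if rm[i, j] >= param:
                    g.add_edge(ids[i], ids[j], weight=float(rm[i, j]))
    elif rule == "knn":
        kk = int(param)
        if kk < 1:
            raise ValueError("knn parameter must be >= 1")
        for i in range(n):
            others = [j for j in range(n) if j != i]
            nearest = sorted(others, key=lambda j: -rm[i, j])[:kk]
            for j in nearest:
                g.add_edge(ids[i], ids[j], weight=float(rm[i, j]))
    else:
        raise ValueError(f"unknown rule: {rule!r}")
    return g
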