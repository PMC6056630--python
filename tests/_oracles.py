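"""Independent reference implementations used as test oracles.

These are deliberately naive (sort/average/unsort, exhaustive enumeration,
brute-force formula evaluation) and stay independent of the code paths they
check.
"""

from __future__ import annotations

from math import comb

import numpy as np


def quantile_normalize_oracle(x: np.ndarray) -> np.ndarray:
    """Sort-average-unsort quantile normalization (no-tie inputs only)."""
    n, p = x.shape
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(p):
        order = np.argsort(x[:, j])
        out[order, j] = target
    return out


def fisher_enrichment_oracle(n_universe: int, n_spot: int, n_set: int, overlap: int) -> float:
    """Exact one-sided enrichment p: hypergeometric upper tail by direct
    combinatorial enumeration."""
    total = comb(n_universe, n_spot)
    hi = min(n_spot, n_set)
    return sum(comb(n_set, i) * comb(n_universe - n_set, n_spot - i) for i in range(overlap, hi + 1)) / total


def gsz_oracle(values: np.ndarray, set_rows: list[int]) -> np.ndarray:
    """Direct evaluation of the standardized-mean-difference GSZ with
    finite-population correction, one sample at a time."""
    n, p = values.shape
    g = len(set_rows)
    out = np.zeros(p)
    for j in range(p):
        col = values[:, j]
        diff = col[set_rows].mean() - col.mean()
        s = col.std(ddof=1)
        se = s * np.sqrt((n - g) / (g * (n - 1)))
        out[j] = diff / se if se > 0 else 0.0
    return out


def pearson_oracle(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    az, bz = a - a.mean(), b - b.mean()
    return float((az * bz).sum() / np.sqrt((az**2).sum() * (bz**2).sum()))


def silhouette_oracle(portraits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Brute-force correlation silhouette: r to own class-mean portrait
    minus the best r to any other class-mean portrait."""
    classes = np.unique(labels)
    cents = {c: portraits[labels == c].mean(axis=0) for c in classes}
    s = np.zeros(len(labels))
    for i in range(len(labels)):
        own = pearson_oracle(portraits[i], cents[labels[i]])
        other = max(pearson_oracle(portraits[i], cents[c]) for c in classes if c != labels[i])
        s[i] = own - other
    return s
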