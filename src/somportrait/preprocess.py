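"""Preprocessing: quantile normalization and gene-wise centralization.

Expression matrices are plain pandas DataFrames with genes as rows (index =
gene identifiers) and samples as columns (columns = sample identifiers),
holding log-scale intensities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _validate(m: pd.DataFrame, min_genes: int = 1, min_samples: int = 1) -> None:
    if not isinstance(m, pd.DataFrame):
        raise TypeError("expression matrix must be a pandas DataFrame")
    if m.shape[0] < min_genes or m.shape[1] < min_samples:
        raise ValueError(
            f"matrix of shape {m.shape} too small; need >= {min_genes} genes "
            f"and >= {min_samples} samples"
        )
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier: {dup!r}")
    values = m.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TypeError("expression values must be numeric")
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains missing or non-finite values")


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common distribution of rank means.

    Each column is sorted, the mean over columns is taken at every rank, and
    the rank means are written back in each column's original order.  Tied
    values within a column receive the mean of the rank means their tie
    group spans, so the output of a tied group is itself tied.

    Returns a new DataFrame; gene and sample identifiers are preserved.
    """
    _validate(m, min_genes=2, min_samples=2)
    x = m.to_numpy(dtype=float)
    n, p = x.shape
    target = np.sort(x, axis=0).mean(axis=1)  # rank means, ascending
    out = np.empty_like(x)
    for j in range(p):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        # tie groups in the sorted column share the mean of the spanned rank means
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_vals) != 0])
        counts = np.diff(np.r_[starts, n])
        group_means = np.add.reduceat(target, starts) / counts
        out[order, j] = np.repeat(group_means, counts)
    return pd.DataFrame(out, index=m.index.copy(), columns=m.columns.copy())


def centralize(m: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean over all samples (row-wise mean centering)."""
    _validate(m)
    x = m.to_numpy(dtype=float)
    out = x - x.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=m.index.copy(), columns=m.columns.copy())
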