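"""Prognostic map and per-class survival summaries.

The prognostic map links metagene over-expression to 28-day outcome: for
each metagene, the samples whose (centralized) portrait value exceeds
``sd_factor`` times that metagene's across-sample SD form its supporting
cases, and the map shows the percentage of survivors among them.
Metagenes supported by fewer than 10% of outcome-bearing samples are
masked (rendered white); so are metagenes with zero expression SD.
Controls carry no outcome and are excluded throughout, including from the
SD estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassAssignment
from .som import SOMModel

__all__ = ["PrognosticMap", "prognostic_map", "class_survival_rates"]


@dataclass
class PrognosticMap:
    survivor_pct: np.ndarray  # rows x cols, NaN where masked
    support: np.ndarray  # rows x cols, supporting-case counts
    mask: np.ndarray  # rows x cols, True = masked
    sd_factor: float
    n_outcome: int

    def to_frame(self) -> pd.DataFrame:
        rows, cols = self.support.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return pd.DataFrame(
            {
                "row": rr.ravel(),
                "col": cc.ravel(),
                "support": self.support.ravel(),
                "survivor_pct": [
                    "NA" if m else f"{v:.1f}"
                    for m, v in zip(self.mask.ravel(), self.survivor_pct.ravel())
                ],
                "masked": self.mask.ravel().astype(int),
            }
        )


def prognostic_map(model: SOMModel, survival: pd.Series, sd_factor: float = 1.0) -> PrognosticMap:
    """Per-metagene 28-day survivor percentage among over-expressing cases.

    Parameters
    ----------
    survival:
        Boolean Series indexed by sample id (True = survived 28 days);
        samples absent from it (e.g. controls) are ignored.
    sd_factor:
        Over-expression threshold in units of the metagene's SD across the
        outcome-bearing samples; default 1 (portrait value > +1 SD, values
        being centralized).
    """
    ids = [s for s in model.sample_ids if s in survival.index]
    if not ids:
        raise ValueError("no outcome-bearing samples present in the model")
    idx = [model.sample_index(s) for s in ids]
    sub = model.codebook[:, idx]  # n_nodes x n_outcome
    outcome = survival.loc[ids].astype(bool).to_numpy()
    n_outcome = len(ids)
    min_support = math.ceil(0.10 * n_outcome)

    sd = sub.std(axis=1, ddof=1) if n_outcome > 1 else np.zeros(sub.shape[0])
    exceed = sub > (sd_factor * sd)[:, None]
    support = exceed.sum(axis=1)
    survivors = (exceed & outcome[None, :]).sum(axis=1)
    masked = (support < min_support) | (sd <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * survivors / support
    pct = np.where(masked, np.nan, pct)

    shape = (model.rows, model.cols)
    return PrognosticMap(
        survivor_pct=pct.reshape(shape),
        support=support.reshape(shape).astype(int),
        mask=masked.reshape(shape),
        sd_factor=float(sd_factor),
        n_outcome=n_outcome,
    )


def class_survival_rates(classes: ClassAssignment | pd.Series, survival: pd.Series) -> pd.DataFrame:
    """Per-class survivor percentage with a one-sided Fisher exact test of
    the class against all remaining outcome-bearing samples.

    The test is one-sided in the direction of the class's observed
    deviation from the rest (reported in the ``direction`` column).
    Classes without any outcome data are absent from the table.
    """
    labels = classes.labels if isinstance(classes, ClassAssignment) else classes
    common = [s for s in labels.index if s in survival.index]
    if not common:
        raise ValueError("no overlap between class labels and survival records")
    lab = labels.loc[common]
    out = survival.loc[common].astype(bool)

    rows = []
    for c in sorted(lab.unique()):
        members = lab.index[lab == c]
        if len(members) == 0:
            continue
        surv_in = int(out.loc[members].sum())
        n_in = len(members)
        rest = out.drop(members)
        surv_rest, n_rest = int(rest.sum()), len(rest)
        table = [[surv_in, n_in - surv_in], [surv_rest, n_rest - surv_rest]]
        rate_in = surv_in / n_in
        rate_rest = surv_rest / n_rest if n_rest else float("nan")
        alternative = "greater" if (n_rest == 0 or rate_in >= rate_rest) else "less"
        if n_rest == 0:
            p = 1.0
        else:
            _, p = stats.fisher_exact(table, alternative=alternative)
        rows.append(
            {
                "class": c,
                "n": n_in,
                "survivors": surv_in,
                "survivor_pct": 100.0 * rate_in,
                "p_value": float(p),
                "direction": alternative,
            }
        )
    return pd.DataFrame(rows).set_index("class")
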