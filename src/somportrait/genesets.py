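"""Gene-set analysis: Fisher spot enrichment, GSZ profiles, population maps,
and the named transcriptomic scores (severity, viral/IFN, erythrocyte,
platelet, coagulation).

The per-sample gene set Z-score (GSZ) used here is a standardized mean
difference with finite-population correction.  For sample j, gene set G of
size g drawn from N genes with per-sample expression SD s_j:

    GSZ_j = (mean_{g in G} e_gj - mean_all e_.j) / (s_j * sqrt((N - g) / (g * (N - 1))))

i.e. the set mean is compared against the null of drawing g genes without
replacement from the sample's transcriptome.  An optional variance-shrinkage
mode stabilizes s_j toward the median sample SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .som import SOMModel
from .spots import SpotSegmentation, spot_expression_profile

__all__ = [
    "GeneSet",
    "fisher_spot_enrichment",
    "enrichment_table",
    "gsz_profile",
    "population_map",
    "named_scores",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.genes)


def fisher_spot_enrichment(spot_genes, gene_set: GeneSet, universe) -> dict:
    """One-sided Fisher exact test for enrichment of a gene set in a spot.

    2x2 table over the universe: in/out of spot x in/out of set; the
    alternative is enrichment (overlap larger than expected).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    spot = set(spot_genes) & universe
    members = set(gene_set.genes) & universe
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} disjoint from universe")
    if not set(spot_genes) <= universe:
        raise ValueError("spot genes must be a subset of the universe")
    k = len(spot & members)
    table = [
        [k, len(spot) - k],
        [len(members) - k, len(universe) - len(spot) - len(members) + k],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return {"p_value": float(p), "overlap": k, "odds_ratio": float(odds)}


def enrichment_table(
    seg: SpotSegmentation,
    gene_sets,
    universe,
    annotate_below: float = 1e-7,
) -> pd.DataFrame:
    """Fisher enrichment of every set in every spot, with per-spot BH
    correction across sets reported alongside the raw p-values."""
    rows = []
    for spot in seg:
        for gs in gene_sets:
            res = fisher_spot_enrichment(spot.genes, gs, universe)
            rows.append(
                {
                    "spot": spot.label,
                    "set": gs.name,
                    "overlap": res["overlap"],
                    "n_spot": len(spot.genes),
                    "n_set": len(set(gs.genes) & set(universe)),
                    "p_value": res["p_value"],
                    "odds_ratio": res["odds_ratio"],
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = np.nan
    for spot_label, idx in out.groupby("spot").groups.items():
        _, q, _, _ = multipletests(out.loc[idx, "p_value"], method="fdr_bh")
        out.loc[idx, "q_value"] = q
    out["annotated"] = out["p_value"] < annotate_below
    return out


def gsz_profile(
    gene_set: GeneSet,
    m: pd.DataFrame,
    mode: str = "smd",
    shrink_lambda: float = 0.1,
) -> pd.Series:
    """Per-sample GSZ score of a gene set on a centralized matrix.

    Set members absent from the matrix are dropped with a warning.  With
    ``mode="shrunk"`` the per-sample SD is shrunk toward the median sample
    SD: s_eff = sqrt((1 - lambda) s_j^2 + lambda median(s)^2).
    """
    present = [g for g in gene_set.genes if g in m.index]
    dropped = len(gene_set.genes) - len(present)
    if dropped:
        warnings.warn(
            f"gene set {gene_set.name!r}: dropped {dropped} members absent from matrix",
            stacklevel=2,
        )
    g = len(present)
    if g == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no members in the matrix")
    n = m.shape[0]
    if g == n:
        return pd.Series(0.0, index=m.columns, name=gene_set.name)
    diff = m.loc[present].mean(axis=0) - m.mean(axis=0)
    s = m.std(axis=0, ddof=1)
    if mode == "shrunk":
        s = np.sqrt((1.0 - shrink_lambda) * s**2 + shrink_lambda * float(np.median(s)) ** 2)
    elif mode != "smd":
        raise ValueError(f"unknown GSZ mode: {mode!r}")
    denom = s * np.sqrt((n - g) / (g * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / denom
    z = z.where(denom > 0, 0.0)
    z.name = gene_set.name
    return z


def population_map(
    gene_set: GeneSet,
    model: SOMModel,
    seg: SpotSegmentation | None = None,
) -> tuple[np.ndarray, dict[str, float] | None]:
    """Where a gene set's members sit on the map.

    Returns the per-pixel count of set genes (by BMU) and, if a
    segmentation is given, the per-spot local percentage
    ``100 * set genes in spot / all genes in spot`` (NaN for gene-free
    spots).
    """
    members = set(gene_set.genes)
    counts = np.zeros((model.rows, model.cols), dtype=int)
    in_set = np.array([g in members for g in model.gene_ids])
    rr, cc = np.unravel_index(model.bmu[in_set], (model.rows, model.cols))
    np.add.at(counts, (rr, cc), 1)
    if seg is None:
        return counts, None
    pct = {}
    for spot in seg:
        n_genes = len(spot.genes)
        n_in = len(members & set(spot.genes))
        pct[spot.label] = 100.0 * n_in / n_genes if n_genes else float("nan")
    return counts, pct


def named_scores(
    m: pd.DataFrame,
    seg: SpotSegmentation,
    gene_sets: dict[str, GeneSet],
    severity_spot: str,
    gsz_mode: str = "smd",
) -> pd.DataFrame:
    """Per-sample table of the named transcriptomic scores.

    The severity score is the mean expression profile of the designated
    severity spot (the map module tracking inflammatory activity); every
    other score is the GSZ profile of its bound gene set (e.g. viral/IFN,
    erythrocyte, platelet, coagulation signatures).
    """
    out = {"severity": spot_expression_profile(seg, severity_spot, m)}
    for score_name, gs in gene_sets.items():
        if score_name == "severity":
            raise ValueError("'severity' is reserved for the designated spot score")
        out[score_name] = gsz_profile(gs, m, mode=gsz_mode)
    return pd.DataFrame(out)
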