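from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

import somportrait as sp
from somportrait.som import SOMModel


def make_model(codebook: np.ndarray, rows: int, cols: int, bmu=None, gene_ids=None, sample_ids=None) -> SOMModel:
    """Hand-built SOMModel for toy tests (codebook: n_nodes x n_samples)."""
    n_nodes, n_samples = codebook.shape
    assert n_nodes == rows * cols
    if bmu is None:
        bmu = np.zeros(0, dtype=int)
        gene_ids = gene_ids or []
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(bmu))]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_samples)]
    return SOMModel(
        rows=rows,
        cols=cols,
        codebook=np.asarray(codebook, dtype=float),
        bmu=np.asarray(bmu, dtype=int),
        gene_ids=list(gene_ids),
        sample_ids=list(sample_ids),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared by structural tests."""
    cfg = sp.SimConfig(
        n_genes=600, n_modules=12, module_size=30, n_cap=60, n_controls=5, seed=7
    )
    expr, ann, truth = sp.generate_dataset(cfg)
    return cfg, expr, ann, truth


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    """Preprocessed matrix + trained SOM on the small dataset."""
    cfg, expr, ann, truth = small_dataset
    m = sp.centralize(sp.quantile_normalize(expr))
    model = sp.train_som(m, grid=(12, 12), epochs=15, seed=cfg.seed)
    return cfg, m, ann, truth, model


def run_recovery(seed: int) -> dict:
    """Full recovery run at the default study conditions for one seed.

    Generates the default dataset, runs preprocessing, SOM, segmentation,
    scoring, class discovery, and the survival analyses, and returns the
    recovery metrics against the planted truth.
    """
    cfg = sp.SimConfig(seed=seed)
    expr, ann, truth = sp.generate_dataset(cfg)
    m = sp.centralize(sp.quantile_normalize(expr))
    model = sp.train_som(m, grid=(20, 20), epochs=30, seed=seed)
    vmap = sp.variance_map(model)
    planted_fraction = cfg.n_modules * cfg.module_size / cfg.n_genes
    percentile = max(50.0, min(90.0, 100.0 * (1.0 - 1.15 * planted_fraction)))
    seg = sp.segment_spots(model, vmap, percentile=percentile, split_umap=True)

    purity = {
        name: max(len(set(genes) & set(s.genes)) for s in seg) / len(genes)
        for name, genes in truth.module_genes.items()
    }
    sev_spot = max(seg, key=lambda s: len(set(s.genes) & set(truth.module_genes["sev_up"])))
    severity = sp.spot_expression_profile(seg, sev_spot.label, m)
    cap = [s for s in m.columns if ann.loc[s, "group"] == "CAP"]
    rho = float(spearmanr(severity[cap], truth.latents.loc[cap, "u"]).statistic)

    r = sp.portrait_correlation_matrix(model)
    assignment = sp.discover_classes(r, model, k=6, seed=seed, sample_ids=cap)
    ari = float(adjusted_rand_score(truth.class_labels[cap], assignment.labels[cap]))

    survived = ~truth.death_28d
    rates = sp.class_survival_rates(truth.class_labels[cap], survived)

    pmap = sp.prognostic_map(model, survived)
    sev_pix = [pmap.survivor_pct[r_, c_] for r_, c_ in sev_spot.pixels if not pmap.mask[r_, c_]]
    unmasked = pmap.survivor_pct[~pmap.mask]
    prognosis_gap = (
        float(np.mean(sev_pix) - np.median(unmasked)) if sev_pix and unmasked.size else np.nan
    )

    portraits = {s: sp.sample_portrait(model, s) for s in model.sample_ids}
    # hold the over-expression cut at ~50 pixels regardless of map size
    # (the 2% convention of a 50x50 map)
    q = 1.0 - 50.0 / (model.rows * model.cols)
    counts, _ = sp.spot_frequency_distribution(portraits, seg, q=q, groups=ann["group"])
    # "high severity" by the transcriptomic severity score (top tertile of
    # CAP), matching how severity groups are defined downstream
    sev_cap = severity[cap].sort_values()
    high_sev = sev_cap.index[-(len(cap) // 3) :]
    controls = ann.index[ann["group"] == "control"]
    active_gap = float(counts[high_sev].mean() - counts[controls].mean())

    ery = sp.gsz_profile(
        sp.GeneSet("erythrocyte", tuple(truth.module_genes["bd"])), m
    )
    tert = pd.qcut(severity[cap], 3, labels=["low", "mid", "high"])
    ery_mid = float(ery[cap][tert == "mid"].mean())
    ery_outer = float(ery[cap][tert != "mid"].mean())

    return {
        "rho": rho,
        "ari": ari,
        "purity": purity,
        "rates": rates,
        "prognosis_gap": prognosis_gap,
        "active_gap": active_gap,
        "ery_mid_minus_outer": ery_mid - ery_outer,
        "n_cap": len(cap),
        "n_spots": len(seg),
    }


@pytest.fixture(scope="session")
def recovery_runs():
    """Ten independent recovery runs at the default study conditions."""
    return [run_recovery(seed) for seed in range(10)]
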