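"""End-to-end portrayal pipeline.

Stages: preprocess -> train SOM -> portraits -> variance map -> spot
segmentation -> gene-set scoring -> class discovery -> prognostic map.
Every stage logs its wall time to the run manifest; any stage failure
aborts with the stage name and leaves a FAILED marker next to the partial
outputs.  Identical configuration (including seed) reproduces byte-identical
tabular outputs.
"""

from __future__ import annotations

import json
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import bootstrap_stability, discover_classes, portrait_correlation_matrix
from .genesets import enrichment_table, named_scores
from .io import (
    COORD_COMMENT,
    PipelineConfig,
    read_annotation_tsv,
    read_expression_tsv,
    read_gmt,
    save_model,
    survival_from_annotation,
)
from .preprocess import centralize, quantile_normalize
from .prognosis import class_survival_rates, prognostic_map
from .som import sample_portrait, train_som, variance_map
from .spots import segment_spots, spot_frequency_distribution

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(frame: pd.DataFrame, path: Path, coords: bool = False, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if coords:
            fh.write(COORD_COMMENT)
        frame.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a result bundle of in-memory objects
    and writes all tabular/graphical artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    manifest = {
        "package": "somportrait",
        "version": __version__,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "stages": [],
    }
    manifest["config"]["grid"] = list(config.grid)
    bundle: dict = {}
    stage = "validate-inputs"

    def _finish_stage(name: str, t0: float) -> None:
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})

    try:
        t0 = time.time()
        for label, p in [("matrix", config.matrix), ("annotation", config.annotation)]:
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{label} path not found: {p!r}")
        if config.gene_sets and not Path(config.gene_sets).exists():
            raise FileNotFoundError(f"gene set path not found: {config.gene_sets!r}")
        _finish_stage(stage, t0)

        stage = "preprocess"
        t0 = time.time()
        raw = read_expression_tsv(config.matrix)
        ann = read_annotation_tsv(config.annotation)
        expr = centralize(quantile_normalize(raw))
        bundle["expression"] = expr
        _finish_stage(stage, t0)

        stage = "train_som"
        t0 = time.time()
        model = train_som(expr, grid=config.grid, epochs=config.epochs, seed=config.seed)
        save_model(model, out / "som")
        bundle["model"] = model
        _finish_stage(stage, t0)

        stage = "portraits"
        t0 = time.time()
        portraits = {s: sample_portrait(model, s) for s in model.sample_ids}
        bundle["portraits"] = portraits
        _finish_stage(stage, t0)

        stage = "variance_map"
        t0 = time.time()
        vmap = variance_map(model)
        vm = pd.DataFrame(vmap)
        vm.index.name = "row"
        _write_tsv(vm, out / "variance_map.tsv", coords=True)
        bundle["variance_map"] = vmap
        _finish_stage(stage, t0)

        stage = "segment_spots"
        t0 = time.time()
        seg = segment_spots(
            model, vmap, percentile=config.spot_percentile, split_umap=config.split_umap
        )
        _write_tsv(seg.to_frame(), out / "spots.tsv", coords=True, index=False)
        bundle["segmentation"] = seg
        _finish_stage(stage, t0)

        stage = "spot_activation"
        t0 = time.time()
        groups = ann[config.group_column] if config.group_column in ann.columns else None
        counts, hist = spot_frequency_distribution(
            portraits, seg, q=config.activation_quantile, groups=groups
        )
        _write_tsv(counts.to_frame(), out / "active_spot_counts.tsv")
        _write_tsv(hist, out / "spot_frequency_distribution.tsv")
        bundle["active_spot_counts"] = counts
        bundle["spot_frequency"] = hist
        _finish_stage(stage, t0)

        stage = "geneset_scoring"
        t0 = time.time()
        if config.gene_sets:
            sets = read_gmt(config.gene_sets)
            universe = list(expr.index)
            enr = enrichment_table(seg, sets, universe)
            _write_tsv(enr, out / "spot_enrichment.tsv", index=False)
            bundle["enrichment"] = enr
            severity_spot = config.severity_spot or seg.spots[0].label
            by_name = {gs.name: gs for gs in sets}
            bound = {}
            for score, set_name in config.score_sets.items():
                if set_name not in by_name:
                    raise KeyError(f"score {score!r} bound to unknown gene set {set_name!r}")
                bound[score] = by_name[set_name]
            scores = named_scores(expr, seg, bound, severity_spot=severity_spot)
            _write_tsv(scores, out / "scores.tsv")
            bundle["scores"] = scores
        _finish_stage(stage, t0)

        stage = "class_discovery"
        t0 = time.time()
        cap_ids = [
            s
            for s in model.sample_ids
            if config.group_column not in ann.columns or ann.loc[s, config.group_column] != "control"
        ]
        r = portrait_correlation_matrix(model)
        _write_tsv(r, out / "portrait_correlations.tsv")
        assignment = discover_classes(r, model, k=config.k_classes, seed=config.seed, sample_ids=cap_ids)
        if config.bootstrap_b >= 2:
            assignment.stability_pct = bootstrap_stability(
                model, k=config.k_classes, b=config.bootstrap_b, seed=config.seed,
                sample_ids=cap_ids, r=r,
            )
        cls = pd.DataFrame({"class": assignment.labels, "S": assignment.silhouette})
        cls.index.name = "sample_id"
        _write_tsv(cls, out / "classes.tsv")
        bundle["classes"] = assignment
        _finish_stage(stage, t0)

        stage = "prognostic_map"
        t0 = time.time()
        survival = survival_from_annotation(ann, config.survival_column)
        if len(survival):
            pmap = prognostic_map(model, survival, sd_factor=config.sd_factor)
            _write_tsv(pmap.to_frame(), out / "prognostic_map.tsv", coords=True, index=False)
            rates = class_survival_rates(assignment, survival)
            _write_tsv(rates, out / "class_survival.tsv")
            bundle["prognostic_map"] = pmap
            bundle["class_survival"] = rates
        _finish_stage(stage, t0)

        stage = "render"
        t0 = time.time()
        if config.render_png:
            from .render import (
                render_portrait,
                render_prognostic_map,
                render_segmentation,
                render_variance_map,
            )

            render_variance_map(vmap, out / "variance_map.png")
            render_segmentation(vmap, seg, out / "segmentation.png")
            first = model.sample_ids[0]
            render_portrait(portraits[first], out / f"portrait_{first}.png", title=first)
            if "prognostic_map" in bundle:
                render_prognostic_map(bundle["prognostic_map"], out / "prognostic_map.png")
        _finish_stage(stage, t0)

        stage = "manifest"
        manifest["status"] = "ok"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = "".join(traceback.format_exception_only(exc)).strip()
        failed_marker.write_text(f"stage: {stage}\nerror: {manifest['error']}\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineError(stage, exc) from exc
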