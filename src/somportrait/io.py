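"""Readers and writers: expression/annotation TSV, GMT gene sets, model
serialization, and the pipeline configuration.

All tabular outputs are tab-separated text.  Grid coordinates in any output
are 0-based and row-major; tables that carry coordinates state this in a
header comment line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genesets import GeneSet
from .som import SOMModel

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_gmt",
    "write_gmt",
    "save_model",
    "load_model",
    "PipelineConfig",
]

COORD_COMMENT = "# coordinates: 0-based, row-major\n"


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples TSV (header row of sample IDs, first column
    gene IDs) into a validated DataFrame."""
    path = Path(path)
    m = pd.read_csv(path, sep="\t", index_col=0, comment="#", float_precision="round_trip")
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    if m.columns.has_duplicates:
        dup = m.columns[m.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    values = m.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
        raise ValueError(f"{path}: non-numeric or missing expression values")
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    m.index.name = "gene_id"
    return m


def write_expression_tsv(m: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = m.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation_tsv(path) -> pd.DataFrame:
    path = Path(path)
    ann = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    ann.index = ann.index.astype(str)
    return ann


def write_annotation_tsv(ann: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ann.to_csv(path, sep="\t")


def survival_from_annotation(ann: pd.DataFrame, column: str = "survived_28d") -> pd.Series:
    """Boolean 28-day survival Series for outcome-bearing samples."""
    if column not in ann.columns:
        raise KeyError(f"annotation lacks column {column!r}")
    raw = ann[column].astype(str).str.strip()
    has = raw.str.lower().isin(["true", "false", "1", "0"])
    vals = raw[has].str.lower().isin(["true", "1"])
    return pd.Series(vals, name=column)


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: one set per line, tab-separated
    name / description / members.  Trailing empty fields are ignored;
    duplicate set names and empty sets are rejected."""
    path = Path(path)
    sets = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
            name, description = fields[0], fields[1]
            members = tuple(g for g in fields[2:] if g.strip())
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, genes=members, description=description))
    return sets


def write_gmt(sets, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def save_model(model: SOMModel, prefix) -> None:
    """Serialize a model as <prefix>.meta.yaml + <prefix>.codebook.tsv +
    <prefix>.bmu.tsv (all plain text)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "rows": model.rows,
        "cols": model.cols,
        "epochs": model.epochs,
        "seed": model.seed,
        "radius_schedule": model.radius_schedule,
    }
    with open(f"{prefix}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    cb = pd.DataFrame(model.codebook, columns=model.sample_ids)
    cb.index.name = "metagene"
    with open(f"{prefix}.codebook.tsv", "w") as fh:
        fh.write(COORD_COMMENT)
        cb.to_csv(fh, sep="\t", float_format="%.10g")
    bmu = pd.DataFrame({"gene_id": model.gene_ids, "bmu": model.bmu})
    with open(f"{prefix}.bmu.tsv", "w") as fh:
        fh.write(COORD_COMMENT)
        bmu.to_csv(fh, sep="\t", index=False)


def load_model(prefix) -> SOMModel:
    prefix = Path(prefix)
    with open(f"{prefix}.meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    cb = pd.read_csv(f"{prefix}.codebook.tsv", sep="\t", index_col=0, comment="#")
    bmu = pd.read_csv(f"{prefix}.bmu.tsv", sep="\t", comment="#")
    return SOMModel(
        rows=int(meta["rows"]),
        cols=int(meta["cols"]),
        codebook=cb.to_numpy(dtype=float),
        bmu=bmu["bmu"].to_numpy(dtype=int),
        gene_ids=[str(g) for g in bmu["gene_id"]],
        sample_ids=[str(s) for s in cb.columns],
        epochs=int(meta["epochs"]),
        seed=int(meta["seed"]),
        radius_schedule=[float(r) for r in meta.get("radius_schedule", [])],
    )


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end portrayal pipeline."""

    matrix: str = ""
    annotation: str = ""
    gene_sets: str = ""  # GMT path; empty -> skip set scoring
    out_dir: str = "results"
    grid: tuple[int, int] = (50, 50)
    epochs: int = 30
    seed: int = 0
    spot_percentile: float = 90.0
    split_umap: bool = False
    activation_quantile: float = 0.98
    k_classes: int = 6
    bootstrap_b: int = 100
    sd_factor: float = 1.0
    severity_spot: str = ""  # spot label; empty -> highest-variance spot
    score_sets: dict = field(default_factory=dict)  # score name -> gene set name
    group_column: str = "group"
    survival_column: str = "survived_28d"
    render_png: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.grid = tuple(int(x) for x in cfg.grid)
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["grid"] = list(self.grid)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
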