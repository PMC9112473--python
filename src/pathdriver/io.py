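"""Readers, writers and validation for the pipeline's external formats.

Expression matrices are tab-separated with genes in rows (first column =
gene identifier, header = sample identifiers).  Gene sets use the GMT
dialect.  Protein--protein interactions are a three-column edge list with a
combined confidence score; STRING distributes these as integers on a
0--1000 scale, which ``score_scale="string_milli"`` rescales to [0, 1].
Genes are matched by exact string identity throughout — identifier mapping
(symbols vs. Ensembl ids) is the caller's responsibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DrugResponseTable",
    "GeneSetCollection",
    "InteractionEdgeList",
    "FormatError",
    "ValidationError",
    "load_expression",
    "load_response",
    "load_gmt",
    "load_interactions",
    "write_results",
]


class FormatError(ValueError):
    """A file does not follow the declared external format."""


class ValidationError(ValueError):
    """Parsed data violates an internal-model invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized continuous expression.

    ``values.index`` holds unique gene ids, ``values.columns`` unique
    sample ids; no missing entries are allowed after loading.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        if self.values.shape[1] < 2:
            raise ValidationError(
                f"need at least 2 samples, got {self.values.shape[1]}"
            )
        if self.values.isna().any().any():
            raise ValidationError("missing values present after load")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[present])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)])


@dataclass
class DrugResponseTable:
    """Per-sample drug response measured as area under the dose--response
    curve (higher AUC = more resistant)."""

    table: pd.DataFrame  # columns: sample_id, auc

    def __post_init__(self) -> None:
        if set(self.table.columns) < {"sample_id", "auc"}:
            raise ValidationError("response table needs sample_id and auc columns")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in response table")
        if not np.isfinite(self.table["auc"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite AUC values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def auc(self) -> pd.Series:
        return pd.Series(
            self.table["auc"].to_numpy(dtype=float),
            index=self.table["sample_id"].tolist(),
            name="auc",
        )


@dataclass
class GeneSetCollection:
    """Ordered mapping of set id -> (description, member genes)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return out


@dataclass
class InteractionEdgeList:
    """Undirected, deduplicated weighted edges with scores in [0, 1]."""

    edges: pd.DataFrame  # columns: gene_a, gene_b, combined_score

    def __post_init__(self) -> None:
        s = self.edges["combined_score"].to_numpy(dtype=float)
        if len(s) and ((s < 0).any() or (s > 1).any()):
            raise ValidationError("combined scores outside [0, 1]")

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])


def load_expression(path, drop_incomplete: bool = True) -> ExpressionMatrix:
    """Load a genes-in-rows TSV expression matrix.

    Duplicate gene rows are collapsed by mean; rows with any missing value
    are dropped when ``drop_incomplete`` (otherwise missing values raise).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need at least 2 sample columns")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids in header")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression values: {exc}") from exc

    n_dup = int(df.index.duplicated().sum())
    if n_dup:
        df = df.groupby(level=0, sort=False).mean()
        log.info("collapsed %d duplicate gene rows by mean", n_dup)
    n_na = int(df.isna().any(axis=1).sum())
    if n_na:
        if not drop_incomplete:
            raise ValidationError(f"{path}: {n_na} rows with missing values")
        df = df.dropna(axis=0)
        log.info("dropped %d genes with missing values", n_na)
    return ExpressionMatrix(df)


def load_response(path) -> DrugResponseTable:
    """Load a two-column (sample_id, auc) response table; the delimiter
    (comma or tab) is sniffed from the file."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least 2 columns")
    df = df.rename(columns={df.columns[0]: "sample_id", df.columns[1]: "auc"})
    df["sample_id"] = df["sample_id"].astype(str)
    return DrugResponseTable(df[["sample_id", "auc"]])


def load_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated line per set
    (name, description, member genes...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >=3 fields"
                )
            sid, desc, *genes = fields
            genes = [g for g in genes if g]
            if sid in sets:
                raise ValidationError(f"{path}: duplicate set id {sid!r}")
            sets[sid] = set(genes)
            descriptions[sid] = desc
    return GeneSetCollection(sets, descriptions)


def load_interactions(path, score_scale: str = "string_milli") -> InteractionEdgeList:
    """Load a 3-column (gene_a, gene_b, combined_score) edge list.

    ``string_milli`` divides raw 0--1000 STRING scores by 1000; ``unit``
    takes scores as already lying in [0, 1].  Self-edges are dropped;
    duplicate undirected edges keep the maximum score.
    """
    if score_scale not in ("unit", "string_milli"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns")
    df = df.rename(
        columns=dict(zip(df.columns[:3], ["gene_a", "gene_b", "combined_score"]))
    )[["gene_a", "gene_b", "combined_score"]]
    df["gene_a"] = df["gene_a"].astype(str)
    df["gene_b"] = df["gene_b"].astype(str)
    score = df["combined_score"].to_numpy(dtype=float)
    hi = 1000.0 if score_scale == "string_milli" else 1.0
    if (score < 0).any() or (score > hi).any():
        raise ValidationError(
            f"{path}: scores outside declared {score_scale} range [0, {hi:g}]"
        )
    df["combined_score"] = score / hi

    n_self = int((df["gene_a"] == df["gene_b"]).sum())
    if n_self:
        df = df[df["gene_a"] != df["gene_b"]]
        log.info("dropped %d self-edges", n_self)
    # canonical undirected orientation, then max-dedup
    a = df["gene_a"].to_numpy()
    b = df["gene_b"].to_numpy()
    swap = a > b
    df = pd.DataFrame(
        {
            "gene_a": np.where(swap, b, a),
            "gene_b": np.where(swap, a, b),
            "combined_score": df["combined_score"].to_numpy(),
        }
    )
    df = (
        df.groupby(["gene_a", "gene_b"], as_index=False, sort=True)["combined_score"]
        .max()
    )
    return InteractionEdgeList(df.reset_index(drop=True))


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    *,
    params: Mapping | None = None,
    inputs: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write each named table as TSV plus a JSON run manifest.

    The manifest records input paths, parameters, the seed, the package
    version and per-table row counts; it is returned as a dict and written
    to ``manifest.json`` in ``out_dir``.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.10g")
        counts[name] = int(len(table))
    manifest = {
        "version": __version__,
        "seed": seed,
        "inputs": {k: str(v) for k, v in (inputs or {}).items()},
        "parameters": _jsonable(dict(params or {})),
        "row_counts": counts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
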