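"""End-to-end orchestration of the pathway-to-module nomination method.

Stages: label samples from AUC -> z-normalize expression over labeled
samples -> greedy pathway-activity scoring -> pathway filter (percentile
or label-permutation) -> pool genes of retained pathways -> interaction
adjacency / topological overlap / module partition -> per-module shadow
feature selection -> pooled SVM-RFE -> module ranking by minimum member
rank -> enrichment of top modules.  One global seed fans out to per-stage
substreams so identical config + seed reproduces every table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, enrichment, network, ranking
from .io import (
    ExpressionMatrix,
    ValidationError,
    load_expression,
    load_gmt,
    load_interactions,
    load_response,
    write_results,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; read/written as YAML with explicit defaults."""

    expression: str = ""
    response: str = ""
    pathways: str = ""
    interactions: str = ""
    enrichment_terms: str = ""
    out_dir: str = "pathdriver_out"

    label_mode: str = "fixed"  # fixed | percentile
    auc_cutoff: float = 9.0

    filter_mode: str = "percentile"  # percentile | permutation
    tail_pct: float = 10.0
    n_perm: int = 1000
    alpha: float = 0.05

    interaction_threshold: float = 0.4
    score_scale: str = "unit"
    linkage: str = "average"
    cut: str = "height"
    cut_value: float = 0.95
    min_module_size: int = 5

    boruta_max_runs: int = 100
    boruta_p_value: float = 0.01
    boruta_trees: int = 100

    cv: str = "kfold"  # kfold | loocv
    cv_k: int = 10
    svm_C: float = 1.0

    enrich_top_modules: int = 5
    enrich_min_term: int = 3

    seed: int = 0

    def validate(self) -> None:
        for name in ("expression", "response", "pathways", "interactions"):
            p = getattr(self, name)
            if not p:
                raise ValidationError(f"config field {name!r} is required")
            if not Path(p).exists():
                raise ValidationError(f"config field {name!r}: no such file: {p}")
        if self.enrichment_terms and not Path(self.enrichment_terms).exists():
            raise ValidationError(
                f"config field 'enrichment_terms': no such file: {self.enrichment_terms}"
            )
        if self.label_mode not in ("fixed", "percentile"):
            raise ValidationError(f"unknown label_mode {self.label_mode!r}")
        if self.filter_mode not in ("percentile", "permutation"):
            raise ValidationError(f"unknown filter_mode {self.filter_mode!r}")
        if not 0 < self.interaction_threshold <= 1:
            raise ValidationError("interaction_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    labels: activity.ResponseLabels
    pathway_table: pd.DataFrame
    retained_pathways: list[str]
    partition: network.ModulePartition
    decisions: pd.DataFrame
    rank_table: pd.DataFrame
    cv_curve: pd.DataFrame
    module_ranking: pd.DataFrame
    enrichment_tables: dict[int, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write all result tables plus the manifest."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seed_perm, seed_boruta, seed_cv = ss.spawn(3)
    counts: dict[str, int] = {}

    expr = load_expression(config.expression)
    responses = load_response(config.response)
    pathways = load_gmt(config.pathways)
    interactions = load_interactions(config.interactions, score_scale=config.score_scale)
    terms = load_gmt(config.enrichment_terms) if config.enrichment_terms else None
    counts["genes_loaded"] = expr.shape[0]
    counts["samples_loaded"] = expr.shape[1]
    counts["pathways_loaded"] = len(pathways)
    counts["interaction_edges"] = len(interactions)

    labels = activity.label_by_auc(responses, mode=config.label_mode, cutoff=config.auc_cutoff)
    n_s, n_r = labels.counts()
    counts["n_sensitive"], counts["n_resistant"] = n_s, n_r

    labeled = [s for s in expr.sample_ids if s in set(labels.sample_ids)]
    if len(labeled) < 4:
        raise ValidationError("fewer than 4 labeled samples in the matrix")
    z = activity.zscore_rows(expr.subset_samples(labeled))

    results, skipped = activity.score_all_pathways(pathways, z, labels)
    counts["pathways_scored"] = len(results)
    counts["pathways_skipped"] = len(skipped)

    if config.filter_mode == "percentile":
        filtered = activity.filter_percentile(results, tail_pct=config.tail_pct)
    else:
        filtered = activity.filter_permutation(
            pathways, z, labels,
            n_perm=config.n_perm, alpha=config.alpha, seed=seed_perm,
        )
    pathway_table = activity.activity_table(results, filtered)
    retained = [f.pathway_id for f in filtered if f.retained]
    counts["pathways_retained"] = len(retained)

    pooled: set[str] = set()
    zgenes = set(z.gene_ids)
    for pid in retained:
        pooled |= pathways.sets[pid] & zgenes
    counts["genes_pooled"] = len(pooled)
    if len(pooled) < 2:
        raise ValidationError("fewer than 2 genes pooled from retained pathways")

    adj = network.build_adjacency(interactions, pooled, threshold=config.interaction_threshold)
    tom = network.topological_overlap(adj)
    partition = network.cluster_modules(
        tom,
        linkage_method=config.linkage,
        cut=config.cut,
        cut_value=config.cut_value,
        min_module_size=config.min_module_size,
    )
    counts["modules"] = len([m for m in partition.module_ids if m != 0])

    decisions = ranking.boruta_select_modules(
        z.subset_genes(pooled), partition, labels,
        max_runs=config.boruta_max_runs,
        p_value=config.boruta_p_value,
        n_trees=config.boruta_trees,
        seed=seed_boruta,
    )
    decisions_df = ranking.decisions_frame(decisions)
    confirmed = decisions_df.loc[decisions_df["decision"] == ranking.CONFIRMED, "gene_id"]
    counts["genes_confirmed"] = len(confirmed)
    if len(confirmed) < 2:
        raise ValidationError(
            f"only {len(confirmed)} genes confirmed; need >=2 for SVM-RFE"
        )

    module_of_gene = partition.assignments.to_dict()
    rank_table, curve = ranking.svm_rfe_rank(
        z.subset_genes(confirmed), labels,
        module_of_gene=module_of_gene,
        cv=config.cv, k=config.cv_k, C=config.svm_C, seed=seed_cv,
    )
    module_ranking = ranking.rank_modules(rank_table, partition)

    enrich_tables: dict[int, pd.DataFrame] = {}
    if terms is not None:
        universe = zgenes & terms.all_genes()
        top = module_ranking.table["module_id"].head(config.enrich_top_modules)
        for mod in top:
            query = set(partition.module_genes(int(mod))) & universe
            if not query:
                continue
            enrich_tables[int(mod)] = enrichment.enrich(
                query, universe, terms, min_term=config.enrich_min_term
            )

    tables = {
        "pathway_scores": pathway_table,
        "module_partition": network.module_table(partition, tom),
        "boruta_decisions": decisions_df,
        "feature_ranks": rank_table.as_frame(),
        "cv_curve": curve.as_frame(),
        "module_ranking": module_ranking.table,
    }
    for mod, tab in enrich_tables.items():
        tables[f"enrichment_module_{mod}"] = tab
    manifest = write_results(
        tables,
        config.out_dir,
        params={**dataclasses.asdict(config), "stage_counts": counts},
        inputs={
            "expression": config.expression,
            "response": config.response,
            "pathways": config.pathways,
            "interactions": config.interactions,
            "enrichment_terms": config.enrichment_terms,
        },
        seed=config.seed,
    )
    return PipelineResult(
        labels=labels,
        pathway_table=pathway_table,
        retained_pathways=retained,
        partition=partition,
        decisions=decisions_df,
        rank_table=rank_table.as_frame(),
        cv_curve=curve.as_frame(),
        module_ranking=module_ranking.table,
        enrichment_tables=enrich_tables,
        manifest=manifest,
        stage_counts=counts,
    )
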