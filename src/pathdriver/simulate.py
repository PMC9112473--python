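"""Synthetic benchmark data with planted ground truth.

The generator emulates the statistical structure of the real inputs the
pipeline targets: a two-class expression matrix in which the genes of one
or more "driver" pathways shift by a known effect size in resistant
samples, an interaction network drawn from a stochastic block model whose
dense blocks coincide with co-expressed gene groups, drug-response AUCs
driven by the class labels, and gene-set collections containing the
planted pathways among random decoys.  Every planted quantity is recorded
in a ground-truth object so recovery can be measured without re-reading
the generator.

Expression model, per gene i and sample j (block b(i), resistant
indicator r_j):

    x_ij = delta * r_j * [i is a driver gene] + f_{b(i), j} + eps_ij,
    f ~ N(0, 0.5^2) shared within a block (induces intra-module
    correlation), eps ~ N(0, 1).

AUC model: auc_j = 6 + 2 * r_j + N(0, auc_noise_sd); an AUC cutoff of 7
therefore recovers the planted classes up to the noise overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    DrugResponseTable,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionEdgeList,
    write_expression,
)

BLOCK_FACTOR_SD = 0.5
AUC_BASE = 6.0
AUC_EFFECT = 2.0
AUC_CUTOFF = AUC_BASE + AUC_EFFECT / 2.0  # midpoint between class means


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults define the standard benchmark
    condition (100 samples, 1000 genes, one driver pathway of 20 genes
    shifted by 1.5 within-gene standard deviations)."""

    n_samples: int = 100
    n_genes: int = 1000
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (15, 25)
    n_driver_pathways: int = 1
    driver_pathway_size: int = 20
    effect_delta: float = 1.5
    block_p_in: float = 0.3
    block_p_out: float = 0.01
    score_range: tuple[float, float] = (0.4, 1.0)
    between_score_range: tuple[float, float] = (0.05, 0.35)
    label_fraction_resistant: float = 0.5
    auc_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for p in (self.block_p_in, self.block_p_out, self.label_fraction_resistant):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be >= 0")
        if min(self.n_samples, self.n_genes, self.n_pathways) <= 0:
            raise ValueError("sizes must be positive")
        lo, hi = self.pathway_size_range
        need = self.driver_pathway_size * self.n_driver_pathways + hi * (
            self.n_pathways - self.n_driver_pathways
        )
        if need > self.n_genes:
            raise ValueError(
                f"pathways need up to {need} genes but only {self.n_genes} available"
            )


@dataclass
class SyntheticGroundTruth:
    driver_pathway_ids: list[str]
    driver_gene_ids: list[str]
    planted_module_of_gene: dict[str, int]
    true_effect_per_gene: dict[str, float]
    driver_term_ids: list[str] = field(default_factory=list)
    resistant_samples: list[str] = field(default_factory=list)


@dataclass
class SyntheticBundle:
    expression: ExpressionMatrix
    response: DrugResponseTable
    pathways: GeneSetCollection
    enrichment_terms: GeneSetCollection
    interactions: InteractionEdgeList
    truth: SyntheticGroundTruth


def generate_dataset(spec: SyntheticSpec) -> SyntheticBundle:
    """Draw one dataset from the generative model described above."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes

    samples = [f"S{j:04d}" for j in range(n)]
    genes = [f"G{i:05d}" for i in range(g)]

    resistant = np.zeros(n, dtype=bool)
    n_res = int(round(spec.label_fraction_resistant * n))
    resistant[rng.choice(n, size=n_res, replace=False)] = True

    # --- partition genes into planted blocks (= pathway memberships) ---
    lo, hi = spec.pathway_size_range
    sizes = [spec.driver_pathway_size] * spec.n_driver_pathways + [
        int(rng.integers(lo, hi + 1))
        for _ in range(spec.n_pathways - spec.n_driver_pathways)
    ]
    perm = rng.permutation(g)
    block_of_gene = np.zeros(g, dtype=int)  # 0 = background
    pathway_sets: dict[str, set[str]] = {}
    pos = 0
    for b, size in enumerate(sizes, start=1):
        members = perm[pos : pos + size]
        block_of_gene[members] = b
        pathway_sets[f"PW{b:03d}"] = {genes[i] for i in members}
        pos += size
    driver_pids = [f"PW{b:03d}" for b in range(1, spec.n_driver_pathways + 1)]
    driver_genes = sorted(set().union(*(pathway_sets[p] for p in driver_pids)))
    driver_idx = np.array([genes.index(gid) for gid in driver_genes])

    # --- expression: block factor + driver shift + unit noise ---
    n_blocks = len(sizes)
    f = rng.normal(0.0, BLOCK_FACTOR_SD, size=(n_blocks + 1, n))
    x = rng.normal(0.0, 1.0, size=(g, n))
    x += f[block_of_gene]
    effect = np.zeros(g)
    if len(driver_idx):
        effect[driver_idx] = spec.effect_delta
    x += np.outer(effect, resistant.astype(float))

    # --- AUC driven by the planted class ---
    auc = AUC_BASE + AUC_EFFECT * resistant + rng.normal(0.0, spec.auc_noise_sd, n)

    # --- interaction network: stochastic block model over planted blocks ---
    edges = _sbm_edges(rng, genes, block_of_gene, spec)

    # --- enrichment terms: one per planted block + random decoys ---
    terms: dict[str, set[str]] = {}
    for b in range(1, n_blocks + 1):
        terms[f"TERM_BLOCK{b:03d}"] = {genes[i] for i in np.where(block_of_gene == b)[0]}
    for d in range(n_blocks):
        size = int(rng.integers(lo, hi + 1))
        terms[f"TERM_DECOY{d:03d}"] = set(
            np.array(genes)[rng.choice(g, size=size, replace=False)]
        )

    truth = SyntheticGroundTruth(
        driver_pathway_ids=driver_pids,
        driver_gene_ids=driver_genes,
        planted_module_of_gene={genes[i]: int(block_of_gene[i]) for i in range(g)},
        true_effect_per_gene={gid: float(effect[genes.index(gid)]) for gid in driver_genes},
        driver_term_ids=[f"TERM_BLOCK{b:03d}" for b in range(1, spec.n_driver_pathways + 1)],
        resistant_samples=[samples[j] for j in np.where(resistant)[0]],
    )
    return SyntheticBundle(
        expression=ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples)),
        response=DrugResponseTable(pd.DataFrame({"sample_id": samples, "auc": auc})),
        pathways=GeneSetCollection(pathway_sets),
        enrichment_terms=GeneSetCollection(terms),
        interactions=edges,
        truth=truth,
    )


def _sbm_edges(
    rng: np.random.Generator, genes, block_of_gene: np.ndarray, spec: SyntheticSpec
) -> InteractionEdgeList:
    """Stochastic block model restricted to planted blocks: within-block
    pairs connect with ``block_p_in`` and scores in ``score_range``;
    between-block pairs (among planted genes) with ``block_p_out`` and
    scores below the 0.4 threshold.  Background genes stay unconnected."""
    planted = np.where(block_of_gene > 0)[0]
    rows = []
    for ai in range(len(planted)):
        i = planted[ai]
        for j in planted[ai + 1 :]:
            same = block_of_gene[i] == block_of_gene[j]
            p = spec.block_p_in if same else spec.block_p_out
            if rng.random() < p:
                lo, hi = spec.score_range if same else spec.between_score_range
                rows.append(
                    {
                        "gene_a": genes[i],
                        "gene_b": genes[j],
                        "combined_score": float(rng.uniform(lo, hi)),
                    }
                )
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])
    return InteractionEdgeList(df)


def write_fixture(bundle: SyntheticBundle, out_dir) -> dict[str, Path]:
    """Write the bundle in the pipeline's external formats; the returned
    paths load back unchanged through the I/O layer."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "response": out / "response.csv",
        "pathways": out / "pathways.gmt",
        "enrichment_terms": out / "enrichment_terms.gmt",
        "interactions": out / "interactions.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_expression(bundle.expression, paths["expression"])
    bundle.response.table.to_csv(paths["response"], index=False, float_format="%.17g")
    _write_gmt(bundle.pathways, paths["pathways"])
    _write_gmt(bundle.enrichment_terms, paths["enrichment_terms"])
    bundle.interactions.edges.to_csv(
        paths["interactions"], sep="\t", index=False, float_format="%.17g"
    )
    with open(paths["ground_truth"], "w") as fh:
        json.dump(asdict(bundle.truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, members in collection:
            desc = collection.descriptions.get(sid, "na")
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def load_ground_truth(path) -> SyntheticGroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SyntheticGroundTruth(**d)
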