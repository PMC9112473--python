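"""Interaction-network module construction.

A weighted adjacency matrix is built from protein--protein interaction
edges restricted to the genes of interest (edges below the combined-score
threshold, 0.4 by default, are removed).  The topological overlap measure
(TOM) turns direct plus shared-neighbor connectivity into a similarity,

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj,   k_i = sum_u a_iu,

and genes are partitioned into mutually exclusive modules by hierarchical
clustering of the dissimilarity 1 - omega.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import InteractionEdgeList, ValidationError

log = logging.getLogger(__name__)

UNASSIGNED_MODULE = 0


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    a: np.ndarray  # symmetric, zero diagonal, entries in {0} u [threshold, 1]


@dataclass
class TomMatrix:
    gene_ids: list[str]
    omega: np.ndarray  # symmetric in [0, 1], unit diagonal

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.omega


@dataclass
class ModulePartition:
    """gene -> module id; module 0 pools genes whose cluster fell below the
    minimum module size (including interaction-less genes)."""

    assignments: pd.Series  # index gene_id, values int module ids

    def module_genes(self, module_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == module_id])

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.assignments))

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def build_adjacency(
    edges: InteractionEdgeList, genes, threshold: float = 0.4, *, binarize: bool = False
) -> AdjacencyMatrix:
    """Weighted adjacency over ``genes`` keeping edges with combined score
    >= threshold.  ``binarize`` replaces surviving scores by 1."""
    genes = sorted(set(genes))
    if not genes:
        raise ValidationError("empty gene set for adjacency")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    a = np.zeros((n, n))
    e = edges.edges
    keep = (
        e["gene_a"].isin(idx)
        & e["gene_b"].isin(idx)
        & (e["combined_score"] >= threshold)
    )
    for ga, gb, s in e.loc[keep].itertuples(index=False):
        i, j = idx[ga], idx[gb]
        w = 1.0 if binarize else float(s)
        a[i, j] = a[j, i] = w
    return AdjacencyMatrix(genes, a)


def topological_overlap(adj: AdjacencyMatrix) -> TomMatrix:
    """Standard (unsigned) topological overlap of a weighted adjacency.

    Isolated gene pairs get omega 0 (denominator 1); the diagonal is 1 by
    definition so the dissimilarity diagonal is 0.
    """
    a = adj.a
    l = a @ a  # a_ii = 0, so the u = i, j terms vanish automatically
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    omega = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(omega, 1.0)
    return TomMatrix(adj.gene_ids, omega)


def cluster_modules(
    tom: TomMatrix,
    *,
    linkage_method: str = "average",
    cut: str = "height",
    cut_value: float = 0.95,
    min_module_size: int = 5,
) -> ModulePartition:
    """Agglomerative clustering of 1 - omega into mutually exclusive modules.

    ``cut='height'`` cuts the tree at dissimilarity ``cut_value``;
    ``cut='n_clusters'`` asks for that many clusters.  Clusters smaller
    than ``min_module_size`` are pooled into module 0; surviving modules
    are relabeled 1..M by decreasing size (ties by smallest member gene id
    for deterministic output).
    """
    if linkage_method not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    n = len(tom.gene_ids)
    if n < 2:
        raise ValidationError("clustering needs >=2 genes")
    d = tom.dissimilarity.copy()
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against fp noise
    z = linkage(squareform(d, checks=False), method=linkage_method)
    if cut == "height":
        if not 0 <= cut_value <= d.max() + 1:
            raise ValueError(f"cut_value {cut_value} out of range")
        raw = fcluster(z, t=cut_value, criterion="distance")
    elif cut == "n_clusters":
        if not 1 <= cut_value <= n:
            raise ValueError(f"cut_value {cut_value} out of range for n_clusters")
        raw = fcluster(z, t=int(cut_value), criterion="maxclust")
    else:
        raise ValueError(f"unknown cut mode {cut!r}")

    genes = np.array(tom.gene_ids)
    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_module_size]
    # order modules by decreasing size, ties by smallest member gene id
    order = sorted(
        big, key=lambda c: (-int(sizes[c]), min(genes[raw == c]))
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    assigned = np.array([relabel.get(c, UNASSIGNED_MODULE) for c in raw])
    n_pooled = int((assigned == UNASSIGNED_MODULE).sum())
    if n_pooled:
        log.info("pooled %d genes from undersized clusters into module 0", n_pooled)
    return ModulePartition(pd.Series(assigned, index=list(genes), name="module_id"))


def module_table(partition: ModulePartition, tom: TomMatrix) -> pd.DataFrame:
    """Per-gene module summary: module id/size, weighted degree and mean
    within-module topological overlap."""
    idx = {g: i for i, g in enumerate(tom.gene_ids)}
    omega = tom.omega
    degree = omega.sum(axis=1) - 1.0  # exclude the unit diagonal
    sizes = partition.sizes()
    rows = []
    for g, mod in partition.assignments.items():
        i = idx[g]
        members = [idx[h] for h in partition.module_genes(mod) if h != g]
        mean_intra = float(np.mean(omega[i, members])) if members else 0.0
        rows.append(
            {
                "gene_id": g,
                "module_id": int(mod),
                "module_size": int(sizes[mod]),
                "degree": float(degree[i]),
                "mean_intra_omega": mean_intra,
            }
        )
    return pd.DataFrame(rows)
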