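"""Condition-responsive pathway-activity scoring.

Samples are labeled sensitive/resistant from their drug-response AUC.
Expression is z-normalized per gene across the labeled samples, and each
pathway receives an activity vector

    a_pj = sum_{i in selected} z_ij / sqrt(k)

where the k member genes are a prefix of the pathway's genes ranked by
their individual t-scores.  The pathway score is the two-sample t statistic
(resistant minus sensitive) of the activity; k is chosen by a greedy prefix
search as the smallest prefix length attaining the maximal |t|.  Pathways
are then filtered either by the two-sided percentile of their score or by
an empirical label-permutation null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DrugResponseTable, ExpressionMatrix, GeneSetCollection, ValidationError

log = logging.getLogger(__name__)

SENSITIVE = "sensitive"
RESISTANT = "resistant"


@dataclass
class ResponseLabels:
    """Binary sensitive/resistant sample labels."""

    labels: pd.Series  # index: sample_id, values in {sensitive, resistant}

    def __post_init__(self) -> None:
        vals = set(self.labels.unique())
        if not vals <= {SENSITIVE, RESISTANT}:
            raise ValidationError(f"unknown labels {vals}")
        n_s = int((self.labels == SENSITIVE).sum())
        n_r = int((self.labels == RESISTANT).sum())
        if n_s == 0 or n_r == 0:
            raise ValidationError(
                f"both classes must be non-empty (sensitive={n_s}, resistant={n_r})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def mask_resistant(self, sample_ids) -> np.ndarray:
        return self.labels.reindex(sample_ids).to_numpy() == RESISTANT

    def counts(self) -> tuple[int, int]:
        """(n_sensitive, n_resistant)."""
        return (
            int((self.labels == SENSITIVE).sum()),
            int((self.labels == RESISTANT).sum()),
        )


@dataclass
class PathwayActivityResult:
    pathway_id: str
    member_genes_ranked: list[str]
    k: int
    activity: pd.Series  # per-sample a_pj
    score: float  # t of activity, resistant - sensitive
    direction: str  # up_in_resistant / down_in_resistant
    n_genes_present: int

    @property
    def selected_genes(self) -> list[str]:
        return self.member_genes_ranked[: self.k]


@dataclass
class PathwayFilterResult:
    pathway_id: str
    score: float
    retained: bool
    p_empirical: float | None = None


def nearest_rank_percentile(values, q: float) -> float:
    """Nearest-rank percentile: the value at sorted rank ceil(q/100 * N)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty input")
    rank = max(1, math.ceil(q / 100.0 * n))
    return float(x[min(rank, n) - 1])


def label_by_auc(
    responses: DrugResponseTable, mode: str = "fixed", cutoff: float = 9.0
) -> ResponseLabels:
    """Label samples sensitive/resistant from their AUC.

    ``fixed``: sensitive iff auc < cutoff (auc == cutoff is resistant).
    ``percentile``: sensitive iff auc <= the cutoff-th nearest-rank
    percentile of the observed AUCs.
    """
    auc = responses.auc
    if mode == "fixed":
        lo, hi = float(auc.min()), float(auc.max())
        if not (lo <= cutoff <= hi):
            log.warning("cutoff %g outside observed AUC range [%g, %g]", cutoff, lo, hi)
        sensitive = auc < cutoff
    elif mode == "percentile":
        thr = nearest_rank_percentile(auc.to_numpy(), cutoff)
        sensitive = auc <= thr
    else:
        raise ValueError(f"unknown labeling mode {mode!r}")
    labels = pd.Series(
        np.where(sensitive, SENSITIVE, RESISTANT), index=auc.index, name="label"
    )
    try:
        return ResponseLabels(labels)
    except ValidationError as exc:
        raise ValidationError(
            f"labeling produced an empty class: {exc} "
            f"(mode={mode}, cutoff={cutoff})"
        ) from exc


def zscore_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-normalize each gene row to mean 0, sd 1 (ddof=1).

    Constant rows carry no discriminative signal and are dropped.
    """
    v = expr.values
    sd = v.std(axis=1, ddof=1)
    keep = sd > 0
    n_const = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError("all gene rows are constant")
    if n_const:
        log.info("dropped %d constant gene rows before z-normalization", n_const)
    v = v.loc[keep]
    z = v.sub(v.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return ExpressionMatrix(z)


def _welch_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Welch t statistic for rows of x (group 1) vs rows of y (group 2),
    oriented group1 - group2."""
    n1, n2 = x.shape[-1], y.shape[-1]
    m1, m2 = x.mean(axis=-1), y.mean(axis=-1)
    v1, v2 = x.var(axis=-1, ddof=1), y.var(axis=-1, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return t


def _pooled_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n1, n2 = x.shape[-1], y.shape[-1]
    m1, m2 = x.mean(axis=-1), y.mean(axis=-1)
    v1, v2 = x.var(axis=-1, ddof=1), y.var(axis=-1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t


def gene_tscores(
    z: ExpressionMatrix, labels: ResponseLabels, *, variant: str = "welch"
) -> pd.Series:
    """Per-gene two-sample t statistic, resistant minus sensitive.

    Genes with zero pooled variance yield NaN and are excluded from the
    returned series (flagged in the log).
    """
    n_s, n_r = labels.counts()
    if n_s < 2 or n_r < 2:
        raise ValidationError(
            f"each class needs >=2 samples (sensitive={n_s}, resistant={n_r})"
        )
    common = [s for s in z.sample_ids if s in set(labels.sample_ids)]
    v = z.values[common].to_numpy()
    res = labels.mask_resistant(common)
    tfun = _welch_t if variant == "welch" else _pooled_t
    t = tfun(v[:, res], v[:, ~res])
    out = pd.Series(t, index=z.gene_ids, name="t")
    bad = ~np.isfinite(out.to_numpy())
    if bad.any():
        log.info("excluded %d genes with degenerate variance from t-scores", bad.sum())
        out = out[~bad]
    return out


def _prefix_scores(zsub: np.ndarray, resistant: np.ndarray) -> np.ndarray:
    """t-score (resistant - sensitive) of the prefix activity for every
    prefix length of the given gene ordering (rows of zsub)."""
    csum = np.cumsum(zsub, axis=0)
    m = np.arange(1, zsub.shape[0] + 1, dtype=float)
    act = csum / np.sqrt(m)[:, None]  # prefix activities, rows = prefix length
    return _welch_t(act[:, resistant], act[:, ~resistant])


def greedy_pathway_activity(
    pathway_id: str,
    pathway_genes,
    z: ExpressionMatrix,
    labels: ResponseLabels,
    *,
    t_variant: str = "welch",
    tscores: pd.Series | None = None,
) -> PathwayActivityResult | None:
    """Greedy condition-responsive gene search for one pathway.

    Member genes present in the matrix are ranked by their individual
    t-scores — ascending when the mean member t is negative, descending
    otherwise — and the activity t-score is evaluated for every prefix.
    Both orderings are searched (the reversed ordering's single-gene prefix
    covers the strongest gene of the opposite sign), the better one wins,
    and k is the smallest prefix length attaining the maximal |t|.

    Returns None when no member gene is present (recorded by the caller).
    """
    gset = set(pathway_genes)
    t_all = gene_tscores(z, labels, variant=t_variant) if tscores is None else tscores
    members = [g for g in t_all.index if g in gset]
    n_absent = len(gset) - len(set(members))
    if not members:
        return None
    if n_absent:
        log.debug("pathway %s: %d member genes absent from matrix", pathway_id, n_absent)

    t_m = t_all[members]
    # deterministic ordering: t value, ties by gene id
    order_df = pd.DataFrame({"t": t_m.to_numpy(), "gene": members})
    asc = order_df.sort_values(["t", "gene"], ascending=[True, True])["gene"].tolist()
    desc = order_df.sort_values(["t", "gene"], ascending=[False, True])["gene"].tolist()
    preferred_desc = float(t_m.mean()) >= 0  # classical mean-t direction rule

    common = [s for s in z.sample_ids if s in set(labels.sample_ids)]
    res = labels.mask_resistant(common)
    zvals = z.values[common]

    best = None  # (abs_t, is_preferred, ordering, prefix_scores, k)
    for ordering, is_pref in ((desc, preferred_desc), (asc, not preferred_desc)):
        scores = _prefix_scores(zvals.loc[ordering].to_numpy(), res)
        finite = np.where(np.isfinite(scores), np.abs(scores), -np.inf)
        k = int(np.argmax(finite)) + 1  # argmax returns first (smallest) maximizer
        cand = (finite[k - 1], is_pref, ordering, scores, k)
        if best is None or cand[:2] > best[:2]:
            best = cand

    _, _, ordering, scores, k = best
    act = zvals.loc[ordering[:k]].to_numpy().sum(axis=0) / math.sqrt(k)
    score = float(scores[k - 1])
    return PathwayActivityResult(
        pathway_id=pathway_id,
        member_genes_ranked=list(ordering),
        k=k,
        activity=pd.Series(act, index=common, name="activity"),
        score=score,
        direction="up_in_resistant" if score >= 0 else "down_in_resistant",
        n_genes_present=len(members),
    )


def score_all_pathways(
    collection: GeneSetCollection,
    z: ExpressionMatrix,
    labels: ResponseLabels,
    *,
    t_variant: str = "welch",
) -> tuple[list[PathwayActivityResult], list[str]]:
    """Score every pathway in input order; pathways with no present gene
    are skipped and returned separately."""
    results: list[PathwayActivityResult] = []
    skipped: list[str] = []
    t_all = gene_tscores(z, labels, variant=t_variant)
    for pid, genes in collection:
        r = greedy_pathway_activity(
            pid, genes, z, labels, t_variant=t_variant, tscores=t_all
        )
        if r is None:
            skipped.append(pid)
            log.warning("pathway %s skipped: no member genes in matrix", pid)
        else:
            results.append(r)
    return results, skipped


def filter_percentile(
    results: list[PathwayActivityResult], tail_pct: float = 10.0
) -> list[PathwayFilterResult]:
    """Retain pathways whose score falls in either tail of the score
    distribution.

    The bottom tail keeps scores <= the tail_pct-th nearest-rank
    percentile; the top tail applies the same rule to the negated scores
    (so both tails keep ceil(tail_pct% * n) pathways and the retained set
    is invariant under score negation).  Retains ~2*tail_pct percent of
    pathways overall.
    """
    if not 0 < tail_pct <= 50:
        raise ValueError("tail_pct must be in (0, 50]")
    scores = np.array([r.score for r in results], dtype=float)
    if len(scores) < 5:
        log.warning("fewer than 5 pathways; retaining all")
        return [PathwayFilterResult(r.pathway_id, r.score, True) for r in results]
    lo = nearest_rank_percentile(scores, tail_pct)
    hi = -nearest_rank_percentile(-scores, tail_pct)
    return [
        PathwayFilterResult(r.pathway_id, r.score, bool(r.score <= lo or r.score >= hi))
        for r in results
    ]


def filter_permutation(
    collection: GeneSetCollection,
    z: ExpressionMatrix,
    labels: ResponseLabels,
    *,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    t_variant: str = "welch",
) -> list[PathwayFilterResult]:
    """Label-permutation null for pathway scores.

    Each permutation shuffles the sample labels and re-runs the full greedy
    search; the empirical p-value uses the add-one estimator
    p = (1 + #{|t*| >= |t|}) / (1 + n_perm), so p >= 1/(1+n_perm) always.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    observed, _ = score_all_pathways(collection, z, labels, t_variant=t_variant)
    if not observed:
        return []

    lab_values = labels.labels.to_numpy().copy()
    index = labels.labels.index
    exceed = {r.pathway_id: 0 for r in observed}
    obs_abs = {r.pathway_id: abs(r.score) for r in observed}
    for _ in range(n_perm):
        while True:  # degenerate shuffles (can't occur with both classes >=1) guard
            rng.shuffle(lab_values)
            if len(set(lab_values)) == 2:
                break
        perm_labels = ResponseLabels(pd.Series(lab_values, index=index, name="label"))
        perm_results, _ = score_all_pathways(
            collection, z, perm_labels, t_variant=t_variant
        )
        for r in perm_results:
            if abs(r.score) >= obs_abs.get(r.pathway_id, np.inf):
                exceed[r.pathway_id] += 1

    out = []
    for r in observed:
        p = (1 + exceed[r.pathway_id]) / (1 + n_perm)
        out.append(PathwayFilterResult(r.pathway_id, r.score, p <= alpha, p))
    return out


def activity_table(
    results: list[PathwayActivityResult],
    filtered: list[PathwayFilterResult] | None = None,
) -> pd.DataFrame:
    """Tidy per-pathway summary table (one row per scored pathway)."""
    fmap = {f.pathway_id: f for f in (filtered or [])}
    rows = []
    for r in results:
        f = fmap.get(r.pathway_id)
        rows.append(
            {
                "pathway_id": r.pathway_id,
                "n_genes_present": r.n_genes_present,
                "k": r.k,
                "score": r.score,
                "direction": r.direction,
                "retained": f.retained if f else pd.NA,
                "p_empirical": f.p_empirical if f and f.p_empirical is not None else pd.NA,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "n_genes_present",
            "k",
            "score",
            "direction",
            "retained",
            "p_empirical",
        ],
    )
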