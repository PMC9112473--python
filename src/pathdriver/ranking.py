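"""Feature selection and ranking.

Two stages sit between network modules and module importance:

1. Per-module all-relevant selection with shadow features (the Boruta
   scheme): each real feature competes against the best of shuffled
   "shadow" copies inside a random-forest classifier; hits accumulate over
   runs and one-sided binomial tests (hit probability 0.5, Bonferroni
   corrected over undecided features) confirm or reject features.  Only
   Confirmed genes advance.

2. Recursive feature elimination with a linear SVM over the pooled
   Confirmed genes: at each iteration the feature with the smallest squared
   weight is removed; the rank of a feature is inversely related to its
   removal iteration (the last survivor has rank 1).  Ranks are averaged
   over stratified k-fold (or leave-one-out) cross-validation, and each
   module's importance is the minimum average rank among its members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .activity import ResponseLabels
from .io import ExpressionMatrix, ValidationError
from .network import ModulePartition

log = logging.getLogger(__name__)

CONFIRMED = "Confirmed"
REJECTED = "Rejected"
TENTATIVE = "Tentative"


@dataclass
class BorutaDecision:
    gene_id: str
    module_id: int
    decision: str
    n_hits: int
    n_runs: int


@dataclass
class FeatureRankTable:
    """Cross-validation-averaged RFE ranks.

    ``per_fold_ranks`` is features x folds; within each fold the column is
    a permutation of 1..n_features.
    """

    gene_ids: list[str]
    module_ids: list[int]
    per_fold_ranks: np.ndarray
    avg_rank: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "module_id": self.module_ids,
                "avg_rank": self.avg_rank,
                "per_fold_ranks": [
                    ",".join(str(int(r)) for r in row) for row in self.per_fold_ranks
                ],
            }
        ).sort_values("avg_rank", kind="stable").reset_index(drop=True)


@dataclass
class CvErrorCurve:
    """Held-out misclassification error of the SVM refit on the top-m
    ranked features, for m = 1..N, against the no-information rate."""

    n_features: np.ndarray
    cv_error: np.ndarray
    no_information_rate_error: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": self.n_features,
                "cv_error": self.cv_error,
                "nir_error": self.no_information_rate_error,
            }
        )


def _design(z: ExpressionMatrix, labels: ResponseLabels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Samples x features matrix and 0/1 response (1 = resistant)."""
    common = [s for s in z.sample_ids if s in set(labels.sample_ids)]
    x = z.values[common].to_numpy().T
    y = labels.mask_resistant(common).astype(int)
    return x, y, common


def boruta_select(
    z_module: ExpressionMatrix,
    labels: ResponseLabels,
    *,
    module_id: int = 0,
    max_runs: int = 100,
    p_value: float = 0.01,
    n_trees: int = 100,
    importance: str = "impurity",
    seed=None,
) -> list[BorutaDecision]:
    """Shadow-feature selection for one module's genes.

    Each run appends an independently shuffled shadow copy of every active
    (non-rejected) feature, fits a random forest, and credits a hit to
    every real feature whose importance exceeds the maximum shadow
    importance.  After each run, features are Confirmed (Rejected) when the
    one-sided binomial tail P(X >= hits) (P(X <= hits)) under p = 0.5,
    Bonferroni-corrected over features still undecided, falls below
    ``p_value``.  Features still undecided after ``max_runs`` are
    Tentative.  A single-gene module is degenerate for the shadow
    comparison and its gene is returned Tentative with a warning.
    """
    genes = z_module.gene_ids
    if len(genes) < 2:
        log.warning(
            "module %s has a single gene; shadow comparison degenerate -> Tentative",
            module_id,
        )
        return [BorutaDecision(genes[0], module_id, TENTATIVE, 0, 0)] if genes else []
    x, y, _ = _design(z_module, labels)
    n_s = int((y == 0).sum())
    n_r = int((y == 1).sum())
    if min(n_s, n_r) < 5:
        raise ValidationError(
            f"both classes need >=5 samples (sensitive={n_s}, resistant={n_r})"
        )
    if importance not in ("impurity", "permutation"):
        raise ValueError(f"unknown importance {importance!r}")

    rng = np.random.default_rng(seed)
    p = len(genes)
    hits = np.zeros(p, dtype=int)
    decision = np.array([TENTATIVE] * p, dtype=object)
    n_runs = np.zeros(p, dtype=int)

    for run in range(1, max_runs + 1):
        active = decision != REJECTED  # confirmed features stay in the model
        if not (decision == TENTATIVE).any():
            break
        xa = x[:, active]
        shadows = xa.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        design = np.hstack([xa, shadows])
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(design, y)
        if importance == "impurity":
            imp = rf.feature_importances_
        else:
            from sklearn.inspection import permutation_importance

            imp = permutation_importance(
                rf, design, y, n_repeats=5,
                random_state=int(rng.integers(2**31 - 1)),
            ).importances_mean
        n_active = xa.shape[1]
        shadow_max = imp[n_active:].max()
        real_imp = imp[:n_active]
        idx_active = np.where(active)[0]
        tentative_active = decision[idx_active] == TENTATIVE
        hit_now = real_imp > shadow_max
        hits[idx_active[tentative_active]] += hit_now[tentative_active]
        n_runs[decision == TENTATIVE] += 1

        undecided = np.where(decision == TENTATIVE)[0]
        m = len(undecided)
        for i in undecided:
            p_conf = stats.binom.sf(hits[i] - 1, n_runs[i], 0.5)
            p_rej = stats.binom.cdf(hits[i], n_runs[i], 0.5)
            if p_conf * m < p_value:
                decision[i] = CONFIRMED
            elif p_rej * m < p_value:
                decision[i] = REJECTED

    return [
        BorutaDecision(g, module_id, str(decision[i]), int(hits[i]), int(n_runs[i]))
        for i, g in enumerate(genes)
    ]


def boruta_select_modules(
    z: ExpressionMatrix,
    partition: ModulePartition,
    labels: ResponseLabels,
    *,
    max_runs: int = 100,
    p_value: float = 0.01,
    n_trees: int = 100,
    seed=None,
) -> list[BorutaDecision]:
    """Run the shadow-feature selection separately for every module
    (including the pooled module 0) with per-module seed substreams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    decisions: list[BorutaDecision] = []
    module_ids = partition.module_ids
    children = ss.spawn(len(module_ids))
    for mod, child in zip(module_ids, children):
        genes = [g for g in partition.module_genes(mod) if g in set(z.gene_ids)]
        if not genes:
            continue
        decisions.extend(
            boruta_select(
                z.subset_genes(genes),
                labels,
                module_id=mod,
                max_runs=max_runs,
                p_value=p_value,
                n_trees=n_trees,
                seed=child,
            )
        )
    return decisions


def _rfe_order(x_tr: np.ndarray, y_tr: np.ndarray, C: float) -> np.ndarray:
    """Removal-based ranks for one training split: rank 1 = last survivor.

    The training split is standardized with its own mean/sd (constant
    features get sd 1, hence weight ~0 and early removal).
    """
    mu = x_tr.mean(axis=0)
    sd = x_tr.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xs = (x_tr - mu) / sd
    n = xs.shape[1]
    remaining = list(range(n))
    ranks = np.empty(n, dtype=int)
    for it in range(1, n + 1):
        if len(remaining) == 1:
            ranks[remaining[0]] = 1
            break
        svm = SVC(kernel="linear", C=C)
        svm.fit(xs[:, remaining], y_tr)
        w2 = np.asarray(svm.coef_).ravel() ** 2
        drop = int(np.argmin(w2))  # first minimum: deterministic tie-break
        ranks[remaining[drop]] = n - it + 1
        del remaining[drop]
    return ranks


def svm_rfe_rank(
    z_confirmed: ExpressionMatrix,
    labels: ResponseLabels,
    *,
    module_of_gene: dict[str, int] | None = None,
    cv: str = "kfold",
    k: int = 10,
    C: float = 1.0,
    seed=None,
) -> tuple[FeatureRankTable, CvErrorCurve]:
    """SVM recursive feature elimination with cross-validation-averaged
    ranks and a held-out error curve.

    ``cv='kfold'`` uses stratified ``k``-fold CV; ``cv='loocv'`` uses
    leave-one-out.  Within each fold, features are standardized with the
    training split's statistics, eliminated one per iteration by smallest
    squared SVM weight, and the error curve entry for m features is the
    held-out misclassification using that fold's top-m ranked features,
    pooled over folds.
    """
    genes = z_confirmed.gene_ids
    if len(genes) < 2:
        raise ValidationError("SVM-RFE needs >=2 confirmed features")
    x, y, _ = _design(z_confirmed, labels)
    n, p = x.shape

    if cv == "kfold":
        n_min = int(np.bincount(y).min())
        if n_min < k:
            raise ValidationError(
                f"stratified {k}-fold impossible: smallest class has {n_min} samples"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=_to_int_seed(seed))
        splits = list(splitter.split(x, y))
    elif cv == "loocv":
        splits = list(LeaveOneOut().split(x, y))
    else:
        raise ValueError(f"unknown cv mode {cv!r}")

    fold_ranks = np.empty((p, len(splits)), dtype=int)
    errors = np.zeros(p)  # misclassified held-out samples when using top-m
    n_held = 0
    for f, (tr, te) in enumerate(splits):
        y_tr, y_te = y[tr], y[te]
        if len(np.unique(y_tr)) < 2:
            raise ValidationError("a training fold lost a class")
        ranks = _rfe_order(x[tr], y_tr, C)
        fold_ranks[:, f] = ranks
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xs_tr = (x[tr] - mu) / sd
        xs_te = (x[te] - mu) / sd
        order = np.argsort(ranks, kind="stable")  # rank 1 first
        for m in range(1, p + 1):
            feats = order[:m]
            svm = SVC(kernel="linear", C=C)
            svm.fit(xs_tr[:, feats], y_tr)
            errors[m - 1] += int((svm.predict(xs_te[:, feats]) != y_te).sum())
        n_held += len(te)

    avg_rank = fold_ranks.mean(axis=1)
    nir_error = 1.0 - np.bincount(y).max() / n
    table = FeatureRankTable(
        gene_ids=list(genes),
        module_ids=[(module_of_gene or {}).get(g, -1) for g in genes],
        per_fold_ranks=fold_ranks,
        avg_rank=avg_rank,
    )
    curve = CvErrorCurve(
        n_features=np.arange(1, p + 1),
        cv_error=errors / n_held,
        no_information_rate_error=float(nir_error),
    )
    return table, curve


@dataclass
class ModuleRanking:
    table: pd.DataFrame  # module_id, position, min_member_rank, n_confirmed


def rank_modules(ranks: FeatureRankTable, partition: ModulePartition) -> ModuleRanking:
    """Module importance = minimum average rank over its ranked genes.

    Modules are ordered by increasing minimum rank; ties prefer the module
    with more confirmed genes, then the smaller module id.  Modules with no
    ranked (Confirmed) gene are excluded.
    """
    assign = partition.assignments
    rows = []
    df = pd.DataFrame(
        {"gene_id": ranks.gene_ids, "avg_rank": ranks.avg_rank}
    )
    df["module_id"] = [assign.get(g, -1) for g in df["gene_id"]]
    missing = df["module_id"] == -1
    if missing.any():
        raise ValidationError(
            f"{int(missing.sum())} ranked genes have no module assignment"
        )
    for mod, grp in df.groupby("module_id"):
        rows.append(
            {
                "module_id": int(mod),
                "min_member_rank": float(grp["avg_rank"].min()),
                "n_confirmed": int(len(grp)),
            }
        )
    excluded = set(partition.module_ids) - {r["module_id"] for r in rows}
    if excluded:
        log.info("modules without confirmed genes excluded from ranking: %s", sorted(excluded))
    out = pd.DataFrame(rows).sort_values(
        by=["min_member_rank", "n_confirmed", "module_id"],
        ascending=[True, False, True],
        kind="stable",
    )
    out["position"] = np.arange(1, len(out) + 1)
    return ModuleRanking(
        out[["module_id", "position", "min_member_rank", "n_confirmed"]].reset_index(
            drop=True
        )
    )


def decisions_frame(decisions: list[BorutaDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": d.gene_id,
                "module_id": d.module_id,
                "decision": d.decision,
                "n_hits": d.n_hits,
                "n_runs": d.n_runs,
            }
            for d in decisions
        ],
        columns=["gene_id", "module_id", "decision", "n_hits", "n_runs"],
    )


def _to_int_seed(seed) -> int | None:
    if seed is None or isinstance(seed, (int, np.integer)):
        return None if seed is None else int(seed) % (2**31 - 1)
    return int(np.random.default_rng(seed).integers(2**31 - 1))
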