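"""Gene-set enrichment and baseline comparator analyses.

Enrichment is the one-sided hypergeometric (over-representation) test of a
query gene set against a gene-set collection within a stated universe,
with Holm step-down family-wise-error correction across terms.  The
comparators mirror the simpler analyses a module-based method is judged
against: a per-gene Welch t-test screen (Holm-significant at 0.1), drug
ranking by mean absolute deviation of AUC, and drug--drug Pearson response
correlation on shared samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import ResponseLabels, gene_tscores
from .io import ExpressionMatrix, GeneSetCollection, ValidationError

log = logging.getLogger(__name__)


def enrich(
    query,
    universe,
    terms: GeneSetCollection,
    min_term: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    p_raw = P(X >= overlap) with population |universe|, successes
    |term & universe|, draws |query|; p_holm is the Holm step-down
    adjustment over all tested terms.  Terms are intersected with the
    universe first; terms smaller than ``min_term`` (after intersection)
    are dropped.  Rows are sorted by p_raw.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValidationError("empty query gene set")
    if not query <= universe:
        raise ValidationError(
            f"{len(query - universe)} query genes outside the universe"
        )
    rows = []
    for tid, genes in terms:
        t = genes & universe
        if len(t) < min_term:
            continue
        overlap = len(query & t)
        p_raw = float(stats.hypergeom.sf(overlap - 1, len(universe), len(t), len(query)))
        rows.append(
            {"term_id": tid, "term_size": len(t), "overlap": overlap, "p_raw": p_raw}
        )
    if not rows:
        return pd.DataFrame(columns=["term_id", "term_size", "overlap", "p_raw", "p_holm"])
    df = pd.DataFrame(rows)
    df["p_holm"] = multipletests(df["p_raw"].to_numpy(), method="holm")[1]
    return df.sort_values(["p_raw", "term_id"], kind="stable").reset_index(drop=True)


def ttest_screen(
    z: ExpressionMatrix, labels: ResponseLabels, alpha_holm: float = 0.1
) -> pd.DataFrame:
    """Per-gene Welch t-test screen with Holm correction.

    Significant genes are those with Holm-adjusted p below ``alpha_holm``
    (0.1 by default, the conventional screen threshold for this
    comparator).
    """
    t = gene_tscores(z, labels)
    n_s, n_r = labels.counts()
    common = [s for s in z.sample_ids if s in set(labels.sample_ids)]
    v = z.values.loc[t.index, common].to_numpy()
    res = labels.mask_resistant(common)
    # Welch p-values via scipy for exact df handling
    _, p = stats.ttest_ind(v[:, res], v[:, ~res], axis=1, equal_var=False)
    p_holm = multipletests(p, method="holm")[1]
    return pd.DataFrame(
        {
            "gene_id": t.index,
            "t": t.to_numpy(),
            "p_raw": p,
            "p_holm": p_holm,
            "significant": p_holm < alpha_holm,
        }
    ).reset_index(drop=True)


def drug_variability(auc_by_drug: pd.DataFrame) -> pd.DataFrame:
    """Rank drugs by the mean absolute deviation of their AUC (descending).

    ``auc_by_drug`` is samples x drugs; missing entries are allowed and
    ignored per drug.  Drugs with fewer than 2 observed samples are
    excluded and logged.
    """
    rows = []
    for drug in auc_by_drug.columns:
        v = auc_by_drug[drug].dropna().to_numpy(dtype=float)
        if len(v) < 2:
            log.info("drug %s excluded from variability ranking (<2 samples)", drug)
            continue
        rows.append({"drug": drug, "n": len(v), "mad_auc": float(np.abs(v - v.mean()).mean())})
    return (
        pd.DataFrame(rows, columns=["drug", "n", "mad_auc"])
        .sort_values("mad_auc", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def response_correlation(auc_a: pd.Series, auc_b: pd.Series) -> float:
    """Pearson correlation of two drugs' AUC over their shared samples."""
    shared = auc_a.index.intersection(auc_b.index)
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared samples (need >=3)")
    r, _ = stats.pearsonr(auc_a[shared].to_numpy(), auc_b[shared].to_numpy())
    return float(r)
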