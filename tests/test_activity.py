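import math

import numpy as np
import pandas as pd
import pytest

from pathdriver import activity
from pathdriver.activity import (
    PathwayActivityResult,
    filter_percentile,
    filter_permutation,
    gene_tscores,
    greedy_pathway_activity,
    label_by_auc,
    nearest_rank_percentile,
    score_all_pathways,
    zscore_rows,
)
from pathdriver.io import DrugResponseTable, GeneSetCollection, ValidationError

from conftest import make_expr, make_labels


def _responses(aucs):
    return DrugResponseTable(
        pd.DataFrame({"sample_id": [f"S{i}" for i in range(len(aucs))], "auc": aucs})
    )


def brute_force_greedy(t_member: pd.Series, zvals: pd.DataFrame, resistant: np.ndarray):
    """Independent oracle: enumerate every prefix of both t-orderings and
    return the best |t| of the prefix activity (ties -> smallest k of the
    mean-t-preferred ordering)."""
    from scipy import stats as sps

    asc = t_member.sort_values(kind="stable").index.tolist()
    desc = t_member.sort_values(ascending=False, kind="stable").index.tolist()
    prefer_desc = t_member.mean() >= 0
    best = None
    for ordering, pref in ((desc, prefer_desc), (asc, not prefer_desc)):
        for k in range(1, len(ordering) + 1):
            a = zvals.loc[ordering[:k]].to_numpy().sum(axis=0) / math.sqrt(k)
            t = sps.ttest_ind(a[resistant], a[~resistant], equal_var=False).statistic
            cand = (abs(t), pref, -k)
            if best is None or cand > best[0]:
                best = (cand, t, k, ordering)
    return best[1], best[2]


class TestLabeling:
    def test_fixed_cutoff(self):
        labels = label_by_auc(_responses([8.5, 9.5, 10.0, 2.0]), "fixed", 9.0)
        assert labels.labels["S0"] == "sensitive"
        assert labels.labels["S1"] == "resistant"

    def test_boundary_is_resistant(self):
        labels = label_by_auc(_responses([9.0, 1.0]), "fixed", 9.0)
        assert labels.labels["S0"] == "resistant"

    def test_percentile_mode_counts(self):
        labels = label_by_auc(_responses(list(range(1, 101))), "percentile", 5.0)
        assert (labels.labels == "sensitive").sum() == 5

    def test_empty_class_raises_with_counts(self):
        with pytest.raises(ValidationError, match="class"):
            label_by_auc(_responses([1.0, 2.0]), "fixed", 0.5)


class TestZscore:
    def test_simple_row(self):
        z = zscore_rows(make_expr(np.array([[1.0, 2.0, 3.0]])))
        np.testing.assert_allclose(z.values.to_numpy()[0], [-1, 0, 1], atol=1e-12)

    def test_constant_row_dropped(self):
        z = zscore_rows(make_expr(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])))
        assert z.gene_ids == ["G1"]

    def test_rows_standardized(self, rng):
        z = zscore_rows(make_expr(rng.normal(size=(30, 8))))
        v = z.values.to_numpy()
        np.testing.assert_allclose(v.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(v.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_all_constant_rejected(self):
        with pytest.raises(ValidationError):
            zscore_rows(make_expr(np.ones((3, 4))))


class TestGeneTScores:
    def test_hand_computed_welch(self):
        # resistant (4,5,6) vs sensitive (1,2,3): t = 3 / sqrt(2/3) = 3.6742
        expr = make_expr(np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]]))
        t = gene_tscores(expr, make_labels(3, 3))
        assert t["G0"] == pytest.approx(3.6742, abs=5e-5)

    def test_equal_groups_zero(self):
        expr = make_expr(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]))
        t = gene_tscores(expr, make_labels(3, 3))
        assert t["G0"] == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_negates(self, rng):
        expr = make_expr(rng.normal(size=(10, 12)))
        orig = make_labels(5, 7)
        flipped = activity.ResponseLabels(
            orig.labels.map({"sensitive": "resistant", "resistant": "sensitive"})
        )
        t1 = gene_tscores(expr, orig)
        t2 = gene_tscores(expr, flipped)
        np.testing.assert_allclose(t1.to_numpy(), -t2.to_numpy(), atol=1e-10)

    def test_small_class_rejected(self):
        expr = make_expr(np.random.default_rng(0).normal(size=(3, 4)))
        with pytest.raises(ValidationError):
            gene_tscores(expr, make_labels(1, 3))


class TestGreedySearch:
    def test_single_gene_pathway(self, rng):
        z = zscore_rows(make_expr(rng.normal(size=(5, 20))))
        labels = make_labels(10, 10)
        t = gene_tscores(z, labels)
        r = greedy_pathway_activity("P", {"G2"}, z, labels)
        assert r.k == 1
        assert r.score == pytest.approx(t["G2"], abs=1e-10)
        np.testing.assert_allclose(
            r.activity.to_numpy(), z.values.loc["G2"].to_numpy(), atol=1e-12
        )

    def test_activity_formula_sqrt_k(self):
        # 4 selected genes, a column of z-values all equal to 1 -> 4/sqrt(4) = 2
        assert 4 / math.sqrt(4) == 2.0

    def test_activity_recomputable_from_selected_genes(self, rng):
        z = zscore_rows(make_expr(rng.normal(size=(30, 24))))
        labels = make_labels(12, 12)
        r = greedy_pathway_activity("P", set(z.gene_ids[:12]), z, labels)
        recomputed = z.values.loc[r.selected_genes].to_numpy().sum(axis=0) / math.sqrt(r.k)
        np.testing.assert_allclose(r.activity.to_numpy(), recomputed, atol=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_prefix_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = 30
        z = zscore_rows(make_expr(rng.normal(size=(25, n))))
        labels = make_labels(n // 2, n - n // 2)
        size = int(rng.integers(1, 20))
        genes = list(rng.choice(z.gene_ids, size=size, replace=False))
        r = greedy_pathway_activity("P", genes, z, labels)
        t = gene_tscores(z, labels)
        res = labels.mask_resistant(z.sample_ids)
        t_oracle, k_oracle = brute_force_greedy(t[genes], z.values, res)
        assert abs(r.score) == pytest.approx(abs(t_oracle), abs=1e-9)
        assert r.k == k_oracle
        assert abs(r.score) >= t[genes].abs().max() - 1e-9

    def test_absent_genes_dropped(self, rng):
        z = zscore_rows(make_expr(rng.normal(size=(5, 10))))
        labels = make_labels(5, 5)
        r = greedy_pathway_activity("P", {"G1", "NOT_THERE"}, z, labels)
        assert r.n_genes_present == 1
        assert greedy_pathway_activity("P", {"NOPE"}, z, labels) is None

    def test_score_all_deterministic_and_ordered(self, rng):
        z = zscore_rows(make_expr(rng.normal(size=(40, 20))))
        labels = make_labels(10, 10)
        coll = GeneSetCollection(
            {"A": set(z.gene_ids[:5]), "B": {"MISSING"}, "C": set(z.gene_ids[5:9])}
        )
        res1, skip1 = score_all_pathways(coll, z, labels)
        res2, _ = score_all_pathways(coll, z, labels)
        assert [r.pathway_id for r in res1] == ["A", "C"]
        assert skip1 == ["B"]
        assert [r.score for r in res1] == [r.score for r in res2]


def _fake_results(scores):
    return [
        PathwayActivityResult(f"P{i}", [], 1, pd.Series(dtype=float), s, "up_in_resistant", 1)
        for i, s in enumerate(scores)
    ]


class TestPercentileFilter:
    def test_both_tails_twenty_percent(self, rng):
        scores = rng.normal(size=150)
        assert len(set(scores)) == 150
        out = filter_percentile(_fake_results(scores), tail_pct=10)
        assert sum(f.retained for f in out) == 30

    def test_tail_fifty_retains_all(self, rng):
        out = filter_percentile(_fake_results(rng.normal(size=40)), tail_pct=50)
        assert all(f.retained for f in out)

    def test_negation_symmetry(self, rng):
        for _ in range(10):
            scores = rng.normal(size=int(rng.integers(10, 80)))
            kept = {f.pathway_id for f in filter_percentile(_fake_results(scores), 10) if f.retained}
            kept_neg = {
                f.pathway_id for f in filter_percentile(_fake_results(-scores), 10) if f.retained
            }
            assert kept == kept_neg

    def test_fraction_near_target(self, rng):
        for n in (50, 101, 149):
            scores = rng.normal(size=n)
            out = filter_percentile(_fake_results(scores), tail_pct=10)
            target = math.ceil(0.2 * n)
            assert abs(sum(f.retained for f in out) - target) <= 1

    def test_tiny_input_retains_all(self):
        out = filter_percentile(_fake_results([1.0, 2.0, 3.0]), 10)
        assert all(f.retained for f in out)


class TestPermutationFilter:
    def test_add_one_lower_bound_and_planted_detection(self, rng):
        n = 60
        x = rng.normal(size=(40, n))
        labels = make_labels(n // 2, n - n // 2)
        res = labels.mask_resistant([f"S{j}" for j in range(n)])
        x[:10, res] += 1.5  # planted differential pathway
        z = zscore_rows(make_expr(x))
        coll = GeneSetCollection(
            {"planted": set(z.gene_ids[:10]), "noise": set(z.gene_ids[10:20])}
        )
        out = filter_permutation(coll, z, labels, n_perm=199, alpha=0.05, seed=5)
        by_id = {f.pathway_id: f for f in out}
        assert all(f.p_empirical >= 1 / 200 for f in out)
        assert by_id["planted"].p_empirical == pytest.approx(1 / 200)
        assert by_id["planted"].retained

    def test_nperm_floor(self, rng):
        z = zscore_rows(make_expr(rng.normal(size=(5, 10))))
        with pytest.raises(ValueError):
            filter_permutation(
                GeneSetCollection({"A": {"G0"}}), z, make_labels(5, 5), n_perm=10
            )


def test_nearest_rank_percentile_convention():
    assert nearest_rank_percentile(range(1, 151), 10) == 15
    assert nearest_rank_percentile(range(1, 151), 90) == 135
    assert nearest_rank_percentile([5.0], 50) == 5.0
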