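"""Enrichment statistics against exact and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import comb

from omicsub import characterize as ch


def _bh_oracle(p):
    """Literal step-up definition: q_i = min over j>=rank(i) of p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestBhFdr:
    def test_closed_form(self):
        np.testing.assert_allclose(ch.bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_step_up_oracle(self, pvals):
        np.testing.assert_allclose(ch.bh_fdr(pvals), _bh_oracle(pvals),
                                   atol=1e-12)

    def test_many_random_vectors_match_oracle(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(ch.bh_fdr(p), _bh_oracle(p), atol=1e-12)


class TestEnrichBinary:
    def test_extreme_table_matches_hypergeometric(self):
        labels = np.array([0] * 10 + [1] * 90)
        feat = pd.DataFrame([[1] * 10 + [0] * 90], index=["f"])
        res = ch.enrich_binary(labels, feat)
        p0 = res.loc[(res["cluster"] == 0), "p"].item()
        assert p0 == pytest.approx(1.0 / comb(100, 10), rel=1e-9)

    def test_equal_prevalence_is_null(self):
        labels = np.array([0] * 20 + [1] * 20)
        feat = pd.DataFrame([([1] * 5 + [0] * 15) * 2], index=["f"])
        res = ch.enrich_binary(labels, feat)
        assert (res["p"] == 1.0).all()
        np.testing.assert_allclose(res["odds_ratio"], 1.0)

    def test_absent_feature_flagged(self):
        labels = np.array([0] * 5 + [1] * 5)
        feat = pd.DataFrame([[0] * 10], index=["f"])
        res = ch.enrich_binary(labels, feat)
        assert res["degenerate"].all() and (res["p"] == 1.0).all()


class TestEnrichContinuous:
    def test_identical_distributions_null(self, rng):
        labels = np.repeat([0, 1], 25)
        scores = pd.DataFrame(np.tile(rng.standard_normal(25), 2)[None, :],
                              index=["s"])
        res = ch.enrich_continuous(labels, scores)
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-12)

    def test_matches_direct_welch_formula(self, rng):
        labels = np.repeat([0, 1], 15)
        x = rng.standard_normal(30)
        x[labels == 0] += 1.2
        res = ch.enrich_continuous(labels, pd.DataFrame(x[None, :], index=["s"]))
        a, b = x[labels == 0], x[labels == 1]
        va, vb = a.var(ddof=1) / 15, b.var(ddof=1) / 15
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        got = res.loc[res["cluster"] == 0, "t"].item()
        assert got == pytest.approx(t_hand, rel=1e-9)

    def test_single_sample_side_rejected(self):
        labels = np.array([0] + [1] * 9)
        with pytest.raises(ValueError, match=">= 2 samples"):
            ch.enrich_continuous(labels, pd.DataFrame(np.zeros((1, 10))))


class TestDifferentialExpression:
    def test_null_data_controls_type_i(self, rng):
        hits = []
        for _ in range(50):
            expr = pd.DataFrame(rng.standard_normal((200, 60)))
            labels = np.repeat([0, 1], 30)
            res = ch.differential_expression(expr, labels, 0)
            hits.append(res["significant"].mean())
        assert np.mean(hits) <= 0.01

    def test_planted_two_fold_shift_recovered(self, rng):
        expr = pd.DataFrame(0.7 * rng.standard_normal((500, 60)))
        labels = np.repeat([0, 1], 30)
        expr.iloc[:100, :30] += 1.0  # 2-fold on log2 scale
        res = ch.differential_expression(expr, labels, 0)
        assert res["significant"].iloc[:100].sum() >= 90

    def test_zero_shrinkage_is_plain_t(self, rng):
        expr = pd.DataFrame(rng.standard_normal((50, 20)))
        labels = np.repeat([0, 1], 10)
        res = ch.differential_expression(expr, labels, 0, shrinkage=0.0)
        t_ref, _ = sps.ttest_ind(expr.iloc[:, :10], expr.iloc[:, 10:],
                                 axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t_ref, rtol=1e-9)

    def test_small_cluster_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((10, 5)))
        with pytest.raises(ValueError):
            ch.differential_expression(expr, np.array([0, 1, 1, 1, 1]), 0)


def _brute_force_es(stats, is_hit, p):
    """Independent running-sum enumeration."""
    w = np.abs(stats) ** p
    hit_total = w[is_hit].sum()
    n, m = len(stats), is_hit.sum()
    dev, best = 0.0, 0.0
    for i in range(n):
        if is_hit[i]:
            dev += w[i] / hit_total
        else:
            dev -= 1.0 / (n - m)
        if abs(dev) > abs(best):
            best = dev
    return best


class TestGsea:
    def test_singleton_top_gene_has_es_one(self):
        stats = pd.Series([5.0, 1.0, 0.5, -2.0], index=list("abcd"))
        res = ch.gsea_preranked(stats, ["a"], n_perm=50)
        assert res.es == pytest.approx(1.0)

    def test_matches_brute_force_on_20_gene_universe(self, rng):
        for _ in range(20):
            stats = pd.Series(rng.standard_normal(20),
                              index=[f"g{i:02d}" for i in range(20)])
            genes = list(rng.choice(stats.index, size=5, replace=False))
            res = ch.gsea_preranked(stats, genes, n_perm=10)
            order = stats.sort_index().sort_values(
                ascending=False, kind="mergesort")
            is_hit = np.isin(order.index, genes)
            assert res.es == pytest.approx(
                _brute_force_es(order.to_numpy(), is_hit, 1.0), abs=1e-12)

    def test_permutation_p_respects_lower_bound(self, rng):
        stats = pd.Series(rng.standard_normal(30))
        res = ch.gsea_preranked(stats, list(stats.index[:5]), n_perm=100)
        assert 1.0 / 101 <= res.p <= 1.0

    def test_weight_zero_is_classic_unweighted_ks(self, rng):
        stats = pd.Series(rng.standard_normal(25),
                          index=[f"g{i:02d}" for i in range(25)])
        genes = list(rng.choice(stats.index, size=6, replace=False))
        res = ch.gsea_preranked(stats, genes, weight=0.0, n_perm=10)
        order = stats.sort_index().sort_values(ascending=False, kind="mergesort")
        is_hit = np.isin(order.index, genes)
        # classic KS: every hit weighs 1/m
        assert res.es == pytest.approx(
            _brute_force_es(np.ones(25), is_hit, 1.0), abs=1e-12)

    def test_degenerate_sets_rejected(self):
        stats = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            ch.gsea_preranked(stats, [])
        with pytest.raises(ValueError):
            ch.gsea_preranked(stats, ["a", "b"])


class TestSignatureScore:
    def test_top_ranked_set_scores_maximal_geometry(self, rng):
        expr = pd.DataFrame(
            rng.uniform(1, 10, size=(20, 3)),
            index=[f"g{i:02d}" for i in range(20)],
        )
        sample = expr.columns[0]
        top = expr[sample].sort_values(ascending=False).index[:5]
        scores = ch.signature_score(expr, list(top))
        # compute the maximal score for 5 hits at the top of 20 centered ranks
        ranks = np.arange(20, 0, -1) - 10.5
        is_hit = np.zeros(20, bool)
        is_hit[:5] = True
        assert scores[sample] == pytest.approx(
            _brute_force_es(ranks, is_hit, 1.0))
        # no other placement of the set can beat having all top ranks
        assert scores[sample] == scores.max()

    def test_reversing_ordering_flips_sign(self, rng):
        vals = rng.uniform(1, 100, size=20)
        expr = pd.DataFrame({"fwd": vals, "rev": vals.max() + vals.min() - vals},
                            index=[f"g{i:02d}" for i in range(20)])
        scores = ch.signature_score(expr, [f"g{i:02d}" for i in range(4)])
        assert scores["fwd"] == pytest.approx(-scores["rev"])

    def test_whole_universe_scores_zero(self, rng):
        expr = pd.DataFrame(rng.uniform(1, 5, size=(6, 2)))
        scores = ch.signature_score(expr, list(expr.index))
        np.testing.assert_allclose(scores, 0.0)

    def test_constant_column_scores_zero(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 4.0, 4.0]},
                            index=["a", "b", "c"])
        scores = ch.signature_score(expr, ["a"])
        assert scores["s2"] == 0.0


class TestSignatureThreshold:
    def test_flags_top_fraction(self):
        scores = pd.Series(np.arange(1.0, 101.0),
                           index=[f"s{i:03d}" for i in range(100)])
        calls = ch.signature_threshold(scores, 0.20)
        assert calls.sum() == 20
        assert (scores[calls == 1] >= 81).all()

    def test_ceiling_arithmetic_at_cohort_scale(self, rng):
        scores = pd.Series(rng.standard_normal(514),
                           index=[f"s{i:03d}" for i in range(514)])
        assert ch.signature_threshold(scores, 0.15).sum() == 78

    def test_all_tied_scores_break_by_sample_id(self):
        scores = pd.Series(1.0, index=["s3", "s1", "s2", "s4"])
        calls = ch.signature_threshold(scores, 0.5)
        assert set(calls[calls == 1].index) == {"s1", "s2"}
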