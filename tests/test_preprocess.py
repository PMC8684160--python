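"""Normalization, filtering and genomic-burden statistics against
direct oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsub import preprocess
from omicsub.dataio import CnvSegmentProfile


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestHousekeeping:
    def test_constant_candidates_win(self, rng):
        candidates = [f"hk{i}" for i in range(11)]
        X = rng.uniform(1, 100, size=(11, 6))
        X[:3] = 7.0  # three exactly constant genes
        expr = _expr(X, genes=candidates)
        assert set(preprocess.select_housekeeping(expr, candidates)) == \
            {"hk0", "hk1", "hk2"}

    def test_selection_matches_direct_sd_oracle(self, rng):
        candidates = [f"hk{i:02d}" for i in range(11)]
        expr = _expr(rng.uniform(0.5, 200, size=(11, 6)), genes=candidates)
        sds = np.log2(expr + 1).std(axis=1, ddof=1)
        expected = list(sds.sort_values(kind="mergesort").index[:3])
        assert preprocess.select_housekeeping(expr, candidates) == expected

    def test_ties_resolve_lexicographically(self):
        # hk_b and hk_a tied at third place
        expr = _expr(
            [[1, 1], [2, 2], [3, 5], [3, 5], [1, 50]],
            genes=["hk_c", "hk_d", "hk_b", "hk_a", "hk_e"],
        )
        chosen = preprocess.select_housekeeping(
            expr, ["hk_a", "hk_b", "hk_c", "hk_d", "hk_e"])
        assert chosen == ["hk_c", "hk_d", "hk_a"]

    def test_missing_candidate_listed(self):
        expr = _expr([[1.0, 2.0]], genes=["g1"])
        with pytest.raises(KeyError, match="absent"):
            preprocess.select_housekeeping(expr, ["g1", "nope"])

    def test_normalization_closed_form(self):
        expr = _expr([[1.0], [4.0], [16.0], [10.0]],
                     genes=["hk1", "hk2", "hk3", "g1"])
        out = preprocess.normalize_housekeeping(expr, ["hk1", "hk2", "hk3"])
        # geometric mean of (1, 4, 16) is 4; gene value 10 -> 2.5
        assert out.loc["g1", "s0"] == pytest.approx(2.5)
        assert out.loc["hk2", "s0"] == pytest.approx(1.0)

    def test_post_normalization_geomean_is_one(self, rng):
        hk = ["hk1", "hk2", "hk3"]
        expr = _expr(rng.uniform(0.5, 50, size=(10, 8)),
                     genes=hk + [f"g{i}" for i in range(7)])
        out = preprocess.normalize_housekeeping(expr, hk)
        geo = np.exp(np.log(out.loc[hk]).mean(axis=0))
        np.testing.assert_allclose(geo, 1.0, atol=1e-12)

    def test_zero_housekeeping_value_names_sample(self):
        expr = _expr([[1.0, 0.0], [2.0, 2.0], [3.0, 3.0]],
                     genes=["hk1", "hk2", "hk3"])
        with pytest.raises(ValueError, match="s1"):
            preprocess.normalize_housekeeping(expr, ["hk1", "hk2", "hk3"])


class TestHighVariance:
    def test_order_matches_direct_cv_oracle(self, rng):
        expr = _expr(rng.uniform(0.1, 100, size=(10, 6)))
        cv = (expr.std(axis=1, ddof=1) / expr.mean(axis=1)).sort_values(
            ascending=False, kind="mergesort")
        assert preprocess.select_high_variance(expr, 10) == list(cv.index)

    def test_constant_gene_ranks_last(self, rng):
        X = rng.uniform(1, 10, size=(5, 6))
        X[2] = 3.0
        expr = _expr(X)
        assert preprocess.select_high_variance(expr, 4) == \
            [g for g in preprocess.select_high_variance(expr, 5) if g != "g2"]

    def test_n_top_equal_to_gene_count(self, rng):
        expr = _expr(rng.uniform(1, 10, size=(6, 4)))
        assert len(preprocess.select_high_variance(expr, 6)) == 6
        with pytest.raises(ValueError):
            preprocess.select_high_variance(expr, 7)


class TestSnvFilter:
    def test_prevalence_threshold_is_inclusive(self):
        mut = pd.DataFrame(0, index=["rare", "exact", "common"],
                           columns=[f"s{i}" for i in range(100)])
        mut.iloc[0, :2] = 1    # 2%
        mut.iloc[1, :3] = 1    # exactly 3%
        mut.iloc[2, :50] = 1   # 50%
        kept = preprocess.filter_snv(mut, threshold=0.03)
        assert list(kept.index) == ["exact", "common"]

    def test_empty_result_warns(self):
        mut = pd.DataFrame(0, index=["g1"], columns=[f"s{i}" for i in range(100)])
        mut.iloc[0, 0] = 1
        with pytest.warns(UserWarning):
            kept = preprocess.filter_snv(mut, threshold=0.03)
        assert kept.empty

    def test_idempotent(self, rng):
        mut = pd.DataFrame((rng.random((20, 50)) < 0.1).astype(int))
        once = preprocess.filter_snv(mut)
        pd.testing.assert_frame_equal(preprocess.filter_snv(once), once)


def _loss_profile(segments, genome_size=100_000_000):
    return CnvSegmentProfile("s", segments, genome_size)


class TestLossFraction:
    def test_closed_forms(self):
        assert preprocess.genomic_loss_fraction(_loss_profile([])) == 0.0
        disjoint = _loss_profile([
            ("chr1", 0, 5_000_000, "loss"),
            ("chr2", 0, 5_000_000, "loss"),
            ("chr3", 0, 5_000_000, "gain"),
        ])
        assert preprocess.genomic_loss_fraction(disjoint) == pytest.approx(0.10)
        overlapping = _loss_profile([
            ("chr1", 0, 6_000_000, "loss"),
            ("chr1", 4_000_000, 10_000_000, "loss"),
        ])
        assert preprocess.genomic_loss_fraction(overlapping) == pytest.approx(0.10)

    def test_matches_per_base_union_oracle(self, rng):
        # small genome with kb resolution so the per-base oracle is cheap
        genome_size = 10_000
        for _ in range(20):
            segs = []
            covered = np.zeros(genome_size, bool)
            for _ in range(rng.integers(0, 8)):
                s = int(rng.integers(0, genome_size - 1))
                e = int(rng.integers(s + 1, genome_size))
                call = rng.choice(["loss", "neutral", "gain"])
                segs.append(("chr1", s, e, call))
                if call == "loss":
                    covered[s:e] = True
            got = preprocess.genomic_loss_fraction(
                CnvSegmentProfile("s", segs, genome_size))
            assert got == pytest.approx(covered.mean(), abs=1e-12)

    @given(st.lists(
        st.tuples(st.integers(0, 999), st.integers(1, 1000)).map(
            lambda t: (min(t), max(t)) if t[0] != t[1] else (t[0], t[1] + 1)),
        min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_splitting_a_segment_leaves_value_unchanged(self, intervals):
        segs = [("chr1", s, e, "loss") for s, e in intervals]
        base = preprocess.genomic_loss_fraction(
            CnvSegmentProfile("s", segs, 1000))
        s0, e0 = intervals[0]
        mid = (s0 + e0) // 2
        split = segs[1:] + [("chr1", s0, mid, "loss")] if mid > s0 else segs[1:]
        if mid < e0:
            split.append(("chr1", mid, e0, "loss"))
        again = preprocess.genomic_loss_fraction(
            CnvSegmentProfile("s", split[::-1], 1000))
        assert again == pytest.approx(base, abs=1e-12)

    def test_bad_genome_size(self):
        with pytest.raises(ValueError):
            CnvSegmentProfile("s", [], 0)


class TestCytobandAggregation:
    bands = pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "start": [0, 1000],
        "end": [1000, 2000],
        "band": ["chr1_b1", "chr1_b2"],
    })

    def test_full_loss_and_majority_rule(self):
        profiles = {
            "sA": CnvSegmentProfile("sA", [("chr1", 0, 1000, "loss"),
                                           ("chr1", 1000, 1600, "loss")], 2000),
            "sB": CnvSegmentProfile("sB", [("chr1", 1200, 2000, "gain")], 2000),
        }
        states, loss_ind, gain_ind = preprocess.aggregate_cnv_to_cytobands(
            profiles, self.bands)
        assert states.loc["chr1_b1", "sA"] == 1
        assert loss_ind.loc["chr1_b1", "sA"] == 1
        # band 2 for sA: 60% loss / 40% uncovered-neutral -> loss
        assert states.loc["chr1_b2", "sA"] == 1
        # band 2 for sB: 80% gain -> gain; band 1 untouched -> neutral
        assert states.loc["chr1_b2", "sB"] == 3
        assert states.loc["chr1_b1", "sB"] == 2
        assert gain_ind.loc["chr1_b2", "sB"] == 1

    def test_exact_tie_resolves_to_lower_state(self):
        profiles = {"s": CnvSegmentProfile(
            "s", [("chr1", 0, 500, "loss"), ("chr1", 500, 1000, "gain")], 2000)}
        states, _, _ = preprocess.aggregate_cnv_to_cytobands(profiles, self.bands)
        assert states.loc["chr1_b1", "s"] == 1

    def test_matches_per_base_majority_oracle(self, rng):
        n_bands, band_len = 6, 100
        bands = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n_bands) * band_len,
            "end": (np.arange(n_bands) + 1) * band_len,
            "band": [f"b{i}" for i in range(n_bands)],
        })
        genome = n_bands * band_len
        code = {"loss": 1, "neutral": 2, "gain": 3}
        for _ in range(10):
            segs = []
            per_base = {}
            for _ in range(rng.integers(1, 6)):
                s = int(rng.integers(0, genome - 1))
                e = int(rng.integers(s + 1, genome))
                call = str(rng.choice(["loss", "neutral", "gain"]))
                segs.append(("chr1", s, e, call))
            profiles = {"s": CnvSegmentProfile("s", segs, genome)}
            states, _, _ = preprocess.aggregate_cnv_to_cytobands(profiles, bands)
            # brute-force per-base tally: each base counts once per
            # covering segment, uncovered bases count as neutral
            for i in range(n_bands):
                counts = {"loss": 0, "neutral": 0, "gain": 0}
                uncovered = 0
                for b in range(i * band_len, (i + 1) * band_len):
                    hit = False
                    for _, s, e, call in segs:
                        if s <= b < e:
                            counts[call] += 1
                            hit = True
                    if not hit:
                        uncovered += 1
                counts["neutral"] += uncovered
                best = max(counts,
                           key=lambda c: (counts[c],
                                          -("loss", "neutral", "gain").index(c)))
                assert states.iloc[i, 0] == code[best]


class TestStandardize:
    def test_medians_zero_sds_one(self, rng):
        expr = _expr(rng.uniform(1, 50, size=(15, 9)))
        out = preprocess.standardize_genes(expr)
        np.testing.assert_allclose(out.median(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_constant_gene_dropped(self):
        expr = _expr([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        out = preprocess.standardize_genes(expr)
        assert list(out.index) == ["g0"]

    def test_hand_computed_three_samples(self):
        expr = _expr([[1.0, 2.0, 4.0]])
        out = preprocess.standardize_genes(expr)
        sd = np.std([1, 2, 4], ddof=1)
        np.testing.assert_allclose(
            out.loc["g0"], (np.array([1, 2, 4]) - 2.0) / sd)
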