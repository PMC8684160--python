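"""Latent-factor model, BIC, consensus selection and COCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from omicsub import integrate
from omicsub.integrate import (
    BERNOULLI,
    GAUSSIAN,
    Layer,
    LatentFactorModel,
    assign_clusters,
    bic,
    calibrate_penalties,
    coca,
    consensus_select_k,
    fit_latent_model,
)


def _two_blob_layer(rng, n_per=30, p=20, sep=6.0):
    X = rng.standard_normal((2 * n_per, p))
    X[n_per:, :5] += sep
    truth = np.repeat([0, 1], n_per)
    return Layer("expression", X, GAUSSIAN), truth


def _assert_monotone(model):
    tr = np.array(model.loglik_trace)
    assert np.all(np.diff(tr) >= -1e-8 * (np.abs(tr[:-1]) + 1.0))


def test_k1_rejected(rng):
    layer, _ = _two_blob_layer(rng)
    with pytest.raises(ValueError, match="K must be >= 2"):
        fit_latent_model([layer], K=1)


def test_separated_gaussian_clusters_recovered(rng):
    layer, truth = _two_blob_layer(rng)
    oracle = KMeans(2, n_init=10, random_state=0).fit_predict(layer.X)
    assert adjusted_rand_score(truth, oracle) == 1.0  # construction sanity
    model = fit_latent_model([layer], K=2, lambdas=0.5, seed=0)
    _assert_monotone(model)
    labels = assign_clusters(model)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_strong_penalty_zeroes_noise_layer(rng):
    signal, truth = _two_blob_layer(rng)
    noise = Layer("noise", rng.standard_normal((60, 40)), GAUSSIAN)
    model = fit_latent_model([signal, noise], K=2,
                             lambdas={"expression": 0.5, "noise": 50.0}, seed=0)
    _assert_monotone(model)
    frac_zero = np.mean(model.betas["noise"] == 0.0)
    assert frac_zero >= 0.9


def test_mixed_family_fit_is_monotone(rng):
    gauss, truth = _two_blob_layer(rng)
    p_mut = np.where(truth[:, None] == 1, 0.6, 0.05)
    binary = Layer("mutations", (rng.random((60, 8)) < p_mut[:, :8]).astype(float),
                   BERNOULLI)
    model = fit_latent_model([gauss, binary], K=2, lambdas=1.0, seed=0)
    _assert_monotone(model)
    assert adjusted_rand_score(truth, assign_clusters(model)) == 1.0


class TestBic:
    def _model(self, loglik, beta, alpha, n):
        return LatentFactorModel(
            K=2, Z=np.zeros((n, 1)), alphas={"l": alpha}, betas={"l": beta},
            families={"l": GAUSSIAN}, lambdas={"l": 1.0}, loglik_trace=[],
            loglik=loglik, converged=True, seed=0,
        )

    def test_closed_form(self):
        # d = 10 nonzero parameters, n = 100
        m = self._model(-100.0, np.ones((1, 6)), np.ones(4), 100)
        assert bic(m) == pytest.approx(200 + 10 * np.log(100), abs=1e-6)
        assert bic(m) == pytest.approx(246.0517, abs=1e-3)

    def test_zero_loading_feature_leaves_bic_unchanged(self):
        m1 = self._model(-100.0, np.ones((1, 6)), np.zeros(6), 100)
        beta2 = np.hstack([np.ones((1, 6)), np.zeros((1, 1))])
        m2 = self._model(-100.0, beta2, np.zeros(7), 100)
        assert bic(m1) == bic(m2)

    def test_monotone_in_parameter_count_at_equal_loglik(self):
        m_small = self._model(-100.0, np.ones((1, 3)), np.zeros(3), 100)
        m_big = self._model(-100.0, np.ones((1, 5)), np.zeros(5), 100)
        assert bic(m_big) > bic(m_small)


class TestAssignClusters:
    def test_point_masses_split_perfectly(self):
        Z = np.vstack([np.zeros((10, 1)), np.ones((10, 1)) * 5])
        m = LatentFactorModel(K=2, Z=Z, alphas={}, betas={}, families={},
                              lambdas={}, loglik_trace=[], loglik=0.0,
                              converged=True, seed=0)
        labels = assign_clusters(m)
        assert adjusted_rand_score(np.repeat([0, 1], 10), labels) == 1.0

    def test_degenerate_latent_space_rejected(self):
        m = LatentFactorModel(K=2, Z=np.zeros((10, 1)), alphas={}, betas={},
                              families={}, lambdas={}, loglik_trace=[],
                              loglik=0.0, converged=True, seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            assign_clusters(m)

    def test_three_planted_blobs(self, rng):
        Z = np.vstack([rng.normal(c, 0.05, size=(12, 2)) for c in (0, 5, 10)])
        m = LatentFactorModel(K=3, Z=Z, alphas={}, betas={}, families={},
                              lambdas={}, loglik_trace=[], loglik=0.0,
                              converged=True, seed=1)
        assert adjusted_rand_score(np.repeat([0, 1, 2], 12),
                                   assign_clusters(m)) == 1.0


def test_lambda_to_zero_matches_pca_kmeans(rng):
    layer, truth = _two_blob_layer(rng, n_per=40, p=30)
    model = fit_latent_model([layer], K=2, lambdas=1e-6, seed=0)
    labels = assign_clusters(model)
    Xc = layer.X - layer.X.mean(0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    ref = KMeans(2, n_init=10, random_state=0).fit_predict(U[:, :1] * s[:1])
    assert adjusted_rand_score(ref, labels) >= 0.95


class TestConsensus:
    def _three_group_layers(self, rng, n_per=25, p=30):
        X = rng.standard_normal((3 * n_per, p))
        truth = np.repeat([0, 1, 2], n_per)
        for k in range(3):
            X[truth == k, 10 * k:10 * (k + 1)] += 4.0
        return [Layer("expression", X, GAUSSIAN)], truth

    def test_single_iteration_consensus_is_binary(self, rng):
        layers, _ = self._three_group_layers(rng)
        res = consensus_select_k(layers, k_range=range(2, 5), n_iter=1,
                                 sample_frac=1.0, feature_frac=1.0, seed=0)
        assert len(res.k_frequency) == 1
        vals = res.consensus[res.co_sampled_counts > 0]
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_identical_labelings_give_full_consistency(self, rng):
        layers, _ = self._three_group_layers(rng)
        res = consensus_select_k(layers, k_range=[3], n_iter=2,
                                 sample_frac=1.0, feature_frac=1.0, seed=0)
        vals = res.consensus[res.co_sampled_counts > 0]
        assert set(np.unique(vals)) <= {0.0, 1.0}
        assert res.membership_consistency == pytest.approx(1.0)

    def test_recovers_planted_k_and_labels(self, rng):
        layers, truth = self._three_group_layers(rng)
        res = consensus_select_k(layers, k_range=range(2, 7), n_iter=20, seed=1)
        assert res.chosen_K == 3
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_consensus_matrix_symmetric_in_range(self, rng):
        layers, _ = self._three_group_layers(rng)
        res = consensus_select_k(layers, k_range=range(2, 5), n_iter=5, seed=3)
        c = np.nan_to_num(res.consensus, nan=0.0)
        np.testing.assert_allclose(c, c.T)
        assert c.min() >= 0.0 and c.max() <= 1.0
        on_diag = np.diag(res.co_sampled_counts) > 0
        np.testing.assert_allclose(np.diag(c)[on_diag], 1.0)

    def test_zero_iterations_rejected(self, rng):
        layers, _ = self._three_group_layers(rng)
        with pytest.raises(ValueError, match="n_iter"):
            consensus_select_k(layers, n_iter=0)


class TestCoca:
    def test_identical_partitions_pass_through(self, rng):
        truth = np.repeat([0, 1, 2], 20)
        layers = []
        for name in ("a", "b"):
            X = rng.standard_normal((60, 20))
            for k in range(3):
                X[truth == k, 6 * k:6 * (k + 1)] += 5.0
            layers.append(Layer(name, X, GAUSSIAN))
        sol = coca(layers, k_range=range(2, 6), n_iter=8, seed=0)
        assert adjusted_rand_score(truth, sol.labels) == 1.0

    def test_clean_layer_beats_noise_layer(self, rng):
        truth = np.repeat([0, 1, 2, 3], 15)
        X = rng.standard_normal((60, 24))
        for k in range(4):
            X[truth == k, 6 * k:6 * (k + 1)] += 5.0
        clean = Layer("clean", X, GAUSSIAN)
        noise = Layer("noise", rng.standard_normal((60, 24)), GAUSSIAN)
        sol = coca([clean, noise], k_range=range(2, 7), n_iter=8, seed=0)
        assert adjusted_rand_score(truth, sol.labels) >= 0.9

    def test_single_layer_returns_its_solution(self, rng):
        truth = np.repeat([0, 1], 20)
        X = rng.standard_normal((40, 10))
        X[truth == 1, :4] += 5.0
        sol = coca([Layer("only", X, GAUSSIAN)], k_range=range(2, 5), seed=0)
        assert sol.K == 2
        assert adjusted_rand_score(truth, sol.labels) == 1.0


def test_calibrated_penalty_sparser_for_noise_layer(rng):
    signal, _ = _two_blob_layer(rng, n_per=40, p=30)
    noise = Layer("noise", rng.standard_normal((80, 30)), GAUSSIAN)
    lams = calibrate_penalties([signal, noise], K=2, seed=0)
    assert lams["noise"] > lams["expression"]
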