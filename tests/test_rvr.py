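"""Sparse Bayesian regression core: posterior algebra, ARD fit, prediction,
weight-map back-projection."""

import numpy as np
import pytest
from scipy import stats

from rvrmap import (
    RVR,
    FitConfig,
    compute_posterior,
    linear_kernel,
    log_marginal_likelihood,
    vectorize,
)
from rvrmap.features import (
    BrainVolume,
    DesignMatrix,
    KernelMatrix,
    build_design,
)


def make_design(Phi, ids=None):
    n_train = Phi.shape[1] - 1
    ids = ids or [f"T{i}" for i in range(n_train)]
    return DesignMatrix(
        Phi=Phi, train_subject_ids=ids, row_subject_ids=ids[: Phi.shape[0]]
    )


def features_from_rows(X):
    X = np.asarray(X, dtype=float)
    mask = np.ones((1, 1, X.shape[1]), bool)
    vols = [
        BrainVolume(values=x.reshape(1, 1, -1), voxel_size_mm=(1, 1, 1),
                    mask=mask, signed=True)
        for x in X
    ]
    return vectorize(vols, mask)


class TestPosterior:
    def test_scalar_case(self):
        mu, Sigma = compute_posterior(np.array([[1.0]]), np.array([0.0]),
                                      np.array([1.0]), 1.0)
        assert mu[0] == pytest.approx(0.0)
        assert Sigma[0, 0] == pytest.approx(0.5)

    def test_zero_targets_give_zero_mean(self, rng):
        Phi = rng.standard_normal((6, 4))
        mu, _ = compute_posterior(Phi, np.zeros(6), np.ones(4), 0.5)
        np.testing.assert_allclose(mu, 0.0, atol=1e-12)

    def test_matches_dense_formula(self, rng):
        Phi = rng.standard_normal((6, 4))
        t = rng.standard_normal(6)
        alpha = rng.uniform(0.1, 5.0, 4)
        sigma2 = 0.7
        mu, Sigma = compute_posterior(Phi, t, alpha, sigma2)
        Sigma_ref = np.linalg.inv(Phi.T @ Phi / sigma2 + np.diag(alpha))
        mu_ref = Sigma_ref @ Phi.T @ t / sigma2
        np.testing.assert_allclose(Sigma, Sigma_ref, atol=1e-9)
        np.testing.assert_allclose(mu, mu_ref, atol=1e-9)

    def test_rejects_nonpositive_hyperparameters(self):
        with pytest.raises(ValueError):
            compute_posterior(np.eye(2), np.zeros(2), np.array([1.0, -1.0]), 1.0)


class TestEvidence:
    def test_scalar_closed_form(self):
        a, s, t = 2.0, 0.3, 1.7
        got = log_marginal_likelihood(np.array([[1.0]]), np.array([t]),
                                      np.array([a]), s)
        var = s + 1.0 / a
        expected = -0.5 * np.log(2 * np.pi * var) - t**2 / (2 * var)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_targets_value_is_half_logdet(self, rng):
        Phi = rng.standard_normal((5, 3))
        alpha = rng.uniform(0.5, 2.0, 3)
        sigma2 = 0.4
        got = log_marginal_likelihood(Phi, np.zeros(5), alpha, sigma2)
        C = sigma2 * np.eye(5) + (Phi / alpha) @ Phi.T
        expected = -0.5 * (5 * np.log(2 * np.pi) + np.linalg.slogdet(C)[1])
        assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_multivariate_normal_density(self, rng):
        Phi = rng.standard_normal((5, 4))
        t = rng.standard_normal(5)
        alpha = rng.uniform(0.2, 3.0, 4)
        sigma2 = 0.9
        got = log_marginal_likelihood(Phi, t, alpha, sigma2)
        C = sigma2 * np.eye(5) + (Phi / alpha) @ Phi.T
        expected = stats.multivariate_normal(mean=np.zeros(5), cov=C).logpdf(t)
        assert got == pytest.approx(expected, abs=1e-9)


class TestFit:
    def test_single_informative_column_survives(self, rng):
        n = 20
        Phi = np.column_stack([np.ones(n), rng.standard_normal((n, n))])
        j = 5
        t = 3.0 * Phi[:, j]
        res = RVR(t, make_design(Phi)).fit()
        assert j in res.active_idx
        pred = res.predict(Phi)
        np.testing.assert_allclose(pred, t, atol=1e-6)

    def test_constant_targets_captured_by_offset(self, rng):
        n = 12
        Phi = np.column_stack([np.ones(n), rng.standard_normal((n, n))])
        t = np.full(n, 4.2)
        res = RVR(t, make_design(Phi)).fit()
        np.testing.assert_allclose(res.predict(Phi), 4.2, atol=1e-6)

    def test_max_iter_zero_equals_ridge_closed_form(self, rng):
        # hyperparameter updates disabled: the fit is exactly the fixed-prior
        # posterior from compute_posterior with the initial (alpha, sigma2).
        n = 10
        Phi = np.column_stack([np.ones(n), rng.standard_normal((n, n))])
        t = rng.standard_normal(n)
        cfg = FitConfig(max_iter=0, alpha_init=2.5, sigma2_init_fraction=0.2)
        model = RVR(t, make_design(Phi))
        res = model.fit(cfg)
        sigma2 = 0.2 * np.var(t)
        mu_ref, Sigma_ref = compute_posterior(
            model.exog, t, np.full(n + 1, 2.5), sigma2, cfg.jitter
        )
        np.testing.assert_array_equal(res.mu, mu_ref)
        np.testing.assert_array_equal(res.Sigma, Sigma_ref)
        assert res.sigma2 == sigma2

    def test_evidence_never_decreases(self, rng):
        for _ in range(5):
            n = 15
            Phi = np.column_stack([np.ones(n), rng.standard_normal((n, n))])
            t = Phi[:, 1] + 0.3 * rng.standard_normal(n)
            res = RVR(t, make_design(Phi)).fit()
            assert res.llf >= res.llf_init - 1e-6
            assert res.evidence_trace[0] == pytest.approx(res.llf_init)

    def test_nan_targets_rejected(self):
        Phi = np.column_stack([np.ones(3), np.eye(3)])
        with pytest.raises(ValueError, match="NaN"):
            RVR(np.array([1.0, np.nan, 2.0]), make_design(Phi))

    def test_kernel_scale_invariance(self, rng):
        # multiplying the kernel by c is absorbed by the hyperparameters:
        # predictions change by < 1e-6 relative.
        n = 18
        X = rng.standard_normal((n, 25))
        t = X[:, 0] + 0.2 * rng.standard_normal(n)
        K0 = X @ X.T
        X_test = rng.standard_normal((4, 25))
        Kt0 = X_test @ X.T
        ref = None
        for c in (0.01, 1.0, 100.0):
            Phi = np.column_stack([np.ones(n), c * K0])
            res = RVR(t, make_design(Phi)).fit()
            pred = res.predict(np.column_stack([np.ones(4), c * Kt0]))
            if ref is None:
                ref = pred
            else:
                np.testing.assert_allclose(pred, ref, rtol=1e-6, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        n = 14
        X = rng.standard_normal((n, 30))
        t = X[:, 0] + 0.1 * rng.standard_normal(n)
        X_test = rng.standard_normal((3, 30))

        def run(order):
            Xo, to = X[order], t[order]
            Phi = np.column_stack([np.ones(n), Xo @ Xo.T])
            res = RVR(to, make_design(Phi)).fit()
            return res.predict(np.column_stack([np.ones(3), X_test @ Xo.T]))

        base = run(np.arange(n))
        perm = run(rng.permutation(n))
        np.testing.assert_allclose(perm, base, atol=1e-8)

    def test_sparsity_and_generalization_with_noise_bases(self, rng):
        # 5 informative + 45 pure-noise training samples: ARD keeps the fit
        # sparse enough that held-out predictions beat the mean predictor.
        n, d = 50, 60
        X = rng.standard_normal((n, d))
        w_true = np.zeros(d)
        w_true[:3] = [2.0, -1.0, 1.5]
        t = X @ w_true + 0.5 * rng.standard_normal(n)
        res = RVR.from_features(t, features_from_rows(X)).fit()
        assert res.relevance_ratio < 1.0
        X_new = rng.standard_normal((30, d))
        t_new = X_new @ w_true + 0.5 * rng.standard_normal(30)
        pred, _ = res.predict_features(features_from_rows(X_new))
        nrms = np.sqrt(np.mean((pred - t_new) ** 2)) / np.std(t_new)
        assert nrms < 1.0


class TestPredict:
    def test_offset_only_model(self):
        n = 6
        Phi = np.column_stack([np.ones(n), np.eye(n)])
        t = np.full(n, 2.0)
        cfg = FitConfig(max_iter=200)
        res = RVR(t, make_design(Phi)).fit(cfg)
        Phi_test = np.column_stack([np.ones(3), np.zeros((3, n))])
        mean, var = res.predict(Phi_test, return_var=True)
        np.testing.assert_allclose(mean, 2.0, atol=1e-6)
        assert np.all(var >= res.sigma2)

    def test_predictive_variance_at_least_noise(self, rng):
        n = 10
        Phi = np.column_stack([np.ones(n), rng.standard_normal((n, n))])
        t = rng.standard_normal(n)
        res = RVR(t, make_design(Phi)).fit()
        _, var = res.predict(Phi, return_var=True)
        assert np.all(var >= res.sigma2 - 1e-12)

    def test_misaligned_kernel_rejected(self, rng):
        X = rng.standard_normal((5, 10))
        fm = features_from_rows(X)
        res = RVR.from_features(rng.standard_normal(5), fm).fit()
        bad = KernelMatrix(
            K=rng.standard_normal((2, 5)),
            train_subject_ids=["x0", "x1", "x2", "x3", "x4"],
            row_subject_ids=["a", "b"],
            scale=res.model.design.scale,
        )
        with pytest.raises(ValueError, match="misalignment"):
            res.predict(bad)


class TestWeightMap:
    def test_two_path_prediction_equivalence(self, rng):
        # dot(weight_map, features) + offset must equal predict() — the
        # stated recipe for scoring a new subject from the weighting image.
        n, d = 20, 40
        X = rng.standard_normal((n, d))
        t = X[:, 0] - 0.5 * X[:, 3] + 0.1 * rng.standard_normal(n)
        fm = features_from_rows(X)
        res = RVR.from_features(t, fm).fit()
        vol, offset = res.weight_map()
        w = vol.values[fm.mask]
        X_test = rng.standard_normal((7, d))
        direct = X_test @ w + offset
        via_kernel, _ = res.predict_features(features_from_rows(X_test))
        np.testing.assert_allclose(direct, via_kernel, atol=1e-8)

    def test_all_pruned_gives_zero_map(self, rng):
        n = 8
        X = rng.standard_normal((n, 12))
        fm = features_from_rows(X)
        res = RVR.from_features(np.full(n, 3.0), fm).fit()
        vol, _ = res.weight_map()
        if res.relevance_idx.size == 0:
            assert np.all(vol.values == 0)
        else:  # offset may share the load; map must still be near-null
            assert np.abs(vol.values).max() < 1e-3

    def test_requires_features(self, rng):
        Phi = np.column_stack([np.ones(4), np.eye(4)])
        res = RVR(rng.standard_normal(4), make_design(Phi)).fit()
        with pytest.raises(ValueError, match="FeatureMatrix"):
            res.weight_map()


class TestDiagnostics:
    def test_relevance_ratio_counting(self, rng):
        n = 10
        X = rng.standard_normal((n, 15))
        res = RVR.from_features(rng.standard_normal(n), features_from_rows(X)).fit()
        assert res.relevance_ratio == res.relevance_idx.size / n
        assert 0.0 <= res.relevance_ratio <= 1.0

    def test_summary_mentions_key_quantities(self, small_cohort):
        res = RVR.from_cohort(small_cohort).fit()
        text = res.summary()
        for token in ("Relevance ratio", "Log evidence", "sigma^2", "Iterations"):
            assert token in text

    def test_serialization_roundtrip(self, tmp_path, rng):
        import json

        n = 8
        X = rng.standard_normal((n, 10))
        res = RVR.from_features(rng.standard_normal(n), features_from_rows(X)).fit()
        path = tmp_path / "model.json"
        res.save(path)
        payload = json.loads(path.read_text())
        np.testing.assert_allclose(payload["mu"], res.mu)
        assert payload["sigma2"] == res.sigma2
        assert payload["active_idx"] == res.active_idx.tolist()
        assert payload["train_hash"] == res.model.design.train_hash
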