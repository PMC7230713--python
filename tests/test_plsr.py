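"""PLSR fitting, splitting, component selection and prediction."""

import numpy as np
import pytest

from scalespec import (
    RankDeficiencyError,
    ScenePhysics,
    fit_plsr,
    predict,
    select_latent_variables,
    simulate_dataset,
    split_dataset,
    trim_to_analysis_range,
)
from scalespec.datasets import SpectralDataset, WavelengthAxis


def toy_dataset(X, y):
    axis = WavelengthAxis(400.0 + 5.0 * np.arange(X.shape[1]))
    return SpectralDataset(axis, X, y)


class TestSplit:
    def test_default_sixty_forty_disjoint_cover(self, region_dataset):
        split = split_dataset(region_dataset)
        cal, pred = split.calibration_indices, split.prediction_indices
        assert len(cal) == 60 and len(pred) == 40
        assert len(np.intersect1d(cal, pred)) == 0
        assert len(np.union1d(cal, pred)) == 100

    def test_rank_strategy_spans_response_range(self, region_dataset):
        split = split_dataset(region_dataset)
        y = region_dataset.responses
        full = np.ptp(y)
        for idx in (split.calibration_indices, split.prediction_indices):
            assert np.ptp(y[idx]) >= 0.9 * full

    def test_random_strategy_deterministic_per_seed(self, region_dataset):
        a = split_dataset(region_dataset, strategy="random", seed=5)
        b = split_dataset(region_dataset, strategy="random", seed=5)
        assert np.array_equal(a.calibration_indices, b.calibration_indices)

    def test_size_mismatch_rejected(self, region_dataset):
        with pytest.raises(ValueError):
            split_dataset(region_dataset, 50, 40)


class TestFit:
    def test_single_band_truth_fits_exactly_with_one_component(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 1))
        y = 2.0 * X[:, 0] + 1.0
        model = fit_plsr(X, y, 1)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-8)

    def test_full_rank_beta_matches_pseudoinverse(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        model = fit_plsr(X, y, 6)
        beta_ols = np.linalg.pinv(X - X.mean(0)) @ (y - y.mean())
        assert np.linalg.norm(model.beta - beta_ols) <= 1e-6 * np.linalg.norm(beta_ols)

    def test_score_vectors_mutually_orthogonal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 60))
        y = X[:, :3] @ np.array([1.0, -1.0, 0.5]) + 0.1 * rng.normal(size=40)
        model = fit_plsr(X, y, 6)
        # reconstruct the score vectors from the stored decomposition
        Xc = X - model.x_mean
        T = np.zeros((40, 6))
        for a in range(6):
            T[:, a] = Xc @ model.weights[:, a]
            Xc = Xc - np.outer(T[:, a], model.x_loadings[:, a])
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) <= 1e-8 * np.max(np.diag(G))

    def test_matches_reference_pls_implementation(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 80))
        y = X[:, 4] - 2.0 * X[:, 40] + 0.05 * rng.normal(size=50)
        for k in (1, 3, 7):
            ours = fit_plsr(X, y, k)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(ours.beta, ref.coef_.ravel(), rtol=1e-8, atol=1e-10)

    def test_rank_deficiency_reports_achievable_maximum(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=(20, 2))
        X = t @ rng.normal(size=(2, 10))  # rank 2
        y = t @ np.array([1.0, 2.0])
        with pytest.raises(RankDeficiencyError) as err:
            fit_plsr(X, y, 8)
        assert err.value.achievable <= 3

    def test_invalid_component_count_rejected(self):
        X = np.random.default_rng(5).normal(size=(10, 4))
        y = np.arange(10.0)
        with pytest.raises(ValueError):
            fit_plsr(X, y, 0)
        with pytest.raises(ValueError):
            fit_plsr(X, y, 10)


class TestSelectLatentVariables:
    def test_noise_free_rank_two_needs_at_most_three(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=(60, 2))
        X = t @ rng.normal(size=(2, 50))
        y = t @ np.array([1.0, -2.0])
        assert select_latent_variables(X, y, max_lv=10, folds=10) <= 3

    def test_pure_noise_response_gets_one_component(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 100))
        y = np.random.default_rng(17).normal(size=60)
        assert select_latent_variables(X, y, max_lv=15, folds=10) == 1

    def test_max_lv_one_returns_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 5))
        y = X[:, 0]
        assert select_latent_variables(X, y, max_lv=1, folds=5) == 1

    def test_too_many_folds_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError):
            select_latent_variables(X, np.arange(5.0), max_lv=2, folds=10)


class TestPredict:
    def test_mean_row_predicts_mean_response(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        model = fit_plsr(X, y, 4)
        assert predict(model, model.x_mean)[0] == pytest.approx(model.y_mean, abs=1e-9)

    def test_band_mismatch_rejected(self):
        X = np.random.default_rng(10).normal(size=(20, 8))
        model = fit_plsr(X, np.arange(20.0), 2)
        with pytest.raises(ValueError, match="band"):
            predict(model, np.zeros((3, 5)))

    def test_latent_and_collapsed_predictions_agree(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(35, 40))
        y = X[:, 5] + rng.normal(size=35)
        model = fit_plsr(X, y, 5)
        # latent-route prediction: project scores, accumulate q_a * t_a
        Xc = X - model.x_mean
        yhat = np.full(35, model.y_mean)
        for a in range(model.n_latent):
            t = Xc @ model.weights[:, a]
            Xc = Xc - np.outer(t, model.x_loadings[:, a])
            yhat += model.y_loadings[a] * t
        np.testing.assert_allclose(yhat, predict(model, X), rtol=1e-8)

    def test_noise_free_mixtures_recovered_with_two_components(self, axis):
        physics = ScenePhysics(scatter_slope_sd=0.0, baseline_sd=0.0, noise_sd=0.0, seed=12)
        ds = trim_to_analysis_range(simulate_dataset(30, axis, physics))
        model = fit_plsr(ds.spectra, ds.responses, 1)
        np.testing.assert_allclose(predict(model, ds.spectra), ds.responses, atol=1e-6)

    def test_band_reordering_invariance(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 20))
        y = X[:, 2] - X[:, 9] + 0.1 * rng.normal(size=40)
        perm = rng.permutation(20)
        m1 = fit_plsr(X, y, 5)
        m2 = fit_plsr(X[:, perm], y, 5)
        Xnew = rng.normal(size=(6, 20))
        np.testing.assert_allclose(
            predict(m1, Xnew), predict(m2, Xnew[:, perm]), rtol=1e-8
        )
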