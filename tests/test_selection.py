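"""Characteristic-wavelength selectors: SPA, RC extrema, 2D-COS auto-peaks."""

import numpy as np
import pytest

from scalespec import (
    ScenePhysics,
    WavelengthAxis,
    autopeak_select,
    exhaustive_select,
    rc_select,
    simulate_dataset,
    spa_select,
    synchronous_spectrum,
    trim_to_analysis_range,
)
from scalespec.datasets import SpectralDataset
from scalespec.plsr import fit_plsr, predict, split_dataset
from scalespec.selection import WavelengthSubset, loo_rmse_mlr


def toy_dataset(X, y, spacing=10.0):
    axis = WavelengthAxis(400.0 + spacing * np.arange(X.shape[1]))
    return SpectralDataset(axis, X, y)


class TestSPA:
    def test_finds_the_single_informative_band(self):
        rng = np.random.default_rng(0)
        n, b = 40, 30
        X = rng.normal(size=(n, b))
        y = 3.0 * X[:, 17] + 1.0
        subset = spa_select(toy_dataset(X, y), 1, 5)
        assert 17 in subset.indices

    def test_matches_exhaustive_search_on_three_bands(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        ds = toy_dataset(X, y)
        spa = spa_select(ds, 1, 3)
        brute = exhaustive_select(ds, 1, 3)
        r_spa = loo_rmse_mlr(X[:, spa.indices], y)
        r_brute = loo_rmse_mlr(X[:, brute.indices], y)
        assert r_spa <= r_brute * 1.01 + 1e-9 * np.std(y)

    def test_never_selects_a_duplicated_band_twice(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6))
        X = np.column_stack([X, X[:, 2]])  # band 6 duplicates band 2
        y = X[:, 0] + 0.5 * X[:, 4] + 0.01 * rng.normal(size=20)
        subset = spa_select(toy_dataset(X, y), 1, 6)
        assert not ({2, 6} <= set(subset.indices.tolist()))

    def test_parameter_validation(self):
        rng = np.random.default_rng(3)
        ds = toy_dataset(rng.normal(size=(10, 4)), rng.normal(size=10))
        with pytest.raises(ValueError):
            spa_select(ds, 3, 2)
        with pytest.raises(ValueError):
            spa_select(ds, 1, 9)
        with pytest.raises(ValueError):
            spa_select(ds, 1, 4, scorer="nope")

    def test_plsr_scorer_available(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 8))
        y = X[:, 1] - X[:, 5]
        subset = spa_select(toy_dataset(X, y), 1, 4, scorer="plsr")
        assert 1 <= len(subset) <= 4


class TestRC:
    def test_single_interior_spike_band_selected_first(self):
        # response loads on band 7 only; beta's dominant extremum sits there
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 20))
        y = 5.0 * X[:, 7]
        subset = rc_select(toy_dataset(X, y), n_keep=1, n_latent=3)
        assert subset.indices.tolist() == [7]

    def test_two_loaded_bands_among_top_four(self):
        rng = np.random.default_rng(6)
        n, b = 80, 250
        X = rng.normal(size=(n, b)) + 0.1
        y = 6.0 * X[:, 10] - 6.0 * X[:, 200] + 0.01 * rng.normal(size=n)
        subset = rc_select(toy_dataset(X, y, spacing=2.0), n_keep=4, n_latent=5)
        assert {10, 200} <= set(subset.indices.tolist())

    def test_requesting_more_extrema_than_exist_warns_and_returns_all(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 8))
        y = X[:, 3]
        with pytest.warns(UserWarning, match="extrema"):
            subset = rc_select(toy_dataset(X, y), n_keep=50, n_latent=2)
        assert len(subset) >= 1
        assert np.all(np.diff(subset.wavelengths_nm) > 0)


class TestSynchronousSpectrum:
    def test_two_sample_map_matches_direct_formula(self):
        x1 = np.array([1.0, 3.0, 2.0, 5.0])
        x2 = np.array([2.0, 1.0, 4.0, 4.0])
        ds = toy_dataset(np.vstack([x1, x2]), np.array([10.0, 60.0]))
        sync = synchronous_spectrum(ds)
        d = (x2 - x1) / 2.0  # deviation of the higher-rate sample
        expected = 2.0 * np.outer(d, d)  # sum of two outer products over (m-1)=1
        np.testing.assert_allclose(sync.matrix, expected, rtol=1e-12)

    def test_symmetry(self, region_dataset):
        sync = synchronous_spectrum(region_dataset)
        asym = np.max(np.abs(sync.matrix - sync.matrix.T))
        assert asym <= 1e-10 * max(1.0, np.max(np.abs(sync.matrix)))

    def test_positive_semidefinite(self, region_dataset):
        sync = synchronous_spectrum(region_dataset)
        eigmin = np.linalg.eigvalsh(sync.matrix).min()
        assert eigmin >= -1e-8 * sync.diagonal.max()

    def test_single_varying_band_yields_single_autopeak(self):
        rng = np.random.default_rng(8)
        n, b = 20, 15
        X = np.tile(np.linspace(1, 2, b), (n, 1))
        rates = np.linspace(0, 100, n)
        X[:, 6] += rates / 25.0
        ds = toy_dataset(X, rates)
        sync = synchronous_spectrum(ds)
        subset = autopeak_select(sync, max_peaks=8)
        assert subset.indices.tolist() == [6]

    def test_identical_rates_rejected(self):
        ds = toy_dataset(np.random.default_rng(9).normal(size=(4, 6)), np.full(4, 5.0))
        with pytest.raises(ValueError):
            synchronous_spectrum(ds)


class TestAutopeaks:
    def make_sync(self, diag):
        b = len(diag)
        axis = WavelengthAxis(400.0 + 5.0 * np.arange(b))
        from scalespec.selection import SyncSpectrum

        return SyncSpectrum(matrix=np.diag(diag), axis=axis, perturbation=np.arange(b, dtype=float))

    def test_four_gaussian_bumps_found_at_centres(self):
        x = np.arange(120, dtype=float)
        diag = np.zeros(120)
        centres = [15, 45, 75, 105]
        for i, c in enumerate(centres):
            diag += (1.0 + i) * np.exp(-0.5 * ((x - c) / 4.0) ** 2)
        subset = autopeak_select(self.make_sync(diag), max_peaks=8)
        assert subset.indices.tolist() == centres

    def test_cap_keeps_the_tallest(self):
        x = np.arange(120, dtype=float)
        diag = np.zeros(120)
        for i, c in enumerate([15, 45, 75, 105]):
            diag += (1.0 + i) * np.exp(-0.5 * ((x - c) / 4.0) ** 2)
        subset = autopeak_select(self.make_sync(diag), max_peaks=2)
        assert subset.indices.tolist() == [75, 105]

    def test_flat_diagonal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="flat"):
            subset = autopeak_select(self.make_sync(np.full(30, 2.0)))
        assert len(subset) == 0

    def test_subset_invariants_enforced(self):
        with pytest.raises(ValueError):
            WavelengthSubset(
                indices=np.array([3, 3]),
                wavelengths_nm=np.array([400.0, 400.0]),
                method="SPA",
            )


class TestInformationSufficiency:
    @pytest.mark.parametrize("selector", ["spa", "rc", "2dcos"])
    def test_selected_bands_support_excellent_prediction_on_ideal_data(self, axis, selector):
        """On noise-free mixtures every selector keeps enough information
        for near-perfect scaling-rate prediction."""
        physics = ScenePhysics(scatter_slope_sd=0.0, baseline_sd=0.0, noise_sd=0.0, seed=11)
        ds = trim_to_analysis_range(simulate_dataset(60, axis, physics))
        split = split_dataset(ds, 36, 24)
        cal = ds.select_samples(split.calibration_indices)
        prd = ds.select_samples(split.prediction_indices)
        if selector == "spa":
            subset = spa_select(cal, 1, 6)
        elif selector == "rc":
            subset = rc_select(cal, n_keep=6, n_latent=1)
        else:
            subset = autopeak_select(synchronous_spectrum(cal), max_peaks=6)
        assert len(subset) >= 1
        Xc, Xp = cal.spectra[:, subset.indices], prd.spectra[:, subset.indices]
        model = fit_plsr(Xc, cal.responses, 1)
        resid = prd.responses - predict(model, Xp)
        r2 = 100.0 * (1.0 - np.sum(resid**2) / np.sum((prd.responses - prd.responses.mean()) ** 2))
        assert r2 >= 99.0
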