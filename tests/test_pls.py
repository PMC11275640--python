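"""NIPALS PLSR, splitting, LOO-PRESS and F-test factor selection."""

import numpy as np
import pytest
from scipy import stats

from strawspec import (
    DegenerateDataError,
    PressCurve,
    SpectralDataset,
    SplitSpec,
    WavelengthGrid,
    fit_nipals,
    fit_with_selection,
    load_model,
    loo_press,
    predict,
    save_model,
    select_factors,
    split_dataset,
)
from strawspec.pls import loo_predictions


def linear_problem(n=20, p=8, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = X @ rng.standard_normal(p) + noise * rng.standard_normal(n)
    return X, y


class TestSplitDataset:
    @pytest.mark.parametrize("n,train,test", [(180, 126, 54), (150, 105, 45)])
    def test_seventy_thirty_sizes(self, dataset_factory, n, train, test):
        ds = dataset_factory(n=n)
        tr, te = split_dataset(ds, SplitSpec(seed=1))
        assert tr.n_samples == train and te.n_samples == test

    def test_partition_is_disjoint_and_exhaustive(self, dataset_factory):
        ds = dataset_factory(n=30)
        tr, te = split_dataset(ds, SplitSpec(seed=2))
        assert sorted(tr.sample_id + te.sample_id) == sorted(ds.sample_id)
        assert not set(tr.sample_id) & set(te.sample_id)

    def test_deterministic_given_seed(self, dataset_factory):
        ds = dataset_factory(n=40)
        a1, _ = split_dataset(ds, SplitSpec(seed=5))
        a2, _ = split_dataset(ds, SplitSpec(seed=5))
        b, _ = split_dataset(ds, SplitSpec(seed=6))
        assert a1.sample_id == a2.sample_id
        assert a1.sample_id != b.sample_id

    def test_stratified_preserves_variety_proportions(self, dataset_factory):
        white = dataset_factory(n=40, variety="white", seed=0)
        red = dataset_factory(n=20, variety="red", seed=1)
        mixed = SpectralDataset.concat([white, red])
        tr, te = split_dataset(mixed, SplitSpec(seed=3, stratify_by="variety"))
        assert tr.variety.count("white") == 28 and tr.variety.count("red") == 14

    def test_too_small_dataset_errors(self, dataset_factory):
        with pytest.raises(ValueError):
            split_dataset(dataset_factory(n=9), SplitSpec())


class TestFitNipals:
    def test_rank_one_signal_recovered_with_one_factor(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.0, size=(15, 10))
        X[:, 4] = rng.uniform(1.0, 2.0, 15)
        y = 3.0 * X[:, 4] + 1.0
        model = fit_nipals(X, y, 1)
        assert np.allclose(predict(model, X), y, atol=1e-8)

    def test_full_rank_equals_ols(self):
        X, y = linear_problem(n=20, p=8, seed=1, noise=0.5)
        model = fit_nipals(X, y, 8)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        ols = y.mean() + Xc @ np.linalg.lstsq(Xc, yc, rcond=None)[0]
        assert np.allclose(predict(model, X), ols, atol=1e-8)

    def test_training_rmse_non_increasing_in_factors(self):
        X, y = linear_problem(n=25, p=12, seed=2, noise=1.0)
        rmses = []
        for h in range(1, 9):
            m = fit_nipals(X, y, h)
            rmses.append(np.sqrt(np.mean((predict(m, X) - y) ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_scale_equivariance_in_y(self):
        X, y = linear_problem(n=20, p=10, seed=3, noise=0.3)
        m1 = fit_nipals(X, y, 4)
        m2 = fit_nipals(X, 10.0 * y, 4)
        assert np.allclose(10.0 * m1.coefficients, m2.coefficients, rtol=1e-10)
        assert np.allclose(10.0 * predict(m1, X), predict(m2, X), rtol=1e-10)

    def test_constant_y_is_degenerate(self):
        X, _ = linear_problem(n=12, p=6, seed=4)
        with pytest.raises(DegenerateDataError):
            fit_nipals(X, np.full(12, 10.0), 2)

    def test_factor_bound_enforced(self):
        X, y = linear_problem(n=10, p=6, seed=5)
        with pytest.raises(ValueError):
            fit_nipals(X, y, 10)

    def test_coefficient_path_equals_factor_recursion(self):
        # prediction via the assembled coefficient vector must match the
        # score-by-score route t_h = X w_h (after deflation)
        X, y = linear_problem(n=18, p=9, seed=6, noise=0.4)
        h = 4
        model = fit_nipals(X, y, h)
        Xc = X - model.x_mean
        yhat = np.full(X.shape[0], model.y_mean)
        Xr = Xc.copy()
        for k in range(h):
            t = Xr @ model.weights[:, k]
            yhat += model.y_loadings[k] * t
            Xr -= np.outer(t, model.x_loadings[:, k])
        assert np.allclose(yhat, predict(model, X), atol=1e-10)


class TestPredict:
    def test_mean_spectrum_predicts_mean_response(self):
        X, y = linear_problem(n=16, p=7, seed=7, noise=0.2)
        model = fit_nipals(X, y, 3)
        assert predict(model, model.x_mean)[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_duplicated_row_duplicates_prediction(self):
        X, y = linear_problem(n=16, p=7, seed=8, noise=0.2)
        model = fit_nipals(X, y, 3)
        single = predict(model, X[2])
        double = predict(model, np.vstack([X[2], X[2]]))
        assert double[0] == double[1] == single[0]

    def test_wavelength_mismatch_is_shape_error(self):
        X, y = linear_problem(n=16, p=7, seed=9)
        model = fit_nipals(X, y, 2)
        with pytest.raises(ValueError, match="wavelengths"):
            predict(model, np.ones((3, 5)))


class TestLooPress:
    def brute_force_press(self, X, y, h_max):
        n = len(y)
        press = np.zeros(h_max)
        for h in range(1, h_max + 1):
            for i in range(n):
                mask = np.arange(n) != i
                m = fit_nipals(X[mask], y[mask], h)
                press[h - 1] += (y[i] - predict(m, X[i])[0]) ** 2
        return press

    @pytest.mark.parametrize("n,p,seed", [(6, 4, 0), (8, 5, 1), (10, 12, 2), (12, 6, 3)])
    def test_matches_brute_force_refit_loop(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        y = X[:, 0] - 0.5 * X[:, 1] + 0.1 * rng.standard_normal(n)
        h_max = min(3, n - 2)
        curve = loo_press(X, y, h_max)
        assert np.allclose(curve.press, self.brute_force_press(X, y, h_max),
                           rtol=0, atol=1e-10)

    def test_noise_free_rank_one_signal_has_negligible_press(self):
        rng = np.random.default_rng(4)
        X = np.zeros((12, 6))
        X[:, 2] = rng.uniform(1.0, 3.0, 12)
        y = 2.0 * X[:, 2]
        curve = loo_press(X, y, 1)
        assert curve.press[0] < 1e-10 * np.sum((y - y.mean()) ** 2)

    def test_constant_y_raises_degenerate_error(self):
        X = np.random.default_rng(5).standard_normal((10, 4))
        with pytest.raises(DegenerateDataError):
            loo_press(X, np.full(10, 3.0), 2)

    def test_h_max_too_large_for_n_errors(self):
        X, y = linear_problem(n=8, p=10, seed=6)
        with pytest.raises(ValueError):
            loo_press(X, y, 7)


class TestSelectFactors:
    def test_plateau_after_big_drop_selects_first_plateau_factor(self):
        curve = PressCurve(press=np.array([4.0, 1.0, 1.0, 1.0]), n=200)
        # F(1) = 4 far exceeds the F(200,200) upper quartile (~1.17)
        assert select_factors(curve, alpha=0.25) == 2

    def test_flat_curve_selects_one(self):
        curve = PressCurve(press=np.full(5, 2.0), n=50)
        assert select_factors(curve) == 1

    def test_increasing_curve_selects_one(self):
        curve = PressCurve(press=np.array([1.0, 2.0, 3.0]), n=50)
        assert select_factors(curve) == 1

    def test_zero_minimum_short_circuits_to_argmin(self):
        curve = PressCurve(press=np.array([5.0, 0.0, 1.0]), n=30)
        assert select_factors(curve) == 2

    def test_selected_never_significantly_above_minimum(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(10, 200))
            press = rng.uniform(0.5, 5.0, size=int(rng.integers(1, 12)))
            h = select_factors(PressCurve(press=press, n=n), alpha=0.25)
            crit = stats.f.ppf(0.75, n, n)
            assert press[h - 1] / press.min() <= crit


class TestFitWithSelection:
    def test_h_max_one_selects_one(self, dataset_factory):
        ds = dataset_factory(n=15)
        model, curve = fit_with_selection(ds, h_max=1)
        assert model.n_factors == 1 and curve.selected == 1

    def test_selected_model_refit_on_full_training_set(self, dataset_factory):
        ds = dataset_factory(n=20, seed=3)
        model, curve = fit_with_selection(ds, h_max=4)
        refit = fit_nipals(ds.absorbance, ds.ssc, model.n_factors)
        assert np.allclose(model.coefficients, refit.coefficients, atol=0)
        assert "n=20" in model.trained_on

    def test_loo_predictions_columns_align_with_press(self, dataset_factory):
        ds = dataset_factory(n=14, seed=4)
        curve = loo_press(ds.absorbance, ds.ssc, 3)
        preds = loo_predictions(ds.absorbance, ds.ssc, 3)
        manual = np.sum((ds.ssc[:, None] - preds) ** 2, axis=0)
        assert np.allclose(curve.press, manual, atol=0)


class TestModelSerialization:
    def test_json_round_trip_is_lossless(self, tmp_path, dataset_factory):
        ds = dataset_factory(n=16, seed=5)
        model, _ = fit_with_selection(ds, h_max=3)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.coefficients, model.coefficients)
        assert np.array_equal(back.x_mean, model.x_mean)
        assert np.array_equal(back.weights, model.weights)
        assert back.y_mean == model.y_mean
        assert back.n_factors == model.n_factors
        assert back.trained_on == model.trained_on
        assert back.wavelengths == model.wavelengths
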