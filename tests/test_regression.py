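"""Regressors, spectral indices, importances and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spu.regression import (
    ELMRegressor,
    IndexFeature,
    dual_band_index_features,
    elm_predict,
    evaluate_metrics,
    fit_regressor,
    rank_and_select_indices,
    rf_importance_topk,
)
from spu.spectra_io import SpectralDataset
from spu.twodcos import BandSet


class TestEvaluateMetrics:
    def test_hand_computed_values(self):
        rep = evaluate_metrics(np.array([1.0, 2, 3, 4]), np.array([1.5, 2.5, 2.5, 3.5]))
        assert rep.RMSE == pytest.approx(0.5)
        assert rep.MAE == pytest.approx(0.5)
        assert rep.RPD == pytest.approx(2.582, abs=1e-3)  # sample SD 1.2910 / 0.5
        assert rep.n == 4

    def test_perfect_prediction(self):
        rep = evaluate_metrics(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert rep.R2 == pytest.approx(1.0) and rep.RMSE == 0.0
        assert np.isinf(rep.RPD)

    def test_mean_predictor_has_zero_r2(self):
        obs = np.array([1.0, 2, 3, 4])
        rep = evaluate_metrics(obs, np.full(4, obs.mean()))
        assert rep.R2 == pytest.approx(0.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(arrays(float, 12, elements=st.floats(-10, 10, allow_nan=False)),
           arrays(float, 12, elements=st.floats(-10, 10, allow_nan=False)))
    def test_matches_independent_formulas(self, obs, pred):
        if np.ptp(obs) == 0:
            return
        rep = evaluate_metrics(obs, pred)
        sse = np.sum((pred - obs) ** 2)
        assert rep.RMSE == pytest.approx(np.sqrt(sse / 12), abs=1e-10)
        assert rep.R2 == pytest.approx(1 - sse / np.sum((obs - obs.mean()) ** 2), abs=1e-10)
        assert rep.MAE == pytest.approx(np.abs(pred - obs).mean(), abs=1e-10)

    def test_all_zero_observations_marks_mape_undefined(self):
        rep = evaluate_metrics(np.zeros(3), np.array([0.1, 0.2, 0.3]))
        assert np.isnan(rep.MAPE)


class TestELM:
    def test_refit_same_seed_identical(self):
        rng = np.random.default_rng(0)
        x, y = rng.random((30, 6)), rng.random(30)
        p1 = ELMRegressor(50, seed=4).fit(x, y).predict(x)
        p2 = ELMRegressor(50, seed=4).fit(x, y).predict(x)
        np.testing.assert_array_equal(p1, p2)

    def test_interpolates_when_overparameterized(self):
        rng = np.random.default_rng(1)
        x, y = rng.random((25, 4)), rng.random(25)
        m = ELMRegressor(n_hidden=64, seed=0).fit(x, y)
        assert np.abs(m.predict(x) - y).max() < 1e-6

    def test_linear_activation_represents_affine_map(self):
        x = np.linspace(0, 1, 20).reshape(-1, 1)
        y = 3.0 * x.ravel() + 1.0
        m = fit_regressor("ELM", x, y, {"activation": "linear", "n_hidden": 4}, seed=0)
        assert np.sqrt(np.mean((elm_predict(m, x) - y) ** 2)) < 1e-6

    def test_feature_mismatch_rejected(self):
        m = ELMRegressor(8, seed=0).fit(np.random.default_rng(0).random((10, 3)), np.zeros(10))
        with pytest.raises(ValueError, match="features"):
            m.predict(np.zeros((2, 5)))

    def test_zero_feature_input_rejected(self):
        with pytest.raises(ValueError, match="feature"):
            ELMRegressor(8).fit(np.empty((10, 0)), np.zeros(10))

    def test_elm_predict_requires_elm(self):
        rng = np.random.default_rng(0)
        m = fit_regressor("RF", rng.random((10, 2)), rng.random(10),
                          {"n_estimators": 5}, seed=0)
        with pytest.raises(TypeError):
            elm_predict(m, rng.random((2, 2)))


class TestFitRegressor:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown regressor"):
            fit_regressor("XGB", np.zeros((5, 1)), np.arange(5.0))

    def test_degenerate_response_constant_predictor(self):
        with pytest.warns(UserWarning, match="degenerate"):
            m = fit_regressor("GBRT", np.random.default_rng(0).random((6, 2)), np.full(6, 3.0))
        np.testing.assert_allclose(m.predict(np.zeros((3, 2))), 3.0)

    def test_polynomial_interpolates_quadratic(self):
        x = np.array([[1.0], [2.0], [3.0], [1.5], [2.5]])
        m = fit_regressor("polynomial", x, x.ravel() ** 2, {"degree": 2})
        np.testing.assert_allclose(m.model.coef_, [1.0, 0.0, 0.0], atol=1e-9)

    def test_rf_finds_informative_feature(self):
        rng = np.random.default_rng(2)
        x = rng.random((200, 11))
        y = x[:, 0]
        m = fit_regressor("RF", x, y, {"n_estimators": 100}, seed=0)
        top = rf_importance_topk(m, 1)
        assert top[0] == 0
        imp = m.model.feature_importances_
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(3)
        x, y = rng.random((40, 5)), rng.random(40)
        for kind in ("GBRT", "RF", "BPNN", "ELM"):
            p1 = fit_regressor(kind, x, y, seed=11).predict(x)
            p2 = fit_regressor(kind, x, y, seed=11).predict(x)
            np.testing.assert_array_equal(p1, p2)

    def test_topk_larger_than_feature_count_returns_all(self):
        rng = np.random.default_rng(0)
        m = fit_regressor("RF", rng.random((20, 3)), rng.random(20),
                          {"n_estimators": 10}, seed=0)
        assert len(rf_importance_topk(m, 30)) == 3


def _index_dataset(n_bands=14, n=20):
    rng = np.random.default_rng(8)
    wl = np.linspace(400.0, 2400.0, n_bands)
    meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]})
    return SpectralDataset(wl, rng.uniform(0.05, 0.6, (n, n_bands)), meta)


class TestDualBandIndices:
    def test_ndsi_hand_value(self):
        wl = np.array([670.0, 850.0])
        ds = SpectralDataset(wl, np.array([[0.05, 0.5]]),
                             pd.DataFrame({"sample_id": ["a"]}))
        feats = dual_band_index_features(ds, BandSet(wl), forms=("NDSI",))
        assert feats[0].values[0] == pytest.approx(0.45 / 0.55, abs=1e-4)
        assert feats[0].band_i == 850.0  # longer wavelength first

    def test_pair_counts_for_14_bands(self):
        ds = _index_dataset()
        bands = BandSet(ds.wavelengths)
        assert len(dual_band_index_features(ds, bands, forms=("DSI",))) == 91
        assert len(dual_band_index_features(ds, bands, forms=("RSI",))) == 182
        assert len(dual_band_index_features(ds, bands)) == 91 + 182 + 91

    def test_ndsi_bounded_for_positive_reflectance(self):
        ds = _index_dataset()
        for f in dual_band_index_features(ds, BandSet(ds.wavelengths), forms=("NDSI",)):
            assert np.all(np.abs(f.values) <= 1.0)

    def test_rsi_near_zero_denominator_dropped(self):
        wl = np.array([500.0, 600.0])
        ds = SpectralDataset(wl, np.array([[0.0, 0.4]]),
                             pd.DataFrame({"sample_id": ["a"]}), is_derivative=True)
        with pytest.warns(UserWarning, match="denominator"):
            feats = dual_band_index_features(ds, BandSet(wl), forms=("RSI",))
        assert len(feats) == 1  # only the direction with nonzero denominator

    def test_two_bands_required(self):
        ds = _index_dataset()
        with pytest.raises(ValueError, match="2 bands"):
            dual_band_index_features(ds, BandSet(np.array([500.0])))


class TestRankAndSelect:
    def test_caps_at_requested_totals(self):
        ds = _index_dataset()
        feats = dual_band_index_features(ds, BandSet(ds.wavelengths), forms=("DSI",))
        y = np.random.default_rng(1).random(len(ds))
        sel = rank_and_select_indices(feats, y, top_pos=10, top_neg=10)
        assert len(sel) <= 20

    def test_exact_match_ranks_first(self):
        ds = _index_dataset()
        feats = dual_band_index_features(ds, BandSet(ds.wavelengths), forms=("DSI",))
        y = feats[7].values.copy()
        sel = rank_and_select_indices(feats, y, top_pos=1, top_neg=0)
        assert sel[0].name == feats[7].name

    def test_shortage_warns(self):
        vals = np.arange(6.0)
        feats = [IndexFeature("DSI", 800.0, 600.0, vals)]
        with pytest.warns(UserWarning, match="available"):
            sel = rank_and_select_indices(feats, vals, top_pos=3, top_neg=3)
        assert len(sel) == 1
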