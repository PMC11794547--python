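"""2D correlation spectroscopy: map construction, autopeaks and the
band-selection protocols."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spu.spectra_io import SpectralDataset
from spu.synthetic import worked_fixture_small
from spu.twodcos import (
    BandSet,
    CorrelationMaps,
    asynchronous_map,
    autopeak_bands,
    hilbert_noda_matrix,
    repeated_selection_stability,
    select_bands_1der2dcos,
    select_bands_2t2dcos,
    synchronous_map,
    two_trace_maps,
)
from tests.conftest import make_signal_dataset


def brute_force_maps(x: np.ndarray):
    """Independent double-loop evaluation of the correlation formulas."""
    m, b = x.shape
    y = x - x.mean(axis=0)
    n = hilbert_noda_matrix(m)
    phi = np.zeros((b, b))
    psi = np.zeros((b, b))
    for a in range(b):
        for c in range(b):
            phi[a, c] = sum(y[j, a] * y[j, c] for j in range(m)) / (m - 1)
            psi[a, c] = sum(
                y[j, a] * sum(n[j, k] * y[k, c] for k in range(m)) for j in range(m)
            ) / (m - 1)
    return phi, psi


class TestSynchronousMap:
    def test_hand_example(self):
        phi = synchronous_map(np.array([[1.0, 2.0], [3.0, 6.0]]))
        np.testing.assert_allclose(phi, [[2.0, 4.0], [4.0, 8.0]])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(arrays(float, (6, 9), elements=st.floats(-5, 5, allow_nan=False)))
    def test_symmetric_and_psd(self, x):
        phi = synchronous_map(x)
        np.testing.assert_allclose(phi, phi.T, atol=1e-10)
        assert np.linalg.eigvalsh(phi).min() >= -1e-10

    def test_constant_band_row_and_column_zero(self):
        x = np.column_stack([np.full(5, 0.3), np.random.default_rng(0).random(5)])
        phi = synchronous_map(x)
        np.testing.assert_allclose(phi[0, :], 0.0, atol=1e-15)
        np.testing.assert_allclose(phi[:, 0], 0.0, atol=1e-15)

    def test_single_spectrum_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            synchronous_map(np.array([[1.0, 2.0]]))


class TestAsynchronousMap:
    def test_rank_one_dynamic_spectra_vanish(self):
        psi = asynchronous_map(np.array([[1.0, 2.0], [3.0, 6.0]]))
        np.testing.assert_allclose(psi, 0.0, atol=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(arrays(float, (6, 9), elements=st.floats(-5, 5, allow_nan=False)))
    def test_antisymmetric_zero_diagonal(self, x):
        psi = asynchronous_map(x)
        np.testing.assert_allclose(psi, -psi.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(psi), 0.0, atol=1e-12)

    def test_matches_bruteforce_double_loop(self):
        x = np.random.default_rng(3).random((6, 9))
        phi_b, psi_b = brute_force_maps(x)
        np.testing.assert_allclose(synchronous_map(x), phi_b, atol=1e-10)
        np.testing.assert_allclose(asynchronous_map(x), psi_b, atol=1e-10)


class TestTwoTrace:
    def test_hand_example(self):
        maps = two_trace_maps(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(maps.sync, [[0.5, 0.0], [0.0, 0.5]])
        np.testing.assert_allclose(maps.async_, [[0.0, 0.5], [-0.5, 0.0]])
        assert maps.kind == "two_trace"

    def test_identical_traces_have_zero_async(self):
        a = np.random.default_rng(0).random(12)
        np.testing.assert_allclose(two_trace_maps(a, a).async_, 0.0, atol=1e-15)

    def test_bilinearity_under_common_scaling(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(8), rng.random(8)
        m1 = two_trace_maps(a, b)
        m2 = two_trace_maps(3.0 * a, 3.0 * b)
        np.testing.assert_allclose(m2.sync, 9.0 * m1.sync, atol=1e-12)
        np.testing.assert_allclose(m2.async_, 9.0 * m1.async_, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical grids"):
            two_trace_maps(np.zeros(3), np.zeros(4))


class TestAutopeaks:
    def _maps(self, diag):
        b = len(diag)
        return CorrelationMaps(
            400.0 + np.arange(b, dtype=float), np.diag(diag), np.zeros((b, b))
        )

    def test_single_dominant_peak(self):
        bands = autopeak_bands(self._maps([0.1, 0.9, 0.2]), rel_threshold=0.5)
        np.testing.assert_allclose(bands.wavelengths, [401.0])

    def test_close_equal_peaks_merge_to_lower_wavelength(self):
        diag = [0.0, 0.9, 0.0, 0.0, 0.9, 0.0, 0.0]  # peaks 3 nm apart
        bands = autopeak_bands(self._maps(diag), rel_threshold=0.5, min_separation_nm=5.0)
        np.testing.assert_allclose(bands.wavelengths, [401.0])

    def test_zero_diagonal_yields_empty_set(self):
        assert len(autopeak_bands(self._maps([0.0] * 5))) == 0

    def test_scale_invariance(self):
        ds = make_signal_dataset(7, n=30, hi=700.0)
        b1 = select_bands_1der2dcos(ds, "t")
        ds2 = SpectralDataset(
            ds.wavelengths, ds.reflectance * 0.5, ds.meta, ds.traits
        )
        b2 = select_bands_1der2dcos(ds2, "t")
        np.testing.assert_array_equal(b1.wavelengths, b2.wavelengths)

    def test_support_must_be_positive(self):
        with pytest.raises(ValueError, match="support"):
            BandSet(np.array([500.0]), support=np.array([0]))


class TestTraitOrderedSelection:
    def test_planted_band_recovered(self):
        ds = make_signal_dataset(11, n=50, hi=700.0)
        bands = select_bands_1der2dcos(ds, "t")
        assert any(abs(w - 550.0) <= 15.0 for w in bands.wavelengths)

    def test_constant_trait_rejected(self):
        ds = make_signal_dataset(0, n=20, hi=500.0)
        ds.traits["t"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            select_bands_1der2dcos(ds, "t")


class TestTwoTraceConsensus:
    def _stage_pair(self, n=12, center=520.0):
        rng = np.random.default_rng(5)
        wl = np.arange(400.0, 651.0)
        meta = pd.DataFrame({"sample_id": [f"p{i:02d}" for i in range(n)]})
        base = 0.3 + 0.0003 * (wl - 400.0)
        def build(depth):
            x = np.tile(base, (n, 1))
            x = x - depth * rng.uniform(0.5, 1.5, n)[:, None] * np.exp(
                -0.5 * ((wl - center) / 12.0) ** 2
            )
            return SpectralDataset(wl, np.clip(x + rng.normal(0, 1e-4, x.shape), 0, 1), meta.copy())
        return build(0.10), build(0.06)

    def test_majority_rule_is_strict(self):
        a, b = self._stage_pair()
        bands = select_bands_2t2dcos(a, b, majority_fraction=0.5)
        assert len(bands) > 0
        assert all(s > 0.5 * 12 for s in bands.support)

    def test_unpaired_sample_ids_listed(self):
        a, b = self._stage_pair()
        b.meta.loc[0, "sample_id"] = "stranger"
        with pytest.raises(ValueError, match="stranger"):
            select_bands_2t2dcos(a, b)

    def test_identical_stages_still_produce_sync_autopeaks(self):
        a, _ = self._stage_pair()
        bands = select_bands_2t2dcos(a, a, majority_fraction=0.5)
        assert len(bands) > 0  # async vanishes pairwise, sync diagonal does not


class TestRepeatedSelectionStability:
    def test_full_fraction_draws_are_identical(self):
        ds = make_signal_dataset(3, n=30, hi=700.0)
        res = repeated_selection_stability(ds, "t", fractions=[1.0], n_draws=5,
                                           min_count=5, seed=0)
        counts = res.counts[1.0]
        assert (counts == 5).all()

    def test_stable_set_shrinks_with_min_count(self):
        ds = make_signal_dataset(4, n=40, hi=700.0)
        sizes = []
        for mc in (3, 6, 9):
            res = repeated_selection_stability(ds, "t", fractions=[0.5], n_draws=10,
                                               min_count=mc, seed=1)
            sizes.append(len(res.stable[0.5]))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_small_fraction_skipped_with_warning(self):
        ds = make_signal_dataset(5, n=20, hi=600.0)
        with pytest.warns(UserWarning, match="skipped"):
            res = repeated_selection_stability(ds, "t", fractions=[0.2], n_draws=10,
                                               min_count=8, seed=0)
        assert 0.2 not in res.stable


class TestWorkedFixture:
    def test_sync_matches_bruteforce_to_1e12(self):
        ds = worked_fixture_small()
        order = np.argsort(ds.trait("conc"))
        phi_b, psi_b = brute_force_maps(ds.reflectance[order])
        np.testing.assert_allclose(synchronous_map(ds.reflectance[order]), phi_b, atol=1e-12)
        np.testing.assert_allclose(asynchronous_map(ds.reflectance[order]), -psi_b.T, atol=1e-12)

    def test_reload_stability(self):
        a, b = worked_fixture_small(), worked_fixture_small()
        np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_absorption_band_is_selected(self):
        ds = worked_fixture_small()
        bands = select_bands_1der2dcos(ds, "conc", deriv_window=5, deriv_poly=2)
        assert any(abs(w - 450.0) <= 20.0 for w in bands.wavelengths)
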