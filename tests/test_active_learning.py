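"""Representative selection, Eq. 1/Eq. 2 filters and the augmentation
loop of the NRBO-AL strategy."""

import numpy as np
import pytest

from spu.active_learning import (
    ALConfig,
    ALState,
    al_augment_loop,
    candidate_pool_from_nrbo,
    filter_eq1,
    filter_eq2,
    fit_linear_response_model,
    pick_representative_subset,
    verify_constraints,
)
from spu.rtm import MAIZE_RANGES, generate_lut
from spu.rtm.forward import SimulatedLUT


class TestRepresentativeSubset:
    def test_kennard_stone_covers_separated_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.1, (10, 3))
        b = rng.normal(5.0, 0.1, (10, 3))
        x = np.vstack([a, b])
        idx = pick_representative_subset(x, 2, method="kennard_stone")
        assert (idx < 10).sum() == 1 and (idx >= 10).sum() == 1

    def test_kennard_stone_matches_bruteforce_maxmin_seed_pair(self):
        x = np.random.default_rng(1).random((12, 4))
        idx = pick_representative_subset(x, 2, method="kennard_stone")
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        assert set(idx) == {min(i, j), max(i, j)}

    def test_k_equals_n_minus_one(self):
        x = np.random.default_rng(2).random((8, 2))
        assert len(pick_representative_subset(x, 7)) == 7

    def test_random_method_reproducible(self):
        x = np.random.default_rng(3).random((15, 3))
        a = pick_representative_subset(x, 5, method="random", seed=9)
        b = pick_representative_subset(x, 5, method="random", seed=9)
        np.testing.assert_array_equal(a, b)

    def test_k_not_below_n_rejected(self):
        with pytest.raises(ValueError, match="K"):
            pick_representative_subset(np.zeros((5, 2)), 5)

    def test_spxy_requires_response(self):
        with pytest.raises(ValueError, match="spxy"):
            pick_representative_subset(np.zeros((5, 2)), 2, method="spxy")


class TestSpectralFilter:
    def test_strict_boundary_excluded(self):
        reps = np.array([[0.0, 0.0]])
        kept = filter_eq1(np.array([[3.0, 4.0]]), reps, 5.0)  # distance exactly 5
        assert len(kept) == 0

    def test_interior_point_kept(self):
        kept = filter_eq1(np.array([[0.3, 0.4]]), np.array([[0.0, 0.0]]), 1.0)
        np.testing.assert_array_equal(kept, [0])

    def test_monotone_in_epsilon(self):
        rng = np.random.default_rng(4)
        cands, reps = rng.random((200, 6)), rng.random((10, 6))
        small = set(filter_eq1(cands, reps, 0.3))
        large = set(filter_eq1(cands, reps, 0.6))
        assert small <= large

    def test_quantile_mode_keeps_expected_share(self):
        rng = np.random.default_rng(5)
        cands, reps = rng.random((1000, 4)), rng.random((8, 4))
        from spu.active_learning import resolve_epsilon_spectral

        eps = resolve_epsilon_spectral(("quantile", 0.1), cands, reps)
        frac = len(filter_eq1(cands, reps, eps)) / 1000
        assert 0.05 <= frac <= 0.15

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            filter_eq1(np.zeros((2, 2)), np.zeros((1, 2)), 0.0)


class TestResponseFilter:
    def _model(self, seed=0, n=20, p=6):
        rng = np.random.default_rng(seed)
        x = rng.random((n, p))
        beta = rng.normal(size=p)
        y = x @ beta + 1.0
        return fit_linear_response_model(x, y, max_bands=p), x, beta

    def test_consistent_candidates_all_kept(self):
        model, x, beta = self._model()
        rng = np.random.default_rng(1)
        cands = rng.random((50, x.shape[1]))
        y_t = model.predict(cands)  # exactly consistent
        assert len(filter_eq2(cands, y_t, model, 1e-6)) == 50

    def test_shifted_responses_all_dropped(self):
        model, x, _ = self._model()
        cands = np.random.default_rng(2).random((30, x.shape[1]))
        y_t = model.predict(cands) + 10.0 * 0.5
        assert len(filter_eq2(cands, y_t, model, 0.5)) == 0

    def test_mixed_pool_matches_direct_inequality(self):
        model, x, _ = self._model(3)
        rng = np.random.default_rng(3)
        cands = rng.random((100, x.shape[1]))
        y_t = model.predict(cands) + rng.normal(0.0, 0.4, 100)
        eps = 0.3
        kept = filter_eq2(cands, y_t, model, eps)
        expected = np.flatnonzero(np.abs(model.predict(cands) - y_t) < eps)
        np.testing.assert_array_equal(kept, expected)

    def test_wide_design_falls_back_to_ridge_band_subset(self):
        rng = np.random.default_rng(6)
        x = rng.random((8, 50))
        y = rng.random(8)
        model = fit_linear_response_model(x, y, max_bands=10)
        assert len(model.band_idx) <= 6  # capped below sample count
        assert np.isfinite(model.predict(x)).all()


def _toy_lut(n=300, seed=0):
    lut = generate_lut(n=n, seed=seed, windows=[(700.0, 760.0)])
    return lut


class TestCandidatePool:
    def test_exact_archive_arithmetic(self):
        reps = _toy_lut(20, 3)
        pool = candidate_pool_from_nrbo(
            reps.reflectance, reps.wavelengths, pool_target=100, pop=20, iters=4, seed=0
        )
        assert len(pool) == 100  # one restart: pop * (iters + 1)

    def test_deterministic_under_seed(self):
        reps = _toy_lut(10, 4)
        a = candidate_pool_from_nrbo(reps.reflectance, reps.wavelengths,
                                     pool_target=60, pop=10, iters=2, seed=5)
        b = candidate_pool_from_nrbo(reps.reflectance, reps.wavelengths,
                                     pool_target=60, pop=10, iters=2, seed=5)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_pool_concentrates_near_representative_centroid(self):
        reps = _toy_lut(15, 6)
        pool = candidate_pool_from_nrbo(reps.reflectance, reps.wavelengths,
                                        pool_target=200, pop=20, iters=9, seed=1)
        uniform = _toy_lut(200, 7)
        centroid = reps.reflectance.mean(axis=0)
        d_pool = np.linalg.norm(pool.reflectance - centroid, axis=1).mean()
        d_unif = np.linalg.norm(uniform.reflectance - centroid, axis=1).mean()
        assert d_pool < d_unif


class TestAugmentLoop:
    def _state(self, seed=0, n_measured=30, pool=400):
        rng = np.random.default_rng(seed)
        lut = _toy_lut(pool, seed)
        noise = rng.normal(0.0, 0.005, (n_measured, len(lut.wavelengths)))
        idx = rng.choice(pool, n_measured, replace=False)
        measured_x = np.clip(lut.reflectance[idx] + noise, 0.0, 1.0)
        measured_y = lut.response[idx]
        rep = pick_representative_subset(measured_x, 8)
        return ALState(measured_x, measured_y, rep, lut)

    def test_budget_never_exceeded(self):
        state = al_augment_loop(self._state(), ALConfig(max_new_fraction=0.10))
        assert len(state.new_idx) <= int(np.floor(0.10 * 30))

    def test_zero_budget_leaves_measured_side_unchanged(self):
        state = al_augment_loop(self._state(1), ALConfig(max_new_fraction=0.01))
        assert len(state.new_idx) == 0  # floor(0.01 * 30) = 0 new samples

    def test_selected_candidates_satisfy_both_constraints(self):
        cfg = ALConfig()
        state = al_augment_loop(self._state(2), cfg)
        ok, info = verify_constraints(state, cfg)
        assert ok, info

    def test_log_rmse_non_increasing(self):
        state = al_augment_loop(self._state(3), ALConfig(max_new_fraction=0.2))
        rmse = state.log["rmse"].to_numpy()
        assert np.all(np.diff(rmse) <= 1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ALConfig(max_new_fraction=0.0)
        with pytest.raises(ValueError):
            ALConfig(epsilon_spectral=-1.0)
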