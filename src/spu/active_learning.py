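"""NRBO-based active learning for hybrid-model training sets.

A hybrid retrieval model is trained on simulated (reflectance,
response) pairs; simulation that strays far from the measured field
spectra hurts it.  The sampling strategy here constrains the simulated
training pool in two steps, then grows the measured side greedily:

1. spectral constraint — keep a simulated sample x_t only if its
   shortest Euclidean distance to the representative measured set X_m
   is below a threshold: ``min_m ||x_t - x_m|| < eps_spectral``;
2. response constraint — fit a multiple linear regression f on the
   representative samples and keep x_t only if the simulated response
   agrees with it: ``|f(x_t) - y_t| < eps_response``;
3. augmentation — iteratively move the measured sample whose inclusion
   in the representative set most reduces the RMSE of f into the
   training set, re-applying the response filter, up to a budget of
   ``floor(max_new_fraction * N)`` new samples.

The candidate pool itself comes from the archive of an NRBO run that
pulls simulated spectra toward the centroid of the representatives,
which concentrates candidates near the measured manifold before any
filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optimizers import nrbo_minimize
from .rtm import forward as rtm_forward

__all__ = [
    "ALConfig",
    "ALState",
    "pick_representative_subset",
    "candidate_pool_from_nrbo",
    "filter_eq1",
    "filter_eq2",
    "al_augment_loop",
    "fit_linear_response_model",
]


@dataclass
class ALConfig:
    """Thresholds and budgets of the sampling strategy.

    Epsilons are either absolute values or ``("quantile", q)`` pairs
    resolved against the empirical candidate distances (spectral) or
    the representative-response spread (response: ``q`` multiplies the
    sample SD).
    """

    epsilon_spectral: float | tuple = ("quantile", 0.01)
    epsilon_response: float | tuple = ("sd_fraction", 0.25)
    K_representative: int = 12
    max_new_fraction: float = 0.10
    distance: str = "euclidean"
    ols_max_bands: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.max_new_fraction <= 1.0:
            raise ValueError("max_new_fraction must be in (0, 1]")
        for name in ("epsilon_spectral", "epsilon_response"):
            v = getattr(self, name)
            if not isinstance(v, tuple) and v <= 0:
                raise ValueError(f"{name} must be positive or quantile-specified")


@dataclass
class LinearResponseModel:
    """OLS (ridge fallback) map from a band subset of the spectrum to
    the response; the f(x) of the response constraint."""

    band_idx: np.ndarray
    coef: np.ndarray
    intercept: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x[:, self.band_idx] @ self.coef + self.intercept


def fit_linear_response_model(
    x: np.ndarray, y: np.ndarray, max_bands: int = 10, ridge: float = 1e-3
) -> LinearResponseModel:
    """Fit f on representative samples.

    When the band count is not small relative to the sample count, OLS
    is not identifiable on the full spectrum; the model then uses the
    ``max_bands`` highest-variance bands (ridge-regularised if the
    design is still ill-conditioned)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    k = min(p, max_bands, max(1, n - 2))
    band_idx = np.sort(np.argsort(-x.var(axis=0))[:k])
    a = np.column_stack([x[:, band_idx], np.ones(n)])
    gram = a.T @ a
    if np.linalg.cond(gram) > 1e10:
        warnings.warn("singular design in response model; ridge fallback")
        gram = gram + ridge * np.eye(len(gram))
    coef = np.linalg.solve(gram, a.T @ y)
    return LinearResponseModel(band_idx=band_idx, coef=coef[:-1], intercept=float(coef[-1]))


@dataclass
class ALState:
    """Everything the augmentation loop operates on."""

    measured_x: np.ndarray  # (N, p) masked reflectance
    measured_y: np.ndarray  # (N,) responses
    rep_idx: np.ndarray  # indices into measured set
    candidates: rtm_forward.SimulatedLUT
    selected_candidates: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    new_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    model: LinearResponseModel | None = None
    log: pd.DataFrame | None = None

    @property
    def training_x(self) -> np.ndarray:
        keep = np.concatenate([self.rep_idx, self.new_idx]).astype(int)
        return np.vstack([self.candidates.reflectance[self.selected_candidates],
                          self.measured_x[keep]])

    @property
    def training_y(self) -> np.ndarray:
        keep = np.concatenate([self.rep_idx, self.new_idx]).astype(int)
        return np.concatenate([self.candidates.response[self.selected_candidates],
                               self.measured_y[keep]])


def _pairwise_min_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min over rows of b of ||a_i - b_j||, for each row of a."""
    d2 = (
        np.sum(a**2, axis=1)[:, None]
        - 2.0 * a @ b.T
        + np.sum(b**2, axis=1)[None, :]
    )
    return np.sqrt(np.clip(d2, 0.0, None).min(axis=1))


def pick_representative_subset(
    x: np.ndarray,
    k: int,
    method: str = "kennard_stone",
    seed: int | None = None,
    y: np.ndarray | None = None,
) -> np.ndarray:
    """Choose K representative samples covering the spectral space.

    ``kennard_stone`` seeds with the two most distant samples and
    repeatedly adds the sample farthest from the chosen set (max-min);
    ``spxy`` does the same on a distance mixing spectra and response;
    ``random`` is the seeded uniform baseline.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if k >= n:
        raise ValueError(f"K={k} must be < N={n}")
    if method == "random":
        rng = np.random.default_rng(seed)
        return np.sort(rng.choice(n, size=k, replace=False))
    if method == "spxy":
        if y is None:
            raise ValueError("spxy requires responses y")
        dx = np.sqrt(np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2))
        dy = np.abs(np.asarray(y, float)[:, None] - np.asarray(y, float)[None, :])
        dist = dx / max(dx.max(), 1e-30) + dy / max(dy.max(), 1e-30)
    elif method == "kennard_stone":
        dist = np.sqrt(np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2))
    else:
        raise ValueError(f"unknown method {method!r}")
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    chosen = [int(min(i, j)), int(max(i, j))]
    while len(chosen) < k:
        rest = [m for m in range(n) if m not in chosen]
        mind = dist[np.ix_(rest, chosen)].min(axis=1)
        chosen.append(rest[int(np.argmax(mind))])
    return np.sort(np.array(chosen[:k], dtype=int))


def candidate_pool_from_nrbo(
    representatives: np.ndarray,
    wavelengths: np.ndarray,
    ranges: dict | None = None,
    pool_target: int = 2000,
    seed: int | None = None,
    pop: int = 20,
    iters: int = 8,
) -> rtm_forward.SimulatedLUT:
    """Build a simulated candidate pool concentrated near the measured
    centroid.

    Runs NRBO (archive kept) on ``theta -> ||forward(theta) -
    centroid(X_m)||`` over the free parameter ranges; the archive of
    all evaluated parameter vectors, truncated to ``pool_target``,
    becomes the candidate pool with response 100*LAI*Cm.  Short runs
    (``iters`` small) restarted as often as needed keep the pool
    diverse: each restart contributes its whole trajectory from random
    initialization toward the measured centroid.
    """
    if pool_target < 1:
        raise ValueError("pool_target must be >= 1")
    ranges = dict(rtm_forward.MAIZE_RANGES if ranges is None else ranges)
    free = {k: v for k, v in ranges.items() if isinstance(v, (tuple, list))}
    fixed = {k: float(v) for k, v in ranges.items() if not isinstance(v, (tuple, list))}
    if not free:
        raise ValueError("no free parameter intervals in ranges")
    names = list(free)
    bounds = np.array([free[k] for k in names], dtype=float)
    centroid = np.asarray(representatives, dtype=float).mean(axis=0)
    grid_idx = np.searchsorted(rtm_forward.WAVELENGTHS, wavelengths)
    if not np.allclose(rtm_forward.WAVELENGTHS[grid_idx], wavelengths):
        raise ValueError("wavelengths must lie on the simulation grid")

    def objective(theta: np.ndarray) -> float:
        p = dict(fixed)
        p.update(dict(zip(names, theta)))
        spec = rtm_forward.simulate_batch(pd.DataFrame([p]))[0, grid_idx]
        return float(np.linalg.norm(spec - centroid))

    rng = np.random.default_rng(seed)
    thetas: list[np.ndarray] = []
    total = 0
    while total < pool_target:
        res = nrbo_minimize(
            objective, bounds, pop=pop, iters=iters,
            seed=int(rng.integers(2**31)), keep_archive=True,
        )
        thetas.append(res.evaluated_x)
        total += len(res.evaluated_x)
    theta_all = np.concatenate(thetas)[:pool_target]
    params = pd.DataFrame(theta_all, columns=names)
    for k, v in fixed.items():
        params[k] = v
    refl = np.empty((pool_target, len(grid_idx)))
    chunk = 2000
    for s in range(0, pool_target, chunk):
        sl = slice(s, min(s + chunk, pool_target))
        refl[sl] = rtm_forward.simulate_batch(params.iloc[sl])[:, grid_idx]
    response = 100.0 * params["LAI"].to_numpy() * params["Cm"].to_numpy()
    return rtm_forward.SimulatedLUT(params, np.asarray(wavelengths, float), refl, response)


def resolve_epsilon_spectral(
    eps, candidates_x: np.ndarray, representatives_x: np.ndarray
) -> float:
    if isinstance(eps, tuple):
        mode, q = eps
        if mode != "quantile":
            raise ValueError(f"unknown spectral epsilon mode {mode!r}")
        return float(np.quantile(_pairwise_min_dist(candidates_x, representatives_x), q))
    if eps <= 0:
        raise ValueError("epsilon_spectral must be positive")
    return float(eps)


def resolve_epsilon_response(eps, representative_y: np.ndarray) -> float:
    if isinstance(eps, tuple):
        mode, q = eps
        if mode != "sd_fraction":
            raise ValueError(f"unknown response epsilon mode {mode!r}")
        return float(q * np.std(representative_y, ddof=1))
    if eps <= 0:
        raise ValueError("epsilon_response must be positive")
    return float(eps)


def filter_eq1(
    candidates_x: np.ndarray, representatives_x: np.ndarray, epsilon_spectral: float
) -> np.ndarray:
    """Indices of candidates within (strictly) ``epsilon_spectral`` of
    the nearest representative spectrum."""
    if epsilon_spectral <= 0:
        raise ValueError("epsilon_spectral must be positive")
    d = _pairwise_min_dist(np.asarray(candidates_x, float), np.asarray(representatives_x, float))
    return np.flatnonzero(d < epsilon_spectral)


def filter_eq2(
    candidates_x: np.ndarray,
    candidates_y: np.ndarray,
    model: LinearResponseModel,
    epsilon_response: float,
) -> np.ndarray:
    """Indices of candidates whose simulated response (strictly) agrees
    with the representative-sample regression: |f(x_t) - y_t| < eps."""
    if epsilon_response <= 0:
        raise ValueError("epsilon_response must be positive")
    resid = np.abs(model.predict(candidates_x) - np.asarray(candidates_y, float))
    return np.flatnonzero(resid < epsilon_response)


def al_augment_loop(state: ALState, cfg: ALConfig) -> ALState:
    """Greedy augmentation of the training set from the measured pool.

    Each iteration adds the unused measured sample whose inclusion in
    the representative set most reduces the RMSE of f over all
    measured samples, refits f, and re-applies the response filter to
    the spectrally-admissible candidates; stops at
    ``floor(max_new_fraction * N)`` additions or when no sample
    improves the RMSE.
    """
    n = len(state.measured_x)
    budget = int(np.floor(cfg.max_new_fraction * n))
    eps1 = resolve_epsilon_spectral(
        cfg.epsilon_spectral, state.candidates.reflectance, state.measured_x[state.rep_idx]
    )
    eq1_idx = filter_eq1(
        state.candidates.reflectance, state.measured_x[state.rep_idx], eps1
    )

    def refit(rep: np.ndarray) -> tuple[LinearResponseModel, float]:
        m = fit_linear_response_model(
            state.measured_x[rep], state.measured_y[rep], max_bands=cfg.ols_max_bands
        )
        rmse = float(np.sqrt(np.mean((m.predict(state.measured_x) - state.measured_y) ** 2)))
        return m, rmse

    rep = np.asarray(state.rep_idx, dtype=int)
    model, rmse = refit(rep)
    eps2 = resolve_epsilon_response(cfg.epsilon_response, state.measured_y[rep])
    sel = eq1_idx[filter_eq2(
        state.candidates.reflectance[eq1_idx],
        state.candidates.response[eq1_idx], model, eps2,
    )]
    new: list[int] = []
    rows = [{"iteration": 0, "added_sample": -1, "kept_candidates": len(sel), "rmse": rmse}]
    for it in range(1, budget + 1):
        unused = np.setdiff1d(np.arange(n), np.concatenate([rep, np.array(new, int)]))
        if not len(unused):
            break
        best_s, best_rmse, best_model = -1, rmse, model
        for s in unused:
            m_try, rmse_try = refit(np.concatenate([rep, np.array(new + [s], int)]))
            if rmse_try < best_rmse - 1e-12:
                best_s, best_rmse, best_model = int(s), rmse_try, m_try
        if best_s < 0:
            break  # no sample improves f
        new.append(best_s)
        model, rmse = best_model, best_rmse
        eps2 = resolve_epsilon_response(
            cfg.epsilon_response, state.measured_y[np.concatenate([rep, np.array(new, int)])]
        )
        keep2 = filter_eq2(
            state.candidates.reflectance[eq1_idx],
            state.candidates.response[eq1_idx], model, eps2,
        )
        sel = eq1_idx[keep2]
        rows.append({"iteration": it, "added_sample": best_s,
                     "kept_candidates": len(sel), "rmse": rmse})

    state.selected_candidates = np.asarray(sel, dtype=int)
    state.new_idx = np.asarray(new, dtype=int)
    state.model = model
    state.log = pd.DataFrame(rows)
    return state


def verify_constraints(state: ALState, cfg: ALConfig) -> tuple[bool, dict]:
    """Direct assertion that every selected candidate satisfies both
    strict inequalities with the final model/thresholds."""
    rep_and_new = np.concatenate([state.rep_idx, state.new_idx]).astype(int)
    eps1 = resolve_epsilon_spectral(
        cfg.epsilon_spectral, state.candidates.reflectance, state.measured_x[state.rep_idx]
    )
    eps2 = resolve_epsilon_response(cfg.epsilon_response, state.measured_y[rep_and_new])
    x = state.candidates.reflectance[state.selected_candidates]
    yt = state.candidates.response[state.selected_candidates]
    d1 = _pairwise_min_dist(x, state.measured_x[state.rep_idx])
    d2 = np.abs(state.model.predict(x) - yt)
    ok = bool(np.all(d1 < eps1) and np.all(d2 < eps2))
    return ok, {"eps_spectral": eps1, "eps_response": eps2,
                "max_d1": float(d1.max(initial=0.0)), "max_d2": float(d2.max(initial=0.0))}
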