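"""Metaheuristic calibration of the low-sensitivity forward-model
parameters against measured canopy spectra.

The free (high-sensitivity) parameters keep their sampling intervals;
the fixed parameters are point values that must suit the local crop and
soil.  This module finds those point values by minimising the RMSE
between a forward-simulated spectrum and the mean measured spectrum
over the modeling windows, using the sparrow-search hybrid optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..optimizers import OptResult, scassa_minimize
from . import forward


@dataclass
class CalibrationResult:
    params: forward.ProsailParams
    fixed_values: dict[str, float]
    objective: float
    history: np.ndarray


def _interval_midpoints(ranges: dict[str, tuple[float, float] | float]) -> dict[str, float]:
    out = {}
    for k, v in ranges.items():
        out[k] = 0.5 * (v[0] + v[1]) if isinstance(v, (tuple, list)) else float(v)
    return out


def calibrate_fixed_params(
    wavelengths: np.ndarray,
    reflectance: np.ndarray,
    fixed_bounds: dict[str, tuple[float, float]],
    free_values: dict[str, float] | None = None,
    pop: int = 30,
    iters: int = 60,
    restarts: int = 1,
    seed: int | None = None,
) -> CalibrationResult:
    """Calibrate the fixed parameters named in ``fixed_bounds``.

    ``reflectance`` is a (n_samples, n_wl) measured matrix on
    ``wavelengths`` (a subset of the simulation grid, typically already
    masked to the modeling windows); the objective is the RMSE between
    the forward spectrum and the measured mean spectrum on that grid.
    ``free_values`` pins the non-calibrated parameters (defaults: the
    midpoints of the maize ranges).

    Returns the best parameter set and the best-so-far objective trace
    of the winning restart.
    """
    if pop * iters == 0:
        raise ValueError("optimizer budget must be positive")
    wavelengths = np.asarray(wavelengths, dtype=float)
    target = np.asarray(reflectance, dtype=float)
    if target.ndim == 2:
        target = target.mean(axis=0)
    grid_idx = np.searchsorted(forward.WAVELENGTHS, wavelengths)
    if not np.allclose(forward.WAVELENGTHS[grid_idx], wavelengths):
        raise ValueError("measured wavelengths must lie on the 1 nm simulation grid")

    base = _interval_midpoints(forward.MAIZE_RANGES)
    if free_values:
        base.update(free_values)
    names = list(fixed_bounds)
    bounds = np.array([fixed_bounds[k] for k in names], dtype=float)

    def objective(x: np.ndarray) -> float:
        p = dict(base)
        p.update(dict(zip(names, x)))
        spec = forward.simulate_batch(pd.DataFrame([p]))[0, grid_idx]
        return float(np.sqrt(np.mean((spec - target) ** 2)))

    best: OptResult | None = None
    rng = np.random.default_rng(seed)
    for _ in range(max(1, restarts)):
        res = scassa_minimize(objective, bounds, pop=pop, iters=iters, seed=int(rng.integers(2**31)))
        if best is None or res.best_f < best.best_f:
            best = res

    fixed_values = dict(zip(names, best.best_x))
    final = dict(base)
    final.update(fixed_values)
    params = forward.ProsailParams(**{k: final[k] for k in forward.ProsailParams.names() if k in final})
    return CalibrationResult(
        params=params, fixed_values=fixed_values, objective=best.best_f, history=best.history
    )
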