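"""Population metaheuristics used by the calibration and active-learning
stages: a Newton-Raphson-based optimizer (NRBO) and a sparrow-search
hybrid with sine-cosine producer updates and Levy-flight perturbations.

Both optimizers share the same contract: box bounds enforced by
clamping, exactly one objective evaluation per individual per
iteration (so an archive holds ``pop * (iters + 1)`` points), greedy
per-individual replacement (hence a non-increasing best-so-far
history) and full determinism under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma

__all__ = ["OptResult", "nrbo_minimize", "scassa_minimize"]


@dataclass
class OptResult:
    """Outcome of a metaheuristic run."""

    best_x: np.ndarray
    best_f: float
    history: np.ndarray  # best-so-far objective per iteration (incl. init)
    evaluated_x: np.ndarray | None = None  # archive of evaluated points
    evaluated_f: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.history) > 1e-12):
            raise ValueError("history must be non-increasing (best-so-far)")


def _check_bounds(bounds: np.ndarray) -> np.ndarray:
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be an (n_dim, 2) array")
    if not np.all(np.isfinite(bounds)) or np.any(bounds[:, 1] < bounds[:, 0]):
        raise ValueError("bounds must be finite with hi >= lo")
    return bounds


def _levy_step(rng: np.random.Generator, size: int, beta: float = 1.5) -> np.ndarray:
    """Levy-stable step via Mantegna's algorithm."""
    sigma_u = (
        gamma(1.0 + beta) * np.sin(np.pi * beta / 2.0)
        / (gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size)
    v = rng.normal(0.0, 1.0, size)
    return u / np.abs(v) ** (1.0 / beta)


def nrbo_minimize(
    objective,
    bounds,
    pop: int = 30,
    iters: int = 200,
    deciding_factor: float = 0.6,
    seed: int | None = None,
    keep_archive: bool = False,
) -> OptResult:
    """Newton-Raphson-based optimizer.

    Candidate moves follow a population-level Newton-Raphson search
    rule (a secant-like step built from the current best and worst
    individuals) plus a trap-avoidance operator applied with
    probability ``deciding_factor``; every candidate is clamped to the
    bounds, evaluated once, and accepted greedily.
    """
    if pop < 4:
        raise ValueError("pop must be >= 4")
    bounds = _check_bounds(bounds)
    d = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(seed)

    X = lo + (hi - lo) * rng.random((pop, d))
    F = np.array([float(objective(x)) for x in X])
    arch_x = [X.copy()] if keep_archive else None
    arch_f = [F.copy()] if keep_archive else None

    history = [float(F.min())]
    for it in range(1, iters + 1):
        ib, iw = int(np.argmin(F)), int(np.argmax(F))
        xb, xw = X[ib], X[iw]
        delta = (1.0 - 2.0 * it / iters) ** 5
        Xnew = np.empty_like(X)
        for i in range(pop):
            r1, r2 = rng.choice([j for j in range(pop) if j != i], size=2, replace=False)
            a, b = rng.random(), rng.random()
            rho = a * (xb - X[i]) + b * (X[r1] - X[r2])
            dx = rng.random(d) * np.abs(xb - X[i])
            denom = 2.0 * (xb + xw - 2.0 * X[i])
            denom = np.where(np.abs(denom) < 1e-12, 1e-12 * np.sign(denom + 1e-30), denom)
            nrsr = rng.standard_normal() * (xw - xb) * dx / denom
            x1 = X[i] - nrsr + rho
            x2 = xb - nrsr + rho
            x3 = X[i] - delta * (x2 - x1)
            ra, rb = rng.random(), rng.random()
            cand = ra * (rb * x1 + (1.0 - rb) * x2) + (1.0 - ra) * x3
            if rng.random() < deciding_factor:
                # trap avoidance: jump built from best and population mean
                theta1 = rng.uniform(-1.0, 1.0)
                theta2 = rng.uniform(-0.5, 0.5)
                if rng.random() < 0.5:
                    mu1, mu2 = 3.0 * rng.random(), rng.random()
                else:
                    mu1, mu2 = 1.0, 1.0
                cand = cand + theta1 * (mu1 * xb - mu2 * cand) + theta2 * delta * (
                    mu1 * X.mean(axis=0) - mu2 * cand
                )
            Xnew[i] = np.clip(cand, lo, hi)
        Fnew = np.array([float(objective(x)) for x in Xnew])
        if keep_archive:
            arch_x.append(Xnew.copy())
            arch_f.append(Fnew.copy())
        better = Fnew < F
        X[better] = Xnew[better]
        F[better] = Fnew[better]
        history.append(min(history[-1], float(F.min())))

    ib = int(np.argmin(F))
    return OptResult(
        best_x=X[ib].copy(),
        best_f=float(F[ib]),
        history=np.asarray(history),
        evaluated_x=np.concatenate(arch_x) if keep_archive else None,
        evaluated_f=np.concatenate(arch_f) if keep_archive else None,
    )


def scassa_minimize(
    objective,
    bounds,
    pop: int = 30,
    iters: int = 200,
    seed: int | None = None,
    keep_archive: bool = False,
    producer_fraction: float = 0.2,
    scout_fraction: float = 0.1,
    alarm_threshold: float = 0.8,
    levy_beta: float = 1.5,
) -> OptResult:
    """Sparrow-search hybrid with chaotic initialization, sine-cosine
    producer moves and Levy-flight scrounger perturbations.

    Producers (best ``producer_fraction`` of the flock) move with a
    sine-cosine operator contracting toward the current best;
    scroungers follow the best producer with Levy-distributed steps;
    a random ``scout_fraction`` performs anti-predation jumps.
    """
    if pop < 4:
        raise ValueError("pop must be >= 4")
    bounds = _check_bounds(bounds)
    d = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(seed)

    # logistic-map chaotic initialization
    z = rng.uniform(0.05, 0.95, (pop, d))
    for _ in range(20):
        z = 4.0 * z * (1.0 - z)
    X = lo + (hi - lo) * z
    F = np.array([float(objective(x)) for x in X])
    arch_x = [X.copy()] if keep_archive else None
    arch_f = [F.copy()] if keep_archive else None

    n_prod = max(2, int(round(producer_fraction * pop)))
    n_scout = max(1, int(round(scout_fraction * pop)))
    history = [float(F.min())]
    for it in range(1, iters + 1):
        order = np.argsort(F)
        X, F = X[order], F[order]
        xb, fb = X[0].copy(), float(F[0])
        xw, fw = X[-1].copy(), float(F[-1])
        amp = 2.0 * (1.0 - it / iters)  # sine-cosine amplitude decay
        Xnew = X.copy()

        alarm = rng.random()
        for i in range(n_prod):
            if alarm < alarm_threshold:
                r2, r3 = rng.random(d) * 2.0 * np.pi, rng.random(d) * 2.0
                trig = np.sin(r2) if rng.random() < 0.5 else np.cos(r2)
                Xnew[i] = X[i] + amp * trig * np.abs(r3 * xb - X[i])
            else:
                Xnew[i] = X[i] + rng.standard_normal() * np.ones(d)
        for i in range(n_prod, pop):
            if i > pop // 2:
                # worst-off scroungers fly elsewhere
                Xnew[i] = rng.standard_normal() * np.exp((xw - X[i]) / (i + 1) ** 2)
            else:
                step = _levy_step(rng, d, levy_beta)
                Xnew[i] = xb + 0.05 * step * np.abs(X[i] - xb) * (hi - lo != 0)
        for i in rng.choice(pop, size=n_scout, replace=False):
            if F[i] > fb:
                Xnew[i] = xb + rng.standard_normal(d) * np.abs(X[i] - xb)
            else:
                k = rng.uniform(-1.0, 1.0)
                Xnew[i] = X[i] + k * np.abs(X[i] - xw) / (abs(F[i] - fw) + 1e-50)

        Xnew = np.clip(Xnew, lo, hi)
        Fnew = np.array([float(objective(x)) for x in Xnew])
        if keep_archive:
            arch_x.append(Xnew.copy())
            arch_f.append(Fnew.copy())
        better = Fnew < F
        X[better] = Xnew[better]
        F[better] = Fnew[better]
        history.append(min(history[-1], float(F.min())))

    ib = int(np.argmin(F))
    return OptResult(
        best_x=X[ib].copy(),
        best_f=float(F[ib]),
        history=np.asarray(history),
        evaluated_x=np.concatenate(arch_x) if keep_archive else None,
        evaluated_f=np.concatenate(arch_f) if keep_archive else None,
    )
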