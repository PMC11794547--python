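"""Extended Fourier amplitude sensitivity test (eFAST).

Variance-based global sensitivity indices: each parameter in turn is
driven along a space-filling search curve at a high frequency while the
complementary parameters oscillate at low frequencies; the first-order
index Si is the fraction of output variance at the driver frequency and
its harmonics, and the total index STi is one minus the variance
carried by the complementary (low) frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SensitivityReport", "efast_indices", "classify_sensitive_params"]

#: number of driver harmonics summed into Si (interference factor)
INTERFERENCE = 4


@dataclass
class SensitivityReport:
    """First-order (Si) and total (STi) indices per parameter, with the
    high-sensitivity flag used for free/fixed partitioning."""

    indices: pd.DataFrame  # index: parameter, columns: Si, STi, sensitive
    threshold: float

    def sensitive_params(self) -> list[str]:
        return list(self.indices.index[self.indices["sensitive"]])


def _search_curve(s: np.ndarray, omega: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Map curve coordinate ``s`` to the unit hypercube; shape (Ns, p)."""
    return 0.5 + np.arcsin(np.sin(omega[None, :] * s[:, None] + phase[None, :])) / np.pi


def efast_indices(
    model,
    ranges: dict[str, tuple[float, float]],
    n_samples: int = 4096,
    seed: int | None = None,
    threshold: float = 0.1,
) -> SensitivityReport:
    """Compute eFAST Si/STi for ``model`` over box ``ranges``.

    ``model`` maps a dict of parameter values (or keyword-free positional
    array in the order of ``ranges``) to a scalar; it is called once per
    sample point.  ``n_samples`` is the total evaluation budget, split
    over one search curve per parameter (must allow >= 65 points per
    curve, the classic FAST sampling requirement).
    """
    names = list(ranges)
    p = len(names)
    if p < 2:
        raise ValueError("eFAST needs at least 2 free parameters")
    ns = int(n_samples) // p
    if ns < 65:
        raise ValueError(f"n_samples={n_samples} gives {ns} points per curve; need >= 65")
    if ns % 2 == 0:
        ns -= 1  # odd sample count keeps the Fourier grid symmetric
    rng = np.random.default_rng(seed)
    lo = np.array([ranges[k][0] for k in names])
    hi = np.array([ranges[k][1] for k in names])

    # driver frequency and distinct low complementary frequencies
    omega_max = max((ns - 1) // (2 * INTERFERENCE), INTERFERENCE + 1)
    omega_comp_max = max(omega_max // (2 * INTERFERENCE), 1)

    s = np.pi * (2.0 * np.arange(ns) + 1.0 - ns) / ns  # symmetric grid on (-pi, pi)
    si = np.empty(p)
    sti = np.empty(p)
    for i in range(p):
        omega = np.empty(p)
        omega[i] = omega_max
        comp = 1 + (np.arange(p - 1) % omega_comp_max)
        omega[[j for j in range(p) if j != i]] = comp
        phase = rng.uniform(0.0, 2.0 * np.pi, p)
        u = _search_curve(s, omega, phase)
        x = lo[None, :] + (hi - lo)[None, :] * u
        y = np.array([float(model(dict(zip(names, row)))) for row in x])
        var = y.var()
        if var < 1e-30:
            warnings.warn("constant model output; all sensitivity indices set to 0")
            si[:] = 0.0
            sti[:] = 0.0
            break
        # Fourier spectrum on the curve coordinate
        qmax = (ns - 1) // 2
        q = np.arange(1, qmax + 1)
        cosqs = np.cos(q[:, None] * s[None, :])
        sinqs = np.sin(q[:, None] * s[None, :])
        a = cosqs @ y / ns
        b = sinqs @ y / ns
        spectrum = 2.0 * (a**2 + b**2)
        vtot = spectrum.sum()
        harmonics = omega_max * np.arange(1, INTERFERENCE + 1)
        harmonics = harmonics[harmonics <= qmax]
        si[i] = spectrum[harmonics - 1].sum() / vtot
        v_comp = spectrum[: omega_max // 2].sum()
        sti[i] = 1.0 - v_comp / vtot

    df = pd.DataFrame({"Si": si, "STi": sti}, index=pd.Index(names, name="parameter"))
    df["sensitive"] = df[["Si", "STi"]].max(axis=1) > threshold
    return SensitivityReport(indices=df, threshold=threshold)


def classify_sensitive_params(
    reports: dict[str, SensitivityReport],
    threshold: float = 0.1,
    always_include: tuple[str, ...] = ("Cm",),
) -> tuple[list[str], list[str]]:
    """Partition parameters into (free, fixed) from region-wise reports.

    A parameter is free if its first-order or total index exceeds the
    threshold in ANY spectral region, or if it is in ``always_include``
    (dry matter is forced free because the retrieval target, leaf
    biomass, is proportional to it even when reflectance is only weakly
    sensitive).
    """
    all_params: list[str] = []
    free: set[str] = set(always_include)
    for rep in reports.values():
        idx = rep.indices
        for name in idx.index:
            if name not in all_params:
                all_params.append(name)
            if idx.loc[name, ["Si", "STi"]].max() > threshold:
                free.add(name)
    for extra in always_include:
        if extra not in all_params:
            all_params.append(extra)
    fixed = [n for n in all_params if n not in free]
    return [n for n in all_params if n in free], fixed
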