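"""Coupled leaf+canopy forward simulation and look-up-table generation.

The forward model chains the plate leaf model (:mod:`spu.rtm.prospect`)
with the four-stream canopy model (:mod:`spu.rtm.sail`) — the classic
leaf-biochemistry-to-canopy-reflectance pairing used for crop trait
retrieval.  The trait of interest for the phosphorus-uptake pipeline is
leaf dry biomass, obtained from canopy structure and leaf dry matter as

    leaf_biomass [t/ha] = 100 * LAI [m2/m2] * Cm [g/cm2]

(1 g/cm2 over 1 m2/m2 of leaf area is 10 kg/m2 = 100 t/ha).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from . import optical_synthetic as optics
from . import prospect, sail

WAVELENGTHS = optics.WAVELENGTHS

#: literature-typical parameter ranges for field maize; free parameters
#: carry (lo, hi) intervals, low-sensitivity parameters fixed scalars.
MAIZE_RANGES: dict[str, tuple[float, float] | float] = {
    "N_struct": 1.5,
    "Cab": (20.0, 70.0),
    "Car": (5.0, 18.0),
    "Cbrown": 0.1,
    "Cw": (0.008, 0.025),
    "Cm": (0.003, 0.010),
    "LAI": (0.5, 7.0),
    "ALA": (40.0, 70.0),
    "hs": (0.05, 0.5),
    "psoil": 0.7,
}

#: viewing/illumination geometry defaults (nadir view, mid-morning sun)
DEFAULT_GEOMETRY = {"sza": 30.0, "vza": 0.0, "raa": 0.0}

_BOUNDS = {
    "N_struct": (1.0, 3.0),
    "Cab": (0.0, 120.0),
    "Car": (0.0, 40.0),
    "Cbrown": (0.0, 2.0),
    "Cw": (0.0, 0.08),
    "Cm": (0.0, 0.03),
    "LAI": (0.0, 10.0),
    "ALA": (5.0, 85.0),
    "hs": (0.0, 1.0),
    "psoil": (0.0, 1.0),
    "sza": (0.0, 89.0),
    "vza": (0.0, 89.0),
    "raa": (0.0, 360.0),
}


@dataclass
class ProsailParams:
    """One leaf+canopy parameter vector.

    Units: Cab, Car ug/cm2; Cw cm (equivalent water thickness); Cm
    g/cm2; LAI m2/m2; ALA deg; angles deg; N_struct, Cbrown, hs, psoil
    unitless.
    """

    N_struct: float = 1.5
    Cab: float = 40.0
    Car: float = 9.0
    Cbrown: float = 0.1
    Cw: float = 0.015
    Cm: float = 0.007
    LAI: float = 3.0
    ALA: float = 57.0
    hs: float = 0.15
    psoil: float = 0.7
    sza: float = field(default=DEFAULT_GEOMETRY["sza"])
    vza: float = field(default=DEFAULT_GEOMETRY["vza"])
    raa: float = field(default=DEFAULT_GEOMETRY["raa"])

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            lo, hi = _BOUNDS[f.name]
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < lo or v > hi:
                raise ValueError(
                    f"parameter {f.name}={v!r} outside valid range [{lo}, {hi}]"
                )

    @property
    def leaf_biomass(self) -> float:
        """Leaf dry biomass, t/ha."""
        return 100.0 * self.LAI * self.Cm

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dc_fields(self)])

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in dc_fields(cls)]


def simulate_batch(params: pd.DataFrame, diffuse_fraction: float = 0.1) -> np.ndarray:
    """Canopy reflectance spectra for a table of parameter draws.

    ``params`` must contain the :class:`ProsailParams` columns (missing
    columns take the dataclass defaults).  Returns an
    ``(n, 2101)`` reflectance matrix on the 400-2500 nm grid.
    """
    defaults = ProsailParams()
    get = lambda c: (
        params[c].to_numpy(dtype=float)
        if c in params.columns
        else np.full(len(params), getattr(defaults, c))
    )
    refl_leaf, trans_leaf = prospect.leaf_rt(
        get("N_struct"), get("Cab"), get("Car"), get("Cbrown"), get("Cw"), get("Cm")
    )
    soil = optics.soil_reflectance(get("psoil"))
    lai, ala, hs = get("LAI"), get("ALA"), get("hs")
    sza, vza, raa = get("sza"), get("vza"), get("raa")
    out = np.empty_like(refl_leaf)
    for i in range(len(params)):
        out[i] = sail.canopy_reflectance(
            refl_leaf[i], trans_leaf[i], soil[i],
            lai[i], ala[i], hs[i], sza[i], vza[i], raa[i],
            diffuse_fraction=diffuse_fraction,
        )
    return out


def prosail_forward(p: ProsailParams, diffuse_fraction: float = 0.1) -> np.ndarray:
    """Canopy reflectance spectrum (2101 values, 400-2500 nm) for one
    parameter vector."""
    df = pd.DataFrame([{n: getattr(p, n) for n in ProsailParams.names()}])
    return simulate_batch(df, diffuse_fraction=diffuse_fraction)[0]


@dataclass
class SimulatedLUT:
    """A simulated (parameters, reflectance, response) pool.

    ``response`` is leaf biomass in t/ha, always ``100 * LAI * Cm`` of
    the stored parameter draws.
    """

    params: pd.DataFrame
    wavelengths: np.ndarray
    reflectance: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        if self.reflectance.shape != (len(self.params), len(self.wavelengths)):
            raise ValueError("reflectance shape inconsistent with params/wavelengths")
        expected = 100.0 * self.params["LAI"].to_numpy() * self.params["Cm"].to_numpy()
        if not np.allclose(self.response, expected, atol=1e-9):
            raise ValueError("response is not 100*LAI*Cm of the stored parameters")

    def __len__(self) -> int:
        return len(self.params)

    def subset(self, idx: np.ndarray) -> "SimulatedLUT":
        return SimulatedLUT(
            self.params.iloc[idx].reset_index(drop=True),
            self.wavelengths,
            self.reflectance[idx],
            self.response[idx],
        )


def draw_parameters(
    ranges: dict[str, tuple[float, float] | float],
    n: int,
    sampler: str = "lhs",
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` parameter vectors; interval entries are sampled
    (Latin hypercube or a full-factorial-ish grid), scalars held fixed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    free = {k: v for k, v in ranges.items() if isinstance(v, (tuple, list))}
    for k, v in free.items():
        if v[1] < v[0]:
            raise ValueError(f"empty interval for {k}: {v}")
    cols: dict[str, np.ndarray] = {}
    d = len(free)
    if d:
        if sampler == "lhs":
            from scipy.stats import qmc

            u = qmc.LatinHypercube(d=d, seed=seed).random(n)
        elif sampler == "grid":
            per = int(np.ceil(n ** (1.0 / d)))
            axes = np.meshgrid(*[np.linspace(0.0, 1.0, per)] * d, indexing="ij")
            u = np.stack([a.ravel() for a in axes], axis=1)[:n]
        else:
            raise ValueError(f"unknown sampler {sampler!r}")
        for j, (k, (lo, hi)) in enumerate(free.items()):
            cols[k] = lo + (hi - lo) * u[:, j]
    for k, v in ranges.items():
        if not isinstance(v, (tuple, list)):
            cols[k] = np.full(n, float(v))
    return pd.DataFrame(cols)


def generate_lut(
    ranges: dict[str, tuple[float, float] | float] | None = None,
    n: int = 59400,
    sampler: str = "lhs",
    seed: int | None = None,
    windows: list[tuple[float, float]] | None = None,
    chunk: int = 2000,
) -> SimulatedLUT:
    """Simulate a LUT of canopy reflectance and leaf-biomass response.

    ``windows`` restricts the stored spectral grid (default: the
    615-765 and 990-2500 nm modeling windows; pass an empty list to
    keep the full grid).
    """
    ranges = dict(MAIZE_RANGES if ranges is None else ranges)
    params = draw_parameters(ranges, n, sampler=sampler, seed=seed)
    if windows is None:
        windows = [(615.0, 765.0), (990.0, 2500.0)]
    if windows:
        keep = np.zeros(len(WAVELENGTHS), dtype=bool)
        for lo, hi in windows:
            keep |= (WAVELENGTHS >= lo) & (WAVELENGTHS <= hi)
    else:
        keep = np.ones(len(WAVELENGTHS), dtype=bool)
    refl = np.empty((n, int(keep.sum())))
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        refl[sl] = simulate_batch(params.iloc[sl])[:, keep]
    response = 100.0 * params["LAI"].to_numpy() * params["Cm"].to_numpy()
    return SimulatedLUT(params, WAVELENGTHS[keep].copy(), refl, response)
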