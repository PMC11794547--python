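"""Synthetic leaf optical constants and soil endmember spectra.

The plate-model leaf simulator in :mod:`spu.rtm.prospect` needs, per
wavelength, a leaf refractive index and specific absorption coefficient
spectra for chlorophyll a+b, total carotenoids, brown pigment, water and
dry matter.  The measured coefficient tables distributed with the
original leaf models are not redistributable here, so this module ships
*synthetic* stand-ins: smooth Gaussian-mixture curves whose peak
positions and magnitudes follow the well known absorption features of
green leaves (blue/red chlorophyll peaks, 1450/1940 nm water bands,
SWIR dry-matter features).  They produce realistic-looking maize canopy
spectra and preserve every qualitative contract the pipeline relies on
(pigments darken the visible, water darkens the SWIR, dry matter
darkens the far SWIR), but they are not the measured PROSPECT-5B
coefficients and absolute reflectances will differ from instruments.

All curves are defined on the canonical 1 nm grid 400-2500 nm.
"""

from __future__ import annotations

import numpy as np

#: canonical simulation grid, nm
WAVELENGTHS = np.arange(400.0, 2501.0, 1.0)


def _gauss(wl: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def refractive_index(wl: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Leaf mesophyll refractive index, smoothly declining 1.54 -> 1.42."""
    return 1.42 + 0.12 * np.exp(-(wl - 400.0) / 600.0)


def k_chlorophyll(wl: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Specific absorption of chlorophyll a+b, cm^2 ug^-1 (synthetic)."""
    k = (
        _gauss(wl, 430.0, 30.0, 0.032)
        + _gauss(wl, 470.0, 40.0, 0.012)
        + _gauss(wl, 600.0, 60.0, 0.006)
        + _gauss(wl, 670.0, 26.0, 0.026)
    )
    # no pigment absorption beyond the red edge
    k[wl > 780.0] = 0.0
    return k


def k_carotenoid(wl: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Specific absorption of total carotenoids, cm^2 ug^-1 (synthetic)."""
    k = _gauss(wl, 450.0, 22.0, 0.045) + _gauss(wl, 485.0, 22.0, 0.035)
    k[wl > 560.0] = 0.0
    return k


def k_brown(wl: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Absorption of brown (senescent) pigment per unit Cbrown (synthetic)."""
    return 0.9 * np.exp(-(wl - 400.0) / 220.0)


def k_water(wl: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Absorption coefficient of leaf water, cm^-1 (synthetic shapes,
    magnitudes on the order of liquid-water absorption)."""
    return (
        _gauss(wl, 970.0, 28.0, 0.55)
        + _gauss(wl, 1200.0, 45.0, 1.2)
        + _gauss(wl, 1450.0, 48.0, 26.0)
        + _gauss(wl, 1790.0, 60.0, 6.0)
        + _gauss(wl, 1940.0, 55.0, 110.0)
        + _gauss(wl, 2270.0, 90.0, 28.0)
        + _gauss(wl, 2600.0, 120.0, 60.0)
    )


def k_dry_matter(wl: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Specific absorption of dry matter, cm^2 g^-1 (synthetic)."""
    base = 4.0 + 10.0 * np.clip((wl - 800.0) / 1700.0, 0.0, None)
    return (
        base
        + _gauss(wl, 1730.0, 45.0, 22.0)
        + _gauss(wl, 2100.0, 60.0, 45.0)
        + _gauss(wl, 2300.0, 70.0, 40.0)
    )


def soil_reflectance(psoil: float | np.ndarray, wl: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Lambertian soil background spectrum.

    ``psoil`` mixes a dry (bright) and a wet (dark) endmember, the usual
    single-scalar soil parameterisation of SAIL-type canopy models:
    ``psoil=1`` is fully dry, ``psoil=0`` fully wet.
    """
    dry = 0.10 + 0.28 * (1.0 - np.exp(-(wl - 400.0) / 900.0))
    dry = dry * (1.0 - _gauss(wl, 1450.0, 60.0, 0.12) - _gauss(wl, 1940.0, 70.0, 0.22))
    wet = 0.45 * dry
    psoil = np.asarray(psoil, dtype=float)
    return psoil[..., None] * dry + (1.0 - psoil[..., None]) * wet if psoil.ndim else psoil * dry + (1.0 - psoil) * wet
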