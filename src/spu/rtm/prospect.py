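"""Generalized plate model of leaf directional-hemispherical reflectance
and transmittance (PROSPECT-style, N compact layers).

The leaf is modelled as ``N_struct`` absorbing plates separated by air
(Allen/Stokes system of plates), with an incidence solid angle of 40 deg
for the upper surface and isotropic light inside the leaf.  Absorption is
the sum of pigment, water and dry-matter contributions divided by the
structure parameter.  Optical constants come from
:mod:`spu.rtm.optical_synthetic`.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import exp1

from . import optical_synthetic as optics


def _fresnel_reflectance(theta_i: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unpolarised Fresnel reflectance at incidence ``theta_i`` (rad) for
    relative refractive index ``n`` (broadcast: theta along axis 0, n axis 1)."""
    ci = np.cos(theta_i)
    si = np.sin(theta_i)
    st = si / n
    ct = np.sqrt(np.clip(1.0 - st**2, 0.0, None))
    rs = (ci - n * ct) / (ci + n * ct)
    rp = (n * ci - ct) / (n * ci + ct)
    return 0.5 * (rs**2 + rp**2)


def tav(theta_deg: float, n: np.ndarray, n_quad: int = 128) -> np.ndarray:
    """Average transmissivity of a dielectric plane surface for light
    incident within a cone of half-angle ``theta_deg``.

    Computed by direct Gauss-Legendre quadrature of the Fresnel
    equations weighted by the projected solid angle
    (``sin(t) cos(t) dt``), which reproduces the closed-form averages
    used by plate leaf models to quadrature precision.
    """
    n = np.asarray(n, dtype=float)
    if theta_deg == 0:
        return 4.0 * n / (n + 1.0) ** 2
    shape = n.shape
    nf = n.reshape(-1)
    theta_max = np.radians(theta_deg)
    x, wq = _leggauss_cached(n_quad)
    t = 0.5 * theta_max * (x + 1.0)
    wq = 0.5 * theta_max * wq
    weight = np.sin(t) * np.cos(t)
    refl = _fresnel_reflectance(t[:, None], nf[None, :])
    num = np.sum((wq * weight)[:, None] * (1.0 - refl), axis=0)
    den = np.sum(wq * weight)
    return (num / den).reshape(shape)


@lru_cache(maxsize=4)
def _leggauss_cached(n_quad: int):
    return np.polynomial.legendre.leggauss(n_quad)


@lru_cache(maxsize=8)
def _tav_default_grid(theta_deg: float) -> np.ndarray:
    """tav over the canonical refractive-index spectrum (cached: the
    index array never changes within a session)."""
    return tav(theta_deg, optics.refractive_index())


def _layer_transmission(k: np.ndarray) -> np.ndarray:
    """Beam transmission of one elementary layer with absorption ``k``,
    integrated over the isotropic internal light field:
    ``(1-k) e^-k + k^2 E1(k)``."""
    out = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    out[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    return np.clip(out, 0.0, 1.0)


def leaf_rt(
    n_struct: np.ndarray,
    cab: np.ndarray,
    car: np.ndarray,
    cbrown: np.ndarray,
    cw: np.ndarray,
    cm: np.ndarray,
    wl: np.ndarray = optics.WAVELENGTHS,
) -> tuple[np.ndarray, np.ndarray]:
    """Leaf reflectance and transmittance spectra.

    Parameters are broadcastable arrays (typically shape ``(n_samples,)``);
    returns ``(refl, trans)`` of shape ``(n_samples, n_wl)``.
    """
    n_struct = np.atleast_1d(np.asarray(n_struct, dtype=float))[:, None]
    cab = np.atleast_1d(np.asarray(cab, dtype=float))[:, None]
    car = np.atleast_1d(np.asarray(car, dtype=float))[:, None]
    cbrown = np.atleast_1d(np.asarray(cbrown, dtype=float))[:, None]
    cw = np.atleast_1d(np.asarray(cw, dtype=float))[:, None]
    cm = np.atleast_1d(np.asarray(cm, dtype=float))[:, None]

    nr = optics.refractive_index(wl)[None, :]
    kall = (
        cab * optics.k_chlorophyll(wl)
        + car * optics.k_carotenoid(wl)
        + cbrown * optics.k_brown(wl)
        + cw * optics.k_water(wl)
        + cm * optics.k_dry_matter(wl)
    ) / n_struct
    trans = _layer_transmission(kall)

    # interface transmissivities: 40 deg cone on top, isotropic inside
    if wl is optics.WAVELENGTHS:
        talf = _tav_default_grid(40.0)[None, :]
        t12 = _tav_default_grid(90.0)[None, :]
    else:
        talf = tav(40.0, nr)
        t12 = tav(90.0, nr)
    ralf = 1.0 - talf
    r12 = 1.0 - t12
    t21 = t12 / nr**2
    r21 = 1.0 - t21

    # top (first) layer including the directional upper interface
    denom = 1.0 - r21**2 * trans**2
    Ta = talf * trans * t21 / denom
    Ra = ralf + r21 * trans * Ta
    # equivalent layer with isotropic illumination (interior layers)
    t = t12 * trans * t21 / denom
    r = r12 + r21 * trans * t

    # Stokes system of N-1 additional layers
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.sqrt(
            np.clip((1.0 + r + t) * (1.0 + r - t) * (1.0 - r + t) * (1.0 - r - t), 0.0, None)
        )
        rq = r**2
        tq = t**2
        a = (1.0 + rq - tq + D) / (2.0 * r)
        b = (1.0 - rq + tq + D) / (2.0 * t)
        bNm1 = b ** (n_struct - 1.0)
        bN2 = bNm1**2
        a2 = a**2
        denom2 = a2 * bN2 - 1.0
        Rsub = a * (bN2 - 1.0) / denom2
        Tsub = bNm1 * (a2 - 1.0) / denom2

    # conservative-scattering limit (r + t ~ 1): Stokes form degenerates
    sat = (r + t) >= 1.0
    Tsub_sat = t / (t + (1.0 - t) * (n_struct - 1.0))
    Tsub = np.where(sat, Tsub_sat, Tsub)
    Rsub = np.where(sat, 1.0 - Tsub_sat, Rsub)

    denom3 = 1.0 - Rsub * r
    tran = Ta * Tsub / denom3
    refl = Ra + Ta * Rsub * t / denom3
    return np.clip(refl, 0.0, 1.0), np.clip(tran, 0.0, 1.0)
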