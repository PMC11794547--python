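"""Reading, preprocessing and splitting of spectral + trait tables.

The in-memory container is :class:`SpectralDataset`: a sample-by-
wavelength reflectance matrix on a shared, strictly increasing grid,
with per-sample metadata (plot, growth stage, treatment) and an
optional trait table (leaf P concentration, organ biomass, organ P
uptake).  The on-disk format is a wide CSV: metadata columns first,
then one column per wavelength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

STAGES = ("jointing", "filling", "milk")

#: default spectral windows retained for hybrid (RTM-based) modeling;
#: the visible 400-615 nm and red-edge/NIR 765-990 nm regions are
#: excluded because simulated spectra reproduce them poorly.
MODELING_WINDOWS: list[tuple[float, float]] = [(615.0, 765.0), (990.0, 2500.0)]


class FormatError(ValueError):
    """Malformed spectral table (duplicate wavelengths, bad cells...)."""


@dataclass
class SpectralDataset:
    """Reflectance spectra plus aligned per-sample metadata/traits.

    ``is_derivative`` marks datasets that went through a derivative
    transform, whose values are no longer bounded by [0, 1].
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: pd.DataFrame
    traits: pd.DataFrame | None = None
    is_derivative: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1:
            raise FormatError("wavelengths must be 1-D")
        if len(np.unique(self.wavelengths)) != len(self.wavelengths):
            raise FormatError("duplicate wavelengths in grid")
        if np.any(np.diff(self.wavelengths) <= 0):
            order = np.argsort(self.wavelengths)
            self.wavelengths = self.wavelengths[order]
            self.reflectance = self.reflectance[:, order]
        if self.reflectance.ndim != 2 or self.reflectance.shape[1] != len(self.wavelengths):
            raise FormatError("reflectance must be (n_samples, n_wavelengths)")
        if len(self.meta) != len(self.reflectance):
            raise FormatError("meta row count must equal reflectance row count")
        if not self.is_derivative:
            if np.nanmin(self.reflectance) < -1e-9 or np.nanmax(self.reflectance) > 1 + 1e-9:
                raise FormatError("non-derivative reflectance must lie in [0, 1]")
        if self.traits is not None and len(self.traits) != len(self.meta):
            raise FormatError("traits row count must equal sample count")

    def __len__(self) -> int:
        return len(self.reflectance)

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)

    def trait(self, name: str) -> np.ndarray:
        if self.traits is None or name not in self.traits.columns:
            raise KeyError(f"trait {name!r} not present")
        return self.traits[name].to_numpy(dtype=float)

    def subset(self, idx) -> "SpectralDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            reflectance=self.reflectance[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            traits=None if self.traits is None else self.traits.iloc[idx].reset_index(drop=True),
        )


def normalize_windows(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Validate and merge overlapping [lo, hi] wavelength windows."""
    for lo, hi in windows:
        if hi < lo:
            raise ValueError(f"window [{lo}, {hi}] has hi < lo")
    merged: list[list[float]] = []
    for lo, hi in sorted(map(tuple, windows)):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(w) for w in merged]


def load_spectral_table(
    path,
    meta_columns: list[str] | None = None,
    traits_columns: list[str] | None = None,
    resample_off_grid: bool = True,
) -> SpectralDataset:
    """Load a wide CSV (meta columns, then wavelength columns).

    Columns whose names parse as numbers are wavelengths; the rest are
    metadata unless listed in ``traits_columns``.  Off-grid (non
    integer) wavelength inputs are linearly resampled to the canonical
    1 nm grid when ``resample_off_grid`` is set.
    """
    df = pd.read_csv(path)
    wl_cols, meta_cols = [], []
    for c in df.columns:
        try:
            float(c)
            wl_cols.append(c)
        except ValueError:
            meta_cols.append(c)
    if meta_columns is not None:
        missing = set(meta_columns) - set(meta_cols)
        if missing:
            raise FormatError(f"requested meta columns missing: {sorted(missing)}")
        extra = [c for c in meta_cols if c not in meta_columns]
        meta_cols = list(meta_columns)
    else:
        extra = [c for c in meta_cols if pd.api.types.is_numeric_dtype(df[c])]
        meta_cols = [c for c in meta_cols if c not in extra]
    if traits_columns is None:
        traits_columns = [c for c in extra if pd.api.types.is_numeric_dtype(df[c])]
    traits_columns = traits_columns or []

    wl = np.array([float(c) for c in wl_cols])
    if len(np.unique(wl)) != len(wl):
        raise FormatError("duplicate wavelength columns")
    numeric = df[wl_cols].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(f"non-numeric reflectance at row {r}, wavelength {wl_cols[c]}")
    refl = numeric.to_numpy(dtype=float)
    order = np.argsort(wl)
    wl, refl = wl[order], refl[:, order]

    if resample_off_grid and not np.allclose(wl, np.round(wl)):
        grid = np.arange(np.ceil(wl[0]), np.floor(wl[-1]) + 1.0)
        refl = np.vstack([np.interp(grid, wl, row) for row in refl])
        wl = grid

    meta = df[meta_cols].copy()
    traits = df[traits_columns].copy() if traits_columns else None
    return SpectralDataset(wavelengths=wl, reflectance=refl, meta=meta, traits=traits)


def write_spectral_table(ds: SpectralDataset, path) -> None:
    """Write the wide-CSV counterpart of :func:`load_spectral_table`
    (values round-trip to < 1e-12)."""
    wide = pd.concat(
        [
            ds.meta.reset_index(drop=True),
            *([] if ds.traits is None else [ds.traits.reset_index(drop=True)]),
            pd.DataFrame(ds.reflectance, columns=[f"{w:g}" for w in ds.wavelengths]),
        ],
        axis=1,
    )
    wide.to_csv(path, index=False, float_format="%.17g")


def first_derivative(
    ds: SpectralDataset,
    method: str = "savgol",
    window: int = 15,
    poly: int = 2,
) -> SpectralDataset:
    """First derivative of each spectrum with respect to wavelength.

    ``savgol`` (default window 15, poly 2) smooths while
    differentiating — the usual choice for noisy field spectra;
    ``finite_diff`` uses central differences with one-sided ends.
    """
    step = np.diff(ds.wavelengths)
    if not np.allclose(step, step[0]):
        raise ValueError("first_derivative requires a uniform wavelength grid")
    h = float(step[0])
    if method == "finite_diff":
        deriv = np.gradient(ds.reflectance, h, axis=1)
    elif method == "savgol":
        if window % 2 == 0 or window <= poly:
            raise ValueError("savgol window must be odd and > poly")
        if ds.n_bands < window:
            raise ValueError(f"need >= {window} bands for savgol window {window}")
        deriv = savgol_filter(ds.reflectance, window, poly, deriv=1, delta=h, axis=1)
    else:
        raise ValueError(f"unknown derivative method {method!r}")
    return replace(ds, reflectance=deriv, is_derivative=True)


def mask_windows(ds: SpectralDataset, keep: list[tuple[float, float]]) -> SpectralDataset:
    """Retain only wavelengths inside any of the ``keep`` windows."""
    windows = normalize_windows(keep)
    sel = np.zeros(ds.n_bands, dtype=bool)
    for lo, hi in windows:
        sel |= (ds.wavelengths >= lo) & (ds.wavelengths <= hi)
    if not sel.any():
        raise ValueError(f"no wavelengths fall inside windows {windows}")
    return replace(ds, wavelengths=ds.wavelengths[sel], reflectance=ds.reflectance[:, sel])


def split_train_test(
    ds: SpectralDataset,
    ratio: float = 0.7,
    stratify_by: str | None = None,
    seed: int | None = None,
) -> tuple[SpectralDataset, SpectralDataset]:
    """Disjoint, exhaustive train/test split.

    Train size is ``floor(ratio * n + 0.5)``; with ``stratify_by`` the
    split preserves group proportions (largest-remainder rounding to
    hit the global train size exactly).  Strata with fewer than 2
    samples stay whole in the training set, with a warning.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = len(ds)
    n_train = int(np.floor(ratio * n + 0.5))
    rng = np.random.default_rng(seed)

    if stratify_by is None:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    else:
        groups = ds.meta[stratify_by].to_numpy()
        train_parts: list[np.ndarray] = []
        quota: list[tuple[float, np.ndarray]] = []
        forced = 0
        for g in pd.unique(groups):
            idx = np.flatnonzero(groups == g)
            if len(idx) < 2:
                warnings.warn(f"stratum {g!r} has < 2 samples; kept whole in train")
                train_parts.append(idx)
                forced += len(idx)
            else:
                quota.append((ratio * len(idx), rng.permutation(idx)))
        remaining = max(n_train - forced, 0)
        base = [int(np.floor(q)) for q, _ in quota]
        rema = [q - b for (q, _), b in zip(quota, base)]
        short = remaining - sum(base)
        for j in np.argsort(rema)[::-1][: max(short, 0)]:
            base[j] += 1
        for (q, idx), k in zip(quota, base):
            k = min(k, len(idx) - 1)  # leave at least one test sample per stratum
            train_parts.append(idx[:k])
        train_idx = np.sort(np.concatenate(train_parts)) if train_parts else np.array([], int)
        test_idx = np.setdiff1d(np.arange(n), train_idx)
    return ds.subset(train_idx), ds.subset(test_idx)
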