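"""Generalized two-dimensional correlation spectroscopy (2DCOS),
two-trace 2DCOS (2T2DCOS), autopeak extraction and the band-selection
protocols built on them.

In generalized 2DCOS a set of spectra ordered by a perturbation
variable (here: a plant trait such as leaf P concentration, ascending)
is decomposed into a synchronous map

    Phi(v1, v2) = (1/(m-1)) * sum_j ytilde_j(v1) * ytilde_j(v2)

and an asynchronous map obtained through the Hilbert-Noda transform

    Psi(v1, v2) = (1/(m-1)) * sum_j ytilde_j(v1) * sum_k N_jk ytilde_k(v2),
    N_jk = 0 if j == k else 1 / (pi * (k - j)),

where ``ytilde`` are the mean-centered dynamic spectra.  Autopeaks —
maxima of the synchronous diagonal — mark wavelengths most responsive
to the perturbation and are the sensitive bands used downstream.

Two-trace 2DCOS correlates exactly two spectra a and b (here the
filling- and milk-stage spectra of one plot):

    Phi = (a a^T + b b^T)/2,   Psi = (a b^T - b a^T)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import SpectralDataset, first_derivative

__all__ = [
    "CorrelationMaps",
    "BandSet",
    "synchronous_map",
    "asynchronous_map",
    "hilbert_noda_matrix",
    "two_trace_maps",
    "autopeak_bands",
    "select_bands_1der2dcos",
    "select_bands_2t2dcos",
    "repeated_selection_stability",
]


@dataclass
class CorrelationMaps:
    """Synchronous/asynchronous correlation maps on a wavelength grid."""

    wavelengths: np.ndarray
    sync: np.ndarray
    async_: np.ndarray
    kind: str = "perturbation_2dcos"  # or "two_trace"

    def __post_init__(self) -> None:
        b = len(self.wavelengths)
        if self.sync.shape != (b, b) or self.async_.shape != (b, b):
            raise ValueError("maps must be square on the wavelength grid")
        if not np.allclose(self.sync, self.sync.T, atol=1e-10):
            raise ValueError("synchronous map must be symmetric")
        if not np.allclose(self.async_, -self.async_.T, atol=1e-10):
            raise ValueError("asynchronous map must be antisymmetric")


@dataclass
class BandSet:
    """Selected sensitive wavelengths with provenance and per-band support."""

    wavelengths: np.ndarray
    provenance: dict = field(default_factory=dict)
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.support is None:
            self.support = np.ones(len(self.wavelengths), dtype=int)
        self.support = np.asarray(self.support, dtype=int)
        if np.any(self.support < 1):
            raise ValueError("band support must be >= 1")

    def __len__(self) -> int:
        return len(self.wavelengths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "support": self.support,
             "provenance": [str(self.provenance)] * len(self)}
        )


def _dynamic(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 ordered spectra")
    return x - x.mean(axis=0, keepdims=True)


def synchronous_map(ordered_spectra: np.ndarray) -> np.ndarray:
    """Synchronous 2D correlation map of trait-ordered spectra."""
    y = _dynamic(ordered_spectra)
    return y.T @ y / (y.shape[0] - 1)


def hilbert_noda_matrix(m: int) -> np.ndarray:
    """The Hilbert-Noda transform matrix N_jk = 1/(pi (k-j)), zero diagonal."""
    j = np.arange(m)
    diff = j[None, :] - j[:, None]
    with np.errstate(divide="ignore"):
        n = 1.0 / (np.pi * diff)
    np.fill_diagonal(n, 0.0)
    return n


def asynchronous_map(ordered_spectra: np.ndarray) -> np.ndarray:
    """Asynchronous 2D correlation map via the Hilbert-Noda transform."""
    y = _dynamic(ordered_spectra)
    n = hilbert_noda_matrix(y.shape[0])
    return y.T @ (n @ y) / (y.shape[0] - 1)


def two_trace_maps(
    trace_a: np.ndarray, trace_b: np.ndarray, wavelengths: np.ndarray | None = None
) -> CorrelationMaps:
    """Two-trace 2DCOS of a pair of spectra on a shared grid."""
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-D spectra on identical grids")
    if wavelengths is None:
        wavelengths = np.arange(len(a), dtype=float)
    sync = 0.5 * (np.outer(a, a) + np.outer(b, b))
    async_ = 0.5 * (np.outer(a, b) - np.outer(b, a))
    return CorrelationMaps(np.asarray(wavelengths, float), sync, async_, kind="two_trace")


def perturbation_maps(ds: SpectralDataset, trait: str) -> CorrelationMaps:
    """Order samples by ascending trait (ties by sample_id) and build
    both correlation maps."""
    order = _trait_order(ds, trait)
    x = ds.reflectance[order]
    return CorrelationMaps(
        ds.wavelengths, synchronous_map(x), asynchronous_map(x), kind="perturbation_2dcos"
    )


def _trait_order(ds: SpectralDataset, trait: str) -> np.ndarray:
    t = ds.trait(trait)
    if np.ptp(t) == 0:
        raise ValueError(f"trait {trait!r} is constant; perturbation ordering undefined")
    tie = (
        ds.meta["sample_id"].astype(str).to_numpy()
        if "sample_id" in ds.meta.columns
        else np.arange(len(ds)).astype(str)
    )
    return np.lexsort((tie, t))


def autopeak_bands(
    maps: CorrelationMaps,
    rel_threshold: float = 0.1,
    min_separation_nm: float = 10.0,
) -> BandSet:
    """Extract autopeaks: local maxima of the synchronous diagonal above
    ``rel_threshold * max``, with non-maximum suppression inside
    ``min_separation_nm`` (ties keep the lower wavelength)."""
    if not 0.0 < rel_threshold <= 1.0:
        raise ValueError("rel_threshold must be in (0, 1]")
    d = np.diag(maps.sync).copy()
    if np.all(d <= 0.0):
        return BandSet(np.empty(0), provenance={"method": "autopeak", "note": "zero diagonal"})
    # strictly interior local maxima (plateau keeps leftmost point);
    # grid endpoints are excluded: one-sided derivative windows inflate
    # edge variance and produce spurious boundary autopeaks
    is_max = np.zeros_like(d, dtype=bool)
    if len(d) > 2:
        is_max[1:-1] = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
    cand = np.flatnonzero(is_max & (d >= rel_threshold * d.max()))
    # suppress by value desc then wavelength asc
    order = cand[np.lexsort((maps.wavelengths[cand], -d[cand]))]
    kept: list[int] = []
    for i in order:
        if all(abs(maps.wavelengths[i] - maps.wavelengths[j]) >= min_separation_nm for j in kept):
            kept.append(i)
    kept.sort()
    return BandSet(
        maps.wavelengths[kept],
        provenance={
            "method": "autopeak",
            "rel_threshold": rel_threshold,
            "min_separation_nm": min_separation_nm,
        },
    )


def select_bands_1der2dcos(
    ds: SpectralDataset,
    trait: str,
    rel_threshold: float = 0.1,
    min_separation_nm: float = 10.0,
    deriv_window: int = 15,
    deriv_poly: int = 2,
) -> BandSet:
    """Derivative-enhanced 2DCOS band selection: first derivative ->
    trait-ordered synchronous map -> autopeaks."""
    der = ds if ds.is_derivative else first_derivative(ds, window=deriv_window, poly=deriv_poly)
    maps = perturbation_maps(der, trait)
    bands = autopeak_bands(maps, rel_threshold, min_separation_nm)
    bands.provenance.update({"method": "1Der-2DCOS", "trait": trait})
    return bands


def select_bands_2t2dcos(
    ds_stage_a: SpectralDataset,
    ds_stage_b: SpectralDataset,
    majority_fraction: float = 0.5,
    rel_threshold: float = 0.1,
    min_separation_nm: float = 10.0,
) -> BandSet:
    """Two-trace consensus band selection across a pair of growth stages.

    For each plot paired by ``sample_id``, two-trace maps are built from
    the derivative spectra of the two stages and autopeaks extracted;
    bands supported by strictly more than ``majority_fraction`` of the
    pairs are retained.
    """
    if not np.array_equal(ds_stage_a.wavelengths, ds_stage_b.wavelengths):
        raise ValueError("stage datasets must share a wavelength grid")
    ida = ds_stage_a.meta["sample_id"].astype(str)
    idb = ds_stage_b.meta["sample_id"].astype(str)
    unpaired = sorted(set(ida) ^ set(idb))
    if unpaired:
        raise ValueError(f"unpaired sample_ids between stages: {unpaired}")
    da = ds_stage_a if ds_stage_a.is_derivative else first_derivative(ds_stage_a)
    db = ds_stage_b if ds_stage_b.is_derivative else first_derivative(ds_stage_b)
    pos_b = {s: i for i, s in enumerate(idb)}

    counts: dict[float, int] = {}
    n_pairs = len(ida)
    for i, sid in enumerate(ida):
        maps = two_trace_maps(da.reflectance[i], db.reflectance[pos_b[sid]], da.wavelengths)
        for w in autopeak_bands(maps, rel_threshold, min_separation_nm).wavelengths:
            counts[w] = counts.get(w, 0) + 1
    cut = majority_fraction * n_pairs
    kept = sorted(w for w, c in counts.items() if c > cut)
    return BandSet(
        np.array(kept),
        provenance={
            "method": "2T2DCOS",
            "majority_fraction": majority_fraction,
            "n_pairs": n_pairs,
        },
        support=np.array([counts[w] for w in kept], dtype=int) if kept else None,
    )


@dataclass
class StabilityResult:
    """Per-fraction band-selection counts and the stable band sets."""

    counts: dict[float, pd.Series]  # fraction -> per-wavelength selection count
    stable: dict[float, BandSet]
    n_draws: int
    min_count: int


def repeated_selection_stability(
    ds: SpectralDataset,
    trait: str,
    fractions: list[float] = (0.3, 0.6, 1.0),
    n_draws: int = 10,
    min_count: int = 8,
    seed: int | None = None,
    rel_threshold: float = 0.1,
    min_separation_nm: float = 10.0,
) -> StabilityResult:
    """Repeatedly select bands on trait-stratified subsamples and keep
    bands chosen in at least ``min_count`` of ``n_draws`` draws.

    Subsamples preserve the trait distribution (quartile-bin stratified
    draws); fractions whose subset would have fewer than 10 samples are
    skipped with a warning.
    """
    if n_draws < min_count:
        raise ValueError("n_draws must be >= min_count")
    rng = np.random.default_rng(seed)
    t = ds.trait(trait)
    bins = np.searchsorted(np.quantile(t, [0.25, 0.5, 0.75]), t, side="left")
    counts: dict[float, pd.Series] = {}
    stable: dict[float, BandSet] = {}
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"fraction {frac} outside (0, 1]")
        size = int(round(frac * len(ds)))
        if size < 10:
            warnings.warn(f"fraction {frac} gives {size} < 10 samples; skipped")
            continue
        tally: dict[float, int] = {}
        for _ in range(n_draws):
            if frac >= 1.0:
                idx = np.arange(len(ds))
            else:
                parts = []
                for b in np.unique(bins):
                    members = np.flatnonzero(bins == b)
                    k = max(1, int(round(frac * len(members))))
                    parts.append(rng.choice(members, size=min(k, len(members)), replace=False))
                idx = np.sort(np.concatenate(parts))
            bands = select_bands_1der2dcos(
                ds.subset(idx), trait, rel_threshold, min_separation_nm
            )
            for w in bands.wavelengths:
                tally[w] = tally.get(w, 0) + 1
        ser = pd.Series(tally, dtype=int).sort_index()
        counts[frac] = ser
        kept = ser.index[ser >= min_count].to_numpy(dtype=float)
        stable[frac] = BandSet(
            kept,
            provenance={"method": "1Der-2DCOS-stability", "fraction": frac,
                        "n_draws": n_draws, "min_count": min_count},
            support=ser[ser >= min_count].to_numpy(dtype=int) if len(kept) else None,
        )
    return StabilityResult(counts=counts, stable=stable, n_draws=n_draws, min_count=min_count)
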