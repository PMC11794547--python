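"""Organ-wise shoot-phosphorus-uptake (SPU) models.

SPU is composed organ by organ: leaf P uptake from an empirically
predicted canopy leaf P concentration (LPC, g/kg) times a hybrid
(RTM + active learning) leaf-biomass retrieval (t/ha); stem P uptake
through a polynomial link from leaf P uptake; grain P uptake from an
empirical grain-biomass model times the mature-leaf P concentration
(which substitutes for the grain P concentration).  A direct
whole-plant spectral model serves as the empirical baseline.

Unit identity used throughout: g/kg x t/ha = kg/ha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .active_learning import (
    ALConfig,
    ALState,
    al_augment_loop,
    candidate_pool_from_nrbo,
    pick_representative_subset,
)
from .regression import FittedRegressor, fit_regressor, rf_importance_topk
from .rtm import forward as rtm_forward
from .spectra_io import MODELING_WINDOWS, SpectralDataset, first_derivative, mask_windows
from .twodcos import BandSet, select_bands_1der2dcos

__all__ = [
    "OrganUptake",
    "StemLink",
    "uptake_from_conc_biomass",
    "fit_stem_link",
    "BandRegressor",
    "fit_band_regressor",
    "predict_canopy_lpc",
    "predict_leaf_biomass_hybrid",
    "predict_grain_uptake",
    "CombinedSpuModel",
    "predict_spu_whole_plant",
]


@dataclass
class OrganUptake:
    """Per-plot organ P uptakes (kg/ha); SPU is always their sum."""

    table: pd.DataFrame  # columns: plot_id, leaf_P, stem_P, grain_P, SPU

    def __post_init__(self) -> None:
        t = self.table
        needed = {"plot_id", "leaf_P", "stem_P", "grain_P", "SPU"}
        if not needed <= set(t.columns):
            raise ValueError(f"missing columns: {sorted(needed - set(t.columns))}")
        organs = t[["leaf_P", "stem_P", "grain_P"]].to_numpy()
        if np.any(organs < -1e-12):
            raise ValueError("organ uptakes must be non-negative")
        if not np.allclose(t["SPU"], organs.sum(axis=1), atol=1e-9):
            raise ValueError("SPU must equal leaf_P + stem_P + grain_P")


def uptake_from_conc_biomass(conc, biomass) -> np.ndarray:
    """P uptake (kg/ha) from concentration (g/kg) and biomass (t/ha)."""
    conc = np.asarray(conc, dtype=float)
    biomass = np.asarray(biomass, dtype=float)
    if np.any(conc < 0) or np.any(biomass < 0):
        raise ValueError("concentration and biomass must be non-negative")
    return conc * biomass


@dataclass
class StemLink:
    """Polynomial map from leaf P uptake to stem P uptake (kg/ha)."""

    degree: int
    coefficients: np.ndarray  # numpy polyval order (highest first)
    train_rmse: float

    def predict(self, leaf_p: np.ndarray) -> np.ndarray:
        out = np.polyval(self.coefficients, np.asarray(leaf_p, dtype=float))
        if np.any(out < 0):
            warnings.warn("negative stem P predictions clipped to 0")
        return np.clip(out, 0.0, None)


def fit_stem_link(leaf_p_obs, stem_p_obs, degree: int = 2) -> StemLink:
    """Least-squares polynomial between measured leaf and stem P uptake."""
    x = np.asarray(leaf_p_obs, dtype=float)
    y = np.asarray(stem_p_obs, dtype=float)
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if len(x) < degree + 2:
        raise ValueError(f"need >= {degree + 2} points for degree {degree}")
    while degree > 1:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            coef = np.polyfit(x, y, degree)
        if not any(issubclass(w.category, np.exceptions.RankWarning) for w in caught):
            break
        warnings.warn(f"rank-deficient fit at degree {degree}; trying {degree - 1}")
        degree -= 1
    else:
        coef = np.polyfit(x, y, degree)
    rmse = float(np.sqrt(np.mean((np.polyval(coef, x) - y) ** 2)))
    return StemLink(degree=degree, coefficients=coef, train_rmse=rmse)


@dataclass
class BandRegressor:
    """A regressor over derivative-spectrum features at selected bands."""

    bands: BandSet
    model: FittedRegressor
    clip_nonnegative: bool = True

    def _features(self, ds: SpectralDataset) -> np.ndarray:
        der = ds if ds.is_derivative else first_derivative(ds)
        idx = []
        for w in self.bands.wavelengths:
            hit = np.flatnonzero(np.isclose(der.wavelengths, w))
            if not len(hit):
                raise KeyError(f"band {w} nm missing from dataset grid")
            idx.append(hit[0])
        return der.reflectance[:, idx]

    def predict(self, ds: SpectralDataset) -> np.ndarray:
        pred = self.model.predict(self._features(ds))
        if self.clip_nonnegative and np.any(pred < 0):
            warnings.warn("negative predictions clipped to 0")
            pred = np.clip(pred, 0.0, None)
        return pred


def fit_band_regressor(
    train_ds: SpectralDataset,
    trait: str,
    bands: BandSet | None = None,
    kind: str = "GBRT",
    hyperparams: dict | None = None,
    seed: int | None = None,
) -> BandRegressor:
    """Select sensitive bands (derivative-enhanced 2DCOS, unless given)
    and fit a regressor on the derivative features at those bands."""
    if bands is None:
        bands = select_bands_1der2dcos(train_ds, trait)
    reg = BandRegressor(bands=bands, model=None)  # type: ignore[arg-type]
    x = reg._features(train_ds)
    reg.model = fit_regressor(kind, x, train_ds.trait(trait), hyperparams, seed=seed)
    return reg


def predict_canopy_lpc(
    ds: SpectralDataset,
    train_ds: SpectralDataset,
    bands: BandSet | None = None,
    kind: str = "GBRT",
    seed: int | None = None,
) -> tuple[np.ndarray, BandRegressor]:
    """Canopy leaf P concentration (g/kg) for the samples of ``ds``,
    from a model trained on ``train_ds`` (which carries the LPC trait).
    Predictions are clipped at zero."""
    reg = fit_band_regressor(train_ds, "LPC", bands=bands, kind=kind, seed=seed)
    return reg.predict(ds), reg


@dataclass
class HybridBiomassModel:
    """ELM retrieval trained on the active-learning-filtered pool.

    Features are the ``band_idx`` subset of the masked grid (the most
    important bands of a random forest fitted to the training pool),
    which keeps the small-sample ELM well conditioned."""

    wavelengths: np.ndarray
    band_idx: np.ndarray
    elm: FittedRegressor
    state: ALState

    def predict(self, ds: SpectralDataset) -> np.ndarray:
        ds_m = mask_windows(ds, [(w[0], w[1]) for w in _windows_of(self.wavelengths)])
        if not np.array_equal(ds_m.wavelengths, self.wavelengths):
            raise ValueError("dataset grid does not match the model grid")
        return np.clip(self.elm.predict(ds_m.reflectance[:, self.band_idx]), 0.0, None)


def _windows_of(wl: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous [lo, hi] runs of a (possibly gappy) 1 nm grid."""
    wl = np.asarray(wl)
    breaks = np.flatnonzero(np.diff(wl) > 1.5)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(wl) - 1]])
    return [(float(wl[s]), float(wl[e])) for s, e in zip(starts, ends)]


def predict_leaf_biomass_hybrid(
    ds: SpectralDataset,
    lut: rtm_forward.SimulatedLUT,
    al_cfg: ALConfig,
    measured_x: np.ndarray,
    measured_y: np.ndarray,
    elm_hyperparams: dict | None = None,
    seed: int | None = None,
    n_bands: int = 30,
    train_noise: tuple[float, float] | None = (0.01, 0.002),
) -> tuple[np.ndarray, HybridBiomassModel]:
    """Leaf biomass (t/ha) for ``ds`` via the hybrid pipeline.

    ``lut`` is the simulated candidate pool on the masked grid;
    ``measured_x``/``measured_y`` are the masked spectra and measured
    leaf biomass of the field training plots.  Pipeline: representative
    subset -> spectral filter -> response filter -> greedy augmentation
    -> ELM on the selected simulated + measured samples.
    """
    measured_x = np.asarray(measured_x, dtype=float)
    measured_y = np.asarray(measured_y, dtype=float)
    k = min(al_cfg.K_representative, len(measured_x) - 1)
    rep = pick_representative_subset(measured_x, k, method="kennard_stone")
    state = ALState(
        measured_x=measured_x, measured_y=measured_y, rep_idx=rep, candidates=lut
    )
    state = al_augment_loop(state, al_cfg)
    train_x, train_y = state.training_x, state.training_y
    if len(train_x) == 0:
        raise RuntimeError(
            "empty post-filter training set; increase epsilon_spectral / "
            "epsilon_response or provide measured samples"
        )
    if len(state.selected_candidates) == 0:
        warnings.warn(
            "no simulated candidates survived the distance filters; "
            "training on measured samples only (consider larger epsilons)"
        )
    if train_noise is not None:
        # sensor-noise augmentation of the (noise-free) simulated rows so
        # their feature distribution matches field spectra
        mult_sd, add_sd = train_noise
        rng = np.random.default_rng(seed)
        n_sim = len(state.selected_candidates)
        sim = train_x[:n_sim]
        sim = sim * (1.0 + rng.normal(0.0, mult_sd, sim.shape))
        sim = np.clip(sim + rng.normal(0.0, add_sd, sim.shape), 0.0, 1.0)
        train_x = np.vstack([sim, train_x[n_sim:]])
    # band reduction: most important bands of a forest over the pool
    rf = fit_regressor("RF", train_x, train_y,
                       {"n_estimators": 200, "max_features": "sqrt"}, seed=seed)
    band_idx = np.sort(rf_importance_topk(rf, n_bands))
    hp = {"n_hidden": 40, "ridge": 1e-3}
    hp.update(elm_hyperparams or {})
    elm = fit_regressor("ELM", train_x[:, band_idx], train_y, hp, seed=seed)
    model = HybridBiomassModel(
        wavelengths=lut.wavelengths, band_idx=band_idx, elm=elm, state=state
    )
    return model.predict(ds), model


def predict_grain_uptake(
    ds_milk: SpectralDataset,
    mature_leaf_p: np.ndarray,
    train_ds_milk: SpectralDataset,
    bands: BandSet | None = None,
    kind: str = "GBRT",
    seed: int | None = None,
) -> tuple[np.ndarray, BandRegressor]:
    """Grain P uptake (kg/ha): milk-stage grain-biomass model times the
    mature-leaf P concentration (substituting for grain concentration)."""
    mature_leaf_p = np.asarray(mature_leaf_p, dtype=float)
    if len(mature_leaf_p) != len(ds_milk):
        raise ValueError("need one mature-leaf P concentration per sample")
    reg = fit_band_regressor(train_ds_milk, "grain_biomass", bands=bands, kind=kind, seed=seed)
    grain_bio = reg.predict(ds_milk)
    return uptake_from_conc_biomass(mature_leaf_p, grain_bio), reg


@dataclass
class CombinedSpuModel:
    """The organ-wise combination model.

    fit() trains the LPC model (jointing+filling samples), the hybrid
    leaf-biomass model (filling stage), the stem polynomial link and
    the grain-biomass model (milk stage) on the training plots;
    predict() composes them into per-plot organ uptakes.  The grain
    concentration uses the predicted LPC by default
    (``grain_conc_source='predicted'``) or the measured mature-leaf
    concentration (``'measured'``).
    """

    al_cfg: ALConfig = field(default_factory=ALConfig)
    lpc_kind: str = "GBRT"
    grain_kind: str = "GBRT"
    stem_degree: int = 2
    grain_conc_source: str = "predicted"
    windows: list[tuple[float, float]] = field(default_factory=lambda: list(MODELING_WINDOWS))
    pool_size: int = 2400
    use_nrbo_pool: bool = True
    seed: int | None = None

    def fit(
        self,
        datasets: dict[str, SpectralDataset],
        train_idx: np.ndarray,
        lut: rtm_forward.SimulatedLUT | None = None,
    ) -> "CombinedSpuModel":
        train_idx = np.asarray(train_idx, dtype=int)
        fill, milk = datasets["filling"], datasets["milk"]
        joint = datasets.get("jointing")

        # LPC: one model per stage (canopy structure differs too much
        # between jointing and filling to pool them at this sample size)
        self.lpc_model_ = fit_band_regressor(
            fill.subset(train_idx), "LPC", kind=self.lpc_kind, seed=self.seed
        )
        self.lpc_model_jointing_ = (
            fit_band_regressor(joint.subset(train_idx), "LPC", kind=self.lpc_kind, seed=self.seed)
            if joint is not None
            else None
        )

        # hybrid leaf biomass on the masked filling-stage grid
        fill_masked = mask_windows(fill, self.windows)
        measured_x = fill_masked.reflectance[train_idx]
        measured_y = fill.trait("leaf_biomass")[train_idx]
        if lut is None:
            if self.use_nrbo_pool:
                k = min(self.al_cfg.K_representative, len(measured_x) - 1)
                rep = pick_representative_subset(measured_x, k, method="kennard_stone")
                lut = candidate_pool_from_nrbo(
                    measured_x[rep], fill_masked.wavelengths,
                    pool_target=self.pool_size, seed=self.seed,
                )
            else:
                lut = rtm_forward.generate_lut(
                    n=self.pool_size, seed=self.seed, windows=self.windows
                )
        _, self.biomass_model_ = predict_leaf_biomass_hybrid(
            fill.subset(train_idx), lut, self.al_cfg, measured_x, measured_y,
            seed=self.seed,
        )

        # stem link + grain model on training plots
        leaf_p_obs = fill.trait("leaf_P")[train_idx]
        stem_p_obs = fill.trait("stem_P")[train_idx]
        self.stem_link_ = fit_stem_link(leaf_p_obs, stem_p_obs, degree=self.stem_degree)
        self.grain_model_ = fit_band_regressor(
            milk.subset(train_idx), "grain_biomass", kind=self.grain_kind, seed=self.seed
        )
        return self

    def predict(
        self, datasets: dict[str, SpectralDataset], idx: np.ndarray
    ) -> OrganUptake:
        idx = np.asarray(idx, dtype=int)
        fill = datasets["filling"].subset(idx)
        milk = datasets["milk"].subset(idx)
        lpc_hat = self.lpc_model_.predict(fill)
        biomass_hat = self.biomass_model_.predict(fill)
        leaf_p = uptake_from_conc_biomass(lpc_hat, biomass_hat)
        stem_p = self.stem_link_.predict(leaf_p)
        if self.grain_conc_source == "predicted":
            # mature-leaf P composites jointing + filling leaf layers, so
            # the predicted proxy averages the two stages' LPC predictions
            grain_conc = lpc_hat
            if "jointing" in datasets and self.lpc_model_jointing_ is not None:
                lpc_joint = self.lpc_model_jointing_.predict(datasets["jointing"].subset(idx))
                grain_conc = 0.5 * (lpc_hat + lpc_joint)
        elif self.grain_conc_source == "measured":
            grain_conc = milk.trait("mature_leaf_conc")
        else:
            raise ValueError(f"unknown grain_conc_source {self.grain_conc_source!r}")
        grain_bio = self.grain_model_.predict(milk)
        grain_p = uptake_from_conc_biomass(grain_conc, grain_bio)
        table = pd.DataFrame({
            "plot_id": fill.meta["plot_id"].to_numpy(),
            "leaf_P": leaf_p, "stem_P": stem_p, "grain_P": grain_p,
            "SPU": leaf_p + stem_p + grain_p,
        })
        return OrganUptake(table)


def _concat_datasets(parts: list[SpectralDataset]) -> SpectralDataset:
    wl = parts[0].wavelengths
    for p in parts[1:]:
        if not np.array_equal(p.wavelengths, wl):
            raise ValueError("datasets must share a wavelength grid")
    return SpectralDataset(
        wavelengths=wl.copy(),
        reflectance=np.vstack([p.reflectance for p in parts]),
        meta=pd.concat([p.meta for p in parts], ignore_index=True),
        traits=pd.concat([p.traits for p in parts], ignore_index=True),
        is_derivative=parts[0].is_derivative,
    )


def predict_spu_whole_plant(
    ds_stage: SpectralDataset,
    train_idx: np.ndarray,
    predict_idx: np.ndarray,
    kind: str = "GBRT",
    seed: int | None = None,
) -> tuple[np.ndarray, BandRegressor]:
    """Direct single-stage spectral SPU model (the empirical baseline).

    Trains on the SPU labels of the training plots only; overlapping
    train/predict indices are rejected to guard against leakage."""
    train_idx = np.asarray(train_idx, dtype=int)
    predict_idx = np.asarray(predict_idx, dtype=int)
    if np.intersect1d(train_idx, predict_idx).size:
        raise ValueError("train and predict sets overlap")
    stage_vals = set(ds_stage.meta["stage"].unique())
    if not stage_vals <= {"jointing", "filling", "milk"}:
        raise ValueError(f"unknown stage labels: {sorted(stage_vals)}")
    reg = fit_band_regressor(ds_stage.subset(train_idx), "SPU", kind=kind, seed=seed)
    return reg.predict(ds_stage.subset(predict_idx)), reg
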