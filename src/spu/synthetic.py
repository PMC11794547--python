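"""Synthetic multi-treatment field campaign with known ground truth.

Emulates a randomized-block P-fertilization trial on summer maize:
``n_treatments`` P rates x ``n_reps`` replicate plots, observed at the
jointing, filling and milk stages.  Each plot carries a latent "vigor"
deviate shared across its traits, treatment-dependent saturating
responses of LAI, chlorophyll and leaf P concentration to the P rate,
and canopy spectra simulated with the forward radiative-transfer model
plus multiplicative/additive sensor noise and a smooth baseline wiggle.

Phosphorus bookkeeping (all per plot):

* leaf P uptake  = canopy leaf P concentration (filling) x leaf biomass
  (filling)  [g/kg x t/ha = kg/ha];
* stem P uptake  = stem P concentration x stem biomass;
* grain P uptake = f_leaf x leaf P + f_stem x stem P, with remobilized
  fractions drawn uniformly from the physiological ranges
  f_leaf in [0.50, 0.85] and f_stem in [0.15, 0.50];
* grain biomass  = grain P / grain P concentration, where the grain P
  concentration equals the mature-leaf P concentration times
  ``grain_conc_ratio`` (ratio 1 makes the leaf-for-grain concentration
  substitution exact);
* SPU = leaf P + stem P + grain P.

Leaf and stem uptakes are the pre-remobilization (filling-stage) pools,
so SPU is the total P allocated to shoot tissue over the season.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rtm import forward as rtm_forward
from .spectra_io import SpectralDataset

__all__ = ["CampaignConfig", "CampaignTruth", "generate_campaign", "worked_fixture_small"]

STAGES = ("jointing", "filling", "milk")

#: P2O5 application rates (kg/ha) spanning the deficient-to-saturated range
DEFAULT_P_RATES = (0.0, 15.0, 30.0, 45.0, 65.0, 90.0, 120.0)

# stage multipliers of the seasonal trait trajectories
_LAI_MULT = {"jointing": 0.50, "filling": 1.00, "milk": 0.88}
_CM_BASE = {"jointing": 0.0045, "filling": 0.0068, "milk": 0.0078}
_LPC_BASE = {"jointing": 3.4, "filling": 2.8, "milk": 2.2}  # g/kg at full P
_CBROWN = {"jointing": 0.0, "filling": 0.05, "milk": 0.35}
_CW_BASE = {"jointing": 0.017, "filling": 0.016, "milk": 0.013}
# layers measured per stage when compositing the canopy P concentration
MATURE_LAYERS = {"jointing": ("upper", "middle"), "filling": ("upper", "middle", "lower")}
_LAYER_FACTOR = {"upper": 1.08, "middle": 1.00, "lower": 0.88}


@dataclass
class CampaignConfig:
    """Design and noise model of the synthetic campaign."""

    n_treatments: int = 7
    n_reps: int = 4
    p_rates: tuple[float, ...] = DEFAULT_P_RATES
    stages: tuple[str, ...] = STAGES
    k_half: float = 40.0  # P half-saturation, kg/ha
    lai_max: float = 6.0
    vigor_sd: float = 0.06  # plot-level latent deviate (relative)
    trait_noise_sd: float = 0.03  # idiosyncratic relative trait noise
    mult_noise_sd: float = 0.01  # multiplicative reflectance noise
    add_noise_sd: float = 0.002  # additive reflectance noise
    baseline_sd: float = 0.0015  # smooth polynomial baseline wiggle
    grain_conc_ratio: float = 1.0  # grain conc / mature-leaf conc
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_treatments * self.n_reps < 20:
            raise ValueError("campaign needs at least 20 plots")
        if len(self.p_rates) < self.n_treatments:
            raise ValueError("need one P rate per treatment")
        for s in (self.mult_noise_sd, self.add_noise_sd, self.baseline_sd):
            if s < 0:
                raise ValueError("noise SDs must be >= 0")


@dataclass
class CampaignTruth:
    """Ground truth plus the simulated datasets of one campaign."""

    config: CampaignConfig
    plots: pd.DataFrame  # per-plot season truth (organ P, biomass, fractions)
    stage_params: dict[str, pd.DataFrame]  # forward-model parameters per stage
    datasets: dict[str, SpectralDataset]  # noisy spectra + traits per stage
    clean_spectra: dict[str, np.ndarray]  # noise-free counterparts

    def stage(self, name: str) -> SpectralDataset:
        return self.datasets[name]


def _saturating(p: np.ndarray, k: float) -> np.ndarray:
    return p / (p + k)


def generate_campaign(cfg: CampaignConfig | None = None) -> CampaignTruth:
    """Simulate the full campaign (deterministic under ``cfg.seed``)."""
    cfg = cfg or CampaignConfig()
    rng = np.random.default_rng(cfg.seed)
    n_plots = cfg.n_treatments * cfg.n_reps
    rates = np.repeat(np.asarray(cfg.p_rates[: cfg.n_treatments]), cfg.n_reps)
    treatment = np.repeat([f"P{i}" for i in range(cfg.n_treatments)], cfg.n_reps)
    plot_id = np.array([f"plot{i:02d}" for i in range(n_plots)])
    vigor = rng.normal(0.0, cfg.vigor_sd, n_plots)
    resp = _saturating(rates, cfg.k_half)

    def jitter(scale: float = 1.0) -> np.ndarray:
        return 1.0 + rng.normal(0.0, cfg.trait_noise_sd * scale, n_plots)

    ala = np.clip(rng.normal(60.0, 3.0, n_plots) - 6.0 * resp, 42.0, 72.0)
    hs = rng.uniform(0.08, 0.2, n_plots)
    psoil = rng.uniform(0.5, 0.9, n_plots)

    stage_rows: dict[str, pd.DataFrame] = {}
    layer_conc: dict[tuple[str, str], np.ndarray] = {}
    lpc_canopy: dict[str, np.ndarray] = {}
    lai_s: dict[str, np.ndarray] = {}
    cm_s: dict[str, np.ndarray] = {}
    for stage in cfg.stages:
        lai = cfg.lai_max * (0.30 + 0.70 * resp) * _LAI_MULT[stage] * (1.0 + vigor) * jitter()
        lai = np.clip(lai, 0.2, 9.5)
        cm = _CM_BASE[stage] * (1.0 + 0.5 * vigor) * jitter(0.5)
        lpc0 = _LPC_BASE[stage] * (0.55 + 0.60 * resp) * (1.0 + vigor) * jitter(0.5)
        for layer, f in _LAYER_FACTOR.items():
            layer_conc[(stage, layer)] = lpc0 * f * jitter(0.3)
        layers = MATURE_LAYERS.get(stage, ("upper", "middle", "lower"))
        lpc = np.mean([layer_conc[(stage, l)] for l in layers], axis=0)
        cab = np.clip(13.0 * lpc + 3.0 + rng.normal(0.0, 1.5, n_plots), 12.0, 95.0)
        if stage == "milk":
            cab = cab * 0.8
        car = np.clip(cab / 4.2 + rng.normal(0.0, 0.6, n_plots), 2.0, 30.0)
        cw = np.clip(_CW_BASE[stage] * (1.0 + 0.3 * resp) * (1.0 + vigor), 0.005, 0.05)
        params = pd.DataFrame({
            "N_struct": np.full(n_plots, 1.5),
            "Cab": cab, "Car": car, "Cbrown": np.full(n_plots, _CBROWN[stage]),
            "Cw": cw, "Cm": cm, "LAI": lai, "ALA": ala, "hs": hs, "psoil": psoil,
        })
        stage_rows[stage] = params
        lpc_canopy[stage] = lpc
        lai_s[stage], cm_s[stage] = lai, cm

    # season-level P bookkeeping (see module docstring)
    leaf_bio = 100.0 * lai_s["filling"] * cm_s["filling"]
    stem_bio = 1.5 * leaf_bio**1.1 * (1.0 + vigor) * jitter(0.5)
    stem_conc = 0.42 * lpc_canopy["filling"] * jitter(0.5)
    mature_conc = np.mean(
        [layer_conc[(s, l)] for s, layers in MATURE_LAYERS.items() for l in layers], axis=0
    )
    leaf_p = lpc_canopy["filling"] * leaf_bio
    stem_p = stem_conc * stem_bio
    f_leaf = rng.uniform(0.50, 0.85, n_plots)
    f_stem = rng.uniform(0.15, 0.50, n_plots)
    grain_p = f_leaf * leaf_p + f_stem * stem_p
    grain_conc = cfg.grain_conc_ratio * mature_conc
    grain_bio = grain_p / grain_conc
    spu = leaf_p + stem_p + grain_p

    plots = pd.DataFrame({
        "plot_id": plot_id, "treatment": treatment, "p_rate": rates, "vigor": vigor,
        "leaf_biomass": leaf_bio, "stem_biomass": stem_bio, "grain_biomass": grain_bio,
        "AGB": leaf_bio + stem_bio, "mature_leaf_conc": mature_conc,
        "stem_conc": stem_conc, "grain_conc": grain_conc,
        "f_leaf_refix": f_leaf, "f_stem_refix": f_stem,
        "leaf_P": leaf_p, "stem_P": stem_p, "grain_P": grain_p, "SPU": spu,
    })

    datasets: dict[str, SpectralDataset] = {}
    clean: dict[str, np.ndarray] = {}
    wl = rtm_forward.WAVELENGTHS
    xnorm = (wl - wl[0]) / (wl[-1] - wl[0])
    vander = np.vander(xnorm, 3, increasing=True)
    for stage in cfg.stages:
        spec = rtm_forward.simulate_batch(stage_rows[stage])
        clean[stage] = spec.copy()
        noisy = spec * (1.0 + rng.normal(0.0, cfg.mult_noise_sd, spec.shape))
        noisy += rng.normal(0.0, cfg.add_noise_sd, spec.shape)
        noisy += rng.normal(0.0, cfg.baseline_sd, (n_plots, 3)) @ vander.T
        noisy = np.clip(noisy, 0.0, 1.0)
        traits = pd.DataFrame({
            "LPC": lpc_canopy[stage],
            "leaf_biomass": 100.0 * lai_s[stage] * cm_s[stage],
            "AGB": plots["AGB"], "grain_biomass": grain_bio,
            "mature_leaf_conc": mature_conc,
            "leaf_P": leaf_p, "stem_P": stem_p, "grain_P": grain_p, "SPU": spu,
        })
        meta = pd.DataFrame({
            "sample_id": plot_id, "plot_id": plot_id,
            "stage": stage, "treatment": treatment,
        })
        datasets[stage] = SpectralDataset(
            wavelengths=wl.copy(), reflectance=noisy, meta=meta, traits=traits
        )
    return CampaignTruth(cfg, plots, stage_rows, datasets, clean)


# 6 spectra x 12 bands, a 450 nm absorption feature deepening with the
# trait (1.0 ... 3.5) plus a gentle slope and frozen measurement noise;
# small enough that the correlation maps can be checked by hand.
_FIXTURE_WAVELENGTHS = np.arange(400.0, 520.0, 10.0)
_FIXTURE_TRAIT = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
_FIXTURE_REFLECTANCE = np.array([
    [0.4001, 0.4026, 0.4005, 0.3922, 0.3695, 0.3665, 0.3836, 0.4096, 0.4272, 0.4487, 0.4488, 0.4541],
    [0.4026, 0.4041, 0.3937, 0.3792, 0.3496, 0.3350, 0.3533, 0.3940, 0.4291, 0.4424, 0.4477, 0.4581],
    [0.4008, 0.4018, 0.3931, 0.3683, 0.3247, 0.3067, 0.3330, 0.3838, 0.4269, 0.4422, 0.4456, 0.4525],
    [0.3980, 0.3986, 0.3890, 0.3525, 0.3032, 0.2770, 0.3117, 0.3770, 0.4213, 0.4386, 0.4483, 0.4594],
    [0.3999, 0.4011, 0.3850, 0.3412, 0.2761, 0.2473, 0.2830, 0.3611, 0.4164, 0.4371, 0.4501, 0.4547],
    [0.3944, 0.3974, 0.3813, 0.3284, 0.2516, 0.2160, 0.2622, 0.3488, 0.4123, 0.4406, 0.4496, 0.4533],
])


def worked_fixture_small() -> SpectralDataset:
    """Tiny frozen dataset (6 samples x 12 bands) whose 2D correlation
    maps are hand-checkable; the ``conc`` trait orders the samples."""
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "plot_id": [f"s{i}" for i in range(6)],
        "stage": "filling",
        "treatment": [f"T{i}" for i in range(6)],
    })
    traits = pd.DataFrame({"conc": _FIXTURE_TRAIT})
    return SpectralDataset(
        wavelengths=_FIXTURE_WAVELENGTHS.copy(),
        reflectance=_FIXTURE_REFLECTANCE.copy(),
        meta=meta,
        traits=traits,
    )
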