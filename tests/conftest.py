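"""Shared fixtures: a small seeded campaign and helper constructions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spu.spectra_io import SpectralDataset
from spu.synthetic import CampaignConfig, generate_campaign


@pytest.fixture(scope="session")
def campaign():
    """Default synthetic campaign (7 P treatments x 4 replicates)."""
    return generate_campaign(CampaignConfig(seed=123))


@pytest.fixture()
def filling(campaign):
    return campaign.stage("filling")


def make_signal_dataset(
    seed: int,
    signal: bool = True,
    n: int = 60,
    center: float = 550.0,
    lo: float = 400.0,
    hi: float = 900.0,
) -> SpectralDataset:
    """Flat spectra plus (optionally) a Gaussian absorption band whose
    depth scales with the trait, plus white measurement noise."""
    rng = np.random.default_rng(seed)
    wl = np.arange(lo, hi + 1.0)
    t = rng.uniform(1.0, 4.0, n)
    x = np.tile(0.30 + 0.0002 * (wl - wl[0]), (n, 1))
    if signal:
        x = x - 0.04 * t[:, None] * np.exp(-0.5 * ((wl - center) / 10.0) ** 2)
        x = x + rng.normal(0.0, 0.002, x.shape)
    else:
        x = x + rng.normal(0.0, 0.003, x.shape)
    meta = pd.DataFrame({"sample_id": [f"s{i:02d}" for i in range(n)]})
    return SpectralDataset(wl, np.clip(x, 0.0, 1.0), meta, pd.DataFrame({"t": t}))


def plot_train_test(ds, ratio: float = 0.7, seed: int = 0):
    """Treatment-stratified plot-level split returning index arrays."""
    from spu.spectra_io import split_train_test

    tr_ds, _ = split_train_test(ds, ratio, stratify_by="treatment", seed=seed)
    tr = np.flatnonzero(ds.meta["plot_id"].isin(tr_ds.meta["plot_id"]))
    te = np.setdiff1d(np.arange(len(ds)), tr)
    return tr, te
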