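"""Regressors, spectral-index features, variable importance and
evaluation metrics shared by the empirical and hybrid models.

The extreme learning machine (ELM) — a single-hidden-layer network
with seeded random hidden weights and least-squares (Moore-Penrose)
output weights — is implemented here; the remaining regressors wrap
scikit-learn estimators behind one factory so models carry their kind,
hyperparameters and seed for serialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "ELMRegressor",
    "FittedRegressor",
    "fit_regressor",
    "elm_predict",
    "IndexFeature",
    "dual_band_index_features",
    "rank_and_select_indices",
    "rf_importance_topk",
    "EvalReport",
    "evaluate_metrics",
]

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "SVR": {"C": 10.0, "epsilon": 0.01, "kernel": "rbf"},
    "GBRT": {"n_estimators": 500, "learning_rate": 0.05, "max_depth": 3},
    "BPNN": {"hidden_layer_sizes": (16,), "max_iter": 4000, "early_stopping": False},
    "RF": {"n_estimators": 500},
    "ELM": {"n_hidden": 100, "activation": "sigmoid"},
    "polynomial": {"degree": 2},
}


class ELMRegressor:
    """Extreme learning machine: fixed random hidden layer, analytic
    output weights.

    Hidden weights/biases are drawn once from the seeded generator;
    output weights solve the least-squares problem ``H beta = y`` via
    the Moore-Penrose pseudoinverse, so training is non-iterative and,
    with at least as many hidden units as distinct samples, interpolates
    the training data.  Inputs are standardized internally.
    """

    def __init__(
        self,
        n_hidden: int = 100,
        activation: str = "sigmoid",
        seed: int | None = None,
        ridge: float = 0.0,
    ):
        self.n_hidden = int(n_hidden)
        self.activation = activation
        self.seed = seed
        self.ridge = float(ridge)
        self._fitted = False

    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "sigmoid":
            return 1.0 / (1.0 + np.exp(-z))
        if self.activation == "tanh":
            return np.tanh(z)
        if self.activation == "linear":
            return z
        raise ValueError(f"unknown activation {self.activation!r}")

    def _hidden(self, x: np.ndarray) -> np.ndarray:
        z = (x - self._mu) / self._sd
        h = self._act(z @ self._w + self._b)
        return np.column_stack([h, np.ones(len(h))])

    def fit(self, x: np.ndarray, y: np.ndarray) -> "ELMRegressor":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 2 or x.shape[1] == 0:
            raise ValueError("X must be 2-D with at least one feature")
        rng = np.random.default_rng(self.seed)
        self._mu = x.mean(axis=0)
        self._sd = np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
        d = x.shape[1]
        self._w = rng.normal(0.0, 1.0 / np.sqrt(d), (d, self.n_hidden))
        self._b = rng.uniform(-1.0, 1.0, self.n_hidden)
        h = self._hidden(x)
        if self.ridge > 0.0:
            gram = h.T @ h + self.ridge * np.eye(h.shape[1])
            self._beta = np.linalg.solve(gram, h.T @ y)
        else:
            self._beta, *_ = np.linalg.lstsq(h, y, rcond=None)
        self._fitted = True
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("ELM not fitted")
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != len(self._mu):
            raise ValueError(f"expected {len(self._mu)} features, got {x.shape}")
        return self._hidden(x) @ self._beta


class _ConstantRegressor:
    def __init__(self, value: float):
        self.value = float(value)

    def fit(self, x, y):
        return self

    def predict(self, x):
        return np.full(len(x), self.value)


class PolynomialRegressor:
    """Univariate least-squares polynomial (used for organ-uptake links)."""

    def __init__(self, degree: int = 2):
        self.degree = int(degree)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "PolynomialRegressor":
        x = np.asarray(x, dtype=float).reshape(-1)
        self.coef_ = np.polyfit(x, np.asarray(y, float), self.degree)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coef_, np.asarray(x, dtype=float).reshape(-1))


@dataclass
class FittedRegressor:
    """A fitted model plus everything needed to reproduce it."""

    kind: str
    hyperparams: dict
    seed: int | None
    model: object

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(np.asarray(x, dtype=float)))


def fit_regressor(
    kind: str,
    x: np.ndarray,
    y: np.ndarray,
    hyperparams: dict | None = None,
    seed: int | None = None,
) -> FittedRegressor:
    """Fit one of the supported regressors (SVR, GBRT, BPNN, RF, ELM,
    polynomial) with seeded determinism."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 training samples")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing/non-finite values in training data")
    if kind not in DEFAULT_HYPERPARAMS:
        raise ValueError(f"unknown regressor kind {kind!r}")
    hp = dict(DEFAULT_HYPERPARAMS[kind])
    hp.update(hyperparams or {})

    if np.ptp(y) == 0.0:
        warnings.warn("degenerate response (zero variance); fitting constant predictor")
        return FittedRegressor(kind, hp, seed, _ConstantRegressor(y[0]).fit(x, y))

    if kind == "SVR":
        # RBF kernels need standardized features
        model = make_pipeline(StandardScaler(), SVR(**hp))
    elif kind == "GBRT":
        model = GradientBoostingRegressor(random_state=seed, **hp)
    elif kind == "BPNN":
        model = make_pipeline(StandardScaler(), MLPRegressor(random_state=seed, **hp))
    elif kind == "RF":
        model = RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    elif kind == "ELM":
        model = ELMRegressor(seed=seed, **hp)
    elif kind == "polynomial":
        model = PolynomialRegressor(**hp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn convergence chatter
        model.fit(x, y)
    return FittedRegressor(kind, hp, seed, model)


def elm_predict(model: FittedRegressor | ELMRegressor, x: np.ndarray) -> np.ndarray:
    """Predict with a fitted ELM (``H(X) @ beta``)."""
    elm = model.model if isinstance(model, FittedRegressor) else model
    if not isinstance(elm, ELMRegressor):
        raise TypeError("elm_predict requires an ELM model")
    return elm.predict(np.asarray(x, dtype=float))


@dataclass
class IndexFeature:
    """A two-band spectral index evaluated per sample.

    Forms (with i the longer wavelength): DSI = R_i - R_j,
    RSI = R_i / R_j, NDSI = (R_i - R_j) / (R_i + R_j).
    """

    form: str
    band_i: float
    band_j: float
    values: np.ndarray

    @property
    def name(self) -> str:
        return f"{self.form}({self.band_i:g},{self.band_j:g})"


def dual_band_index_features(
    ds,
    bands,
    forms: tuple[str, ...] = ("DSI", "RSI", "NDSI"),
) -> list[IndexFeature]:
    """All pairwise two-band indices over a band set.

    Symmetric forms (DSI, NDSI) use unordered pairs with the longer
    wavelength first; RSI is directional so both orders are produced.
    RSI pairs with a near-zero denominator are dropped with a warning.
    """
    wl = list(np.asarray(getattr(bands, "wavelengths", bands), dtype=float))
    if len(wl) < 2:
        raise ValueError("need at least 2 bands for dual-band indices")
    grid = ds.wavelengths
    cols = {}
    for w in wl:
        hit = np.flatnonzero(np.isclose(grid, w))
        if not len(hit):
            raise KeyError(f"band {w} nm not on dataset grid")
        cols[w] = ds.reflectance[:, hit[0]]
    feats: list[IndexFeature] = []
    ordered = sorted(wl)
    for form in forms:
        if form in ("DSI", "NDSI"):
            for a in range(len(ordered)):
                for b in range(a + 1, len(ordered)):
                    wj, wi = ordered[a], ordered[b]  # i = longer wavelength
                    ri, rj = cols[wi], cols[wj]
                    vals = ri - rj if form == "DSI" else (ri - rj) / (ri + rj)
                    feats.append(IndexFeature(form, wi, wj, vals))
        elif form == "RSI":
            for wi in ordered:
                for wj in ordered:
                    if wi == wj:
                        continue
                    if np.any(np.abs(cols[wj]) < 1e-6):
                        warnings.warn(f"RSI({wi:g},{wj:g}) dropped: near-zero denominator")
                        continue
                    feats.append(IndexFeature("RSI", wi, wj, cols[wi] / cols[wj]))
        else:
            raise ValueError(f"unknown index form {form!r}")
    return feats


def rank_and_select_indices(
    features: list[IndexFeature],
    y: np.ndarray,
    top_pos: int = 10,
    top_neg: int = 10,
) -> list[IndexFeature]:
    """Keep the most positively and most negatively trait-correlated
    indices (Pearson r; ties broken by |r|, then band order)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need n >= 3 to rank correlations")
    scored = []
    for k, f in enumerate(features):
        v = f.values
        r = 0.0 if np.ptp(v) == 0 else float(np.corrcoef(v, y)[0, 1])
        scored.append((r, k))
    pos = sorted((s for s in scored if s[0] > 0), key=lambda s: (-s[0], s[1]))
    neg = sorted((s for s in scored if s[0] < 0), key=lambda s: (s[0], s[1]))
    if len(pos) < top_pos or len(neg) < top_neg:
        warnings.warn(
            f"only {len(pos)} positive / {len(neg)} negative correlated indices available"
        )
    keep = pos[:top_pos] + neg[:top_neg]
    return [features[k] for _, k in keep]


def rf_importance_topk(model: FittedRegressor, k: int, band_names=None) -> np.ndarray:
    """Indices (or names) of the k most important features of a fitted
    random forest, by impurity importance, descending."""
    rf = model.model if isinstance(model, FittedRegressor) else model
    if not hasattr(rf, "feature_importances_"):
        raise TypeError("model does not expose feature importances")
    imp = rf.feature_importances_
    order = np.argsort(-imp)[: min(k, len(imp))]
    if band_names is not None:
        return np.asarray(band_names)[order]
    return order


@dataclass
class EvalReport:
    """Standard chemometric accuracy metrics."""

    R2: float
    RMSE: float
    MAE: float
    MAPE: float
    RPD: float
    n: int

    def as_dict(self) -> dict:
        return {"R2": self.R2, "RMSE": self.RMSE, "MAE": self.MAE,
                "MAPE": self.MAPE, "RPD": self.RPD, "n": self.n}


def evaluate_metrics(y_obs: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """R2, RMSE, MAE, MAPE (fraction, over nonzero observations) and
    RPD (sample SD of the observations / RMSE)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1:
        raise ValueError("y_obs and y_pred must be 1-D of equal length")
    n = len(y_obs)
    if n < 2:
        raise ValueError("need n >= 2")
    err = y_pred - y_obs
    sse = float(np.sum(err**2))
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    rmse = float(np.sqrt(sse / n))
    mae = float(np.mean(np.abs(err)))
    nz = y_obs != 0
    mape = float(np.mean(np.abs(err[nz] / y_obs[nz]))) if nz.any() else float("nan")
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    sd = float(np.std(y_obs, ddof=1))
    rpd = float("inf") if rmse == 0 else sd / rmse
    return EvalReport(R2=r2, RMSE=rmse, MAE=mae, MAPE=mape, RPD=rpd, n=n)
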