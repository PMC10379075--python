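"""Calibration models (PLS1, epsilon-SVR) and evaluation metrics.

Metrics follow the conventions of NIR calibration work:

    R²  = 1 − Σ(f_i − y_i)² / Σ(ȳ − y_i)²          (calibration: R²c, prediction: R²p)
    RMSE = sqrt( (1/m) Σ(f_i − y_i)² )              (RMSEC / RMSEP)

with f_i the predicted and y_i the reference value.  The limit of
detection and quantification use the calibration-curve convention

    LOD = 3.3 · s_res / slope,   LOQ = 10 · s_res / slope,

where s_res is the standard deviation of the training residuals and
slope the slope of the predicted-versus-reference regression line on
the training set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import linregress
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._pls import best_lv_by_cv, fit_pls1, max_components

__all__ = [
    "CalibrationModel",
    "EvaluationReport",
    "fit_pls",
    "fit_svr",
    "evaluate",
    "r_squared",
    "rmse",
    "default_svr_grid",
]


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined: reference values have zero variance")
    return 1.0 - float(np.sum((y_pred - y_true) ** 2)) / ss_tot


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


@dataclass
class CalibrationModel:
    """A fitted calibration: PLS1 or RBF epsilon-SVR.

    ``channel_subset`` records the channel indices the model was trained
    on (None means the full spectrum); ``predict`` expects matrices on
    those channels.
    """

    kind: str
    estimator: object
    n_lv: int | None = None
    hyperparameters: dict = field(default_factory=dict)
    scaler: StandardScaler | None = None
    channel_subset: np.ndarray | None = None
    cv_trace: list = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return np.asarray(self.estimator.predict(X)).ravel()

    @property
    def descriptor(self) -> str:
        if self.kind == "pls":
            return f"PLS({self.n_lv} LV)"
        hp = ", ".join(f"{k}={v:g}" for k, v in self.hyperparameters.items())
        return f"SVR({hp})"


def fit_pls(
    X_train: np.ndarray,
    y_train: np.ndarray,
    max_lv: int = 10,
    cv_folds: int = 5,
    seed: int = 0,
) -> CalibrationModel:
    """PLS1 with the latent-variable count chosen by minimum CV RMSE."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if np.ptp(y_train) == 0.0:
        raise ValueError("degenerate target: y_train is constant")
    cap = max_components(*X_train.shape)
    if max_lv > cap:
        warnings.warn(f"max_lv clamped from {max_lv} to {cap}", stacklevel=2)
        max_lv = cap
    n_lv, _, trace = best_lv_by_cv(X_train, y_train, max_lv, cv_folds, seed)
    model = fit_pls1(X_train, y_train, n_lv)
    return CalibrationModel("pls", model, n_lv=n_lv, cv_trace=trace)


def default_svr_grid(X_train: np.ndarray) -> list[dict]:
    """C/gamma/epsilon grid around sklearn's 'scale' gamma heuristic."""
    X_train = np.asarray(X_train, dtype=float)
    var = float(X_train.var())
    g0 = 1.0 / (X_train.shape[1] * var) if var > 0 else 1.0
    return [
        {"C": C, "gamma": g0 * gm, "epsilon": eps}
        for C, gm, eps in product(
            (0.1, 1.0, 10.0, 100.0), (0.1, 1.0, 10.0), (0.01, 0.1)
        )
    ]


def fit_svr(
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: list[dict] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> CalibrationModel:
    """RBF epsilon-SVR, hyperparameters chosen by cross-validated RMSE.

    Inputs are standardized channel-wise by training statistics.  Ties in
    CV RMSE break toward the earlier grid point, so a single-point grid
    is always selected as-is.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if not (np.all(np.isfinite(X_train)) and np.all(np.isfinite(y_train))):
        raise ValueError("non-finite values in SVR training data")
    scaler = StandardScaler().fit(X_train)
    Xs = scaler.transform(X_train)
    if grid is None:
        # the gamma heuristic must see the standardized matrix the RBF
        # kernel actually operates on
        grid = default_svr_grid(Xs)
    if not grid:
        raise ValueError("SVR hyperparameter grid is empty")
    folds = min(cv_folds, Xs.shape[0])
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))

    best: tuple[float, int] | None = None
    trace = []
    for gi, params in enumerate(grid):
        pred = np.empty_like(y_train)
        for tr, te in splits:
            est = SVR(kernel="rbf", **params)
            est.fit(Xs[tr], y_train[tr])
            pred[te] = est.predict(Xs[te])
        r = rmse(y_train, pred)
        trace.append((params, r))
        if best is None or r < best[0] - 1e-15:
            best = (r, gi)
    params = grid[best[1]]
    est = SVR(kernel="rbf", **params)
    est.fit(Xs, y_train)
    return CalibrationModel(
        "svr", est, hyperparameters=dict(params), scaler=scaler, cv_trace=trace
    )


@dataclass
class EvaluationReport:
    """Calibration and prediction metrics for one fitted model."""

    r2_train: float
    rmse_train: float
    r2_test: float
    rmse_test: float
    lod: float
    loq: float
    model_descriptor: str
    n_train: int
    n_test: int
    n_channels_used: int

    def __post_init__(self) -> None:
        if self.rmse_train < 0 or self.rmse_test < 0:
            raise ValueError("RMSE must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "R2c": self.r2_train,
            "RMSEC": self.rmse_train,
            "R2p": self.r2_test,
            "RMSEP": self.rmse_test,
            "LOD": self.lod,
            "LOQ": self.loq,
            "model": self.model_descriptor,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_channels": self.n_channels_used,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def evaluate(
    model: CalibrationModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> EvaluationReport:
    """Compute R²c/RMSEC, R²p/RMSEP and LOD/LOQ for a fitted model."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float).ravel()
    y_train = np.asarray(y_train, dtype=float).ravel()
    if y_test.size == 0:
        raise ValueError("prediction set is empty")
    if np.ptp(y_test) == 0.0:
        raise ValueError("R²p undefined: y_test has zero variance")

    f_train = model.predict(X_train)
    f_test = model.predict(X_test)
    s_res = float(np.std(f_train - y_train, ddof=1)) if y_train.size > 1 else 0.0
    fit = linregress(y_train, f_train)
    slope = float(fit.slope)
    if slope == 0.0:
        lod = loq = float("inf")
    else:
        lod = 3.3 * s_res / abs(slope)
        loq = 10.0 * s_res / abs(slope)
    return EvaluationReport(
        r2_train=r_squared(y_train, f_train),
        rmse_train=rmse(y_train, f_train),
        r2_test=r_squared(y_test, f_test),
        rmse_test=rmse(y_test, f_test),
        lod=lod,
        loq=loq,
        model_descriptor=model.descriptor,
        n_train=int(y_train.size),
        n_test=int(y_test.size),
        n_channels_used=int(np.asarray(X_train).shape[1]),
    )
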