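"""Internal PLS helpers shared by screening, selection and calibration."""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold


def max_components(n_samples: int, n_features: int) -> int:
    return max(1, min(n_samples - 1, n_features))


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSRegression:
    n_lv = min(n_lv, max_components(*X.shape))
    model = PLSRegression(n_components=n_lv, scale=False)
    with warnings.catch_warnings():
        # expected when the requested LV count exceeds the effective rank
        warnings.filterwarnings("ignore", message="y residual is constant")
        model.fit(X, y.reshape(-1, 1))
    return model


def cv_rmse(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    cv_folds: int = 5,
    seed: int = 0,
) -> float:
    """RMSE of K-fold cross-validated PLS1 predictions."""
    n = X.shape[0]
    folds = min(cv_folds, n)
    if folds < 2:
        raise ValueError("cross-validation needs at least 2 samples")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(n)
    for tr, te in kf.split(X):
        k = min(n_lv, max_components(tr.size, X.shape[1]))
        model = fit_pls1(X[tr], y[tr], k)
        pred[te] = model.predict(X[te]).ravel()
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def best_lv_by_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[int, float, list[tuple[int, float]]]:
    """Pick the latent-variable count with minimum CV RMSE over 1..max_lv.

    Ties break toward fewer components.  Returns (n_lv, rmse, trace).
    """
    cap = max_components(X.shape[0] - X.shape[0] // min(cv_folds, X.shape[0]), X.shape[1])
    trace = []
    best = (None, np.inf)
    for k in range(1, min(max_lv, cap) + 1):
        r = cv_rmse(X, y, k, cv_folds, seed)
        trace.append((k, r))
        if r < best[1] - 1e-15:
            best = (k, r)
    return best[0], best[1], trace
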