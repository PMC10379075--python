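"""Characteristic-wavelength selection: CARS, SPA and UVE.

All three selectors run strictly on calibration data and return a
:class:`WavelengthSubset` carrying the chosen channel indices plus
method diagnostics.

CARS (competitive adaptive reweighted sampling) runs N Monte-Carlo
iterations; each fits a PLS model on a random sample subset, ranks
variables by |regression coefficient|, enforces an exponentially
decreasing retention schedule (the "exponentially decreasing function",
r_i = a·exp(−k·i) with r_1 = 1 and r_N = 2/p), then resamples variables
with probability proportional to |coefficient|.  The iteration whose
survivor set has the lowest cross-validated RMSE wins.

SPA (successive projections algorithm) greedily grows chains of
minimally collinear channels: at each step the unselected column with
the largest norm after projection onto the orthogonal complement of the
selected columns is added.  Chains from several starting channels are
scored by the validation RMSE of an ordinary least-squares model and
the best chain prefix is returned.

UVE (uninformative variable elimination) appends as many random noise
columns as there are real channels, runs leave-one-out PLS collecting
the coefficient vectors, scores every column by the reliability
c_j = mean(b_j)/sd(b_j), and retains the real channels whose |c_j|
exceeds the largest |c| observed among the noise columns.

Ties everywhere break toward the lowest channel index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._pls import cv_rmse, fit_pls1, max_components
from .sample_split import ks_split

__all__ = [
    "WavelengthSubset",
    "CarsSettings",
    "SpaSettings",
    "UveSettings",
    "cars_select",
    "spa_select",
    "uve_select",
    "cars_retention_schedule",
]


@dataclass
class WavelengthSubset:
    """Selected channel indices with per-method diagnostics."""

    selected_indices: np.ndarray
    selected_nm: np.ndarray
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0)):
            raise ValueError("selected indices must be unique and sorted")
        self.selected_indices = idx
        self.selected_nm = np.asarray(self.selected_nm, dtype=float)

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)

    def to_json(self) -> str:
        diag = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.diagnostics.items()
        }
        return json.dumps(
            {
                "method": self.method,
                "selected_indices": self.selected_indices.tolist(),
                "selected_nm": self.selected_nm.tolist(),
                "diagnostics": diag,
            }
        )


@dataclass(frozen=True)
class CarsSettings:
    n_runs: int = 50
    sample_fraction: float = 0.8
    cv_folds: int = 5
    max_lv: int = 10

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("CARS needs at least 2 Monte-Carlo runs")
        if not (0.0 < self.sample_fraction < 1.0):
            raise ValueError("sample_fraction must be in (0, 1)")


@dataclass(frozen=True)
class SpaSettings:
    max_vars: int = 25
    n_start_candidates: int = 10
    validation_ratio: float = 0.75


@dataclass(frozen=True)
class UveSettings:
    n_noise_vars: int | None = None  # None -> one per real channel
    noise_amplitude: float = 1e-10
    n_lv: int | None = None  # None -> CV-optimal on the real channels
    cutoff_rule: str = "max"
    max_lv: int = 10  # cap for the CV search when n_lv is None


def cars_retention_schedule(p: int, n_runs: int) -> np.ndarray:
    """Forced retention ratios r_i = a·exp(−k·i), r_1 = 1, r_N = 2/p."""
    if p < 2:
        raise ValueError("need at least 2 channels")
    k = np.log(p / 2.0) / (n_runs - 1)
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths_nm: np.ndarray,
    settings: CarsSettings | None = None,
    seed: int = 0,
) -> WavelengthSubset:
    """Competitive adaptive reweighted sampling on calibration data."""
    settings = settings or CarsSettings()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    r = cars_retention_schedule(p, settings.n_runs)
    rng = np.random.default_rng(seed)
    retained = np.arange(p)
    n_sub = max(2, int(round(settings.sample_fraction * n)))
    # LV count fixed once at the CV optimum of the full calibration set;
    # over-sized models give noisy coefficient rankings
    from ._pls import best_lv_by_cv

    n_lv0, _, _ = best_lv_by_cv(X, y, settings.max_lv, settings.cv_folds, seed)

    trace_rmsecv: list[float] = []
    trace_edf_count: list[int] = []
    trace_survivors: list[int] = []
    best: tuple[float, np.ndarray] | None = None
    for i in range(settings.n_runs):
        sub = rng.choice(n, size=n_sub, replace=False)
        model = fit_pls1(X[np.ix_(sub, retained)], y[sub],
                         min(n_lv0, max_components(n_sub, retained.size)))
        b = np.abs(np.asarray(model.coef_).ravel())
        # enforced shrink: top ceil(r_i * p) variables by |b|, never more
        # than currently retained, never fewer than 2
        keep_count = int(min(max(2, round(r[i] * p)), retained.size))
        order = np.argsort(-b, kind="stable")  # ties -> lowest index first
        kept_local = np.sort(order[:keep_count])
        retained = retained[kept_local]
        w = b[kept_local]
        trace_edf_count.append(int(retained.size))
        # adaptive reweighted sampling: p weighted draws with replacement
        prob = w / w.sum() if w.sum() > 0 else np.full(w.size, 1.0 / w.size)
        draws = rng.choice(retained.size, size=p, replace=True, p=prob)
        survivors = retained[np.unique(draws)]
        if survivors.size < 2:
            trace_rmsecv.append(np.nan)
            trace_survivors.append(int(survivors.size))
            continue  # failed iteration, excluded from the argmin
        retained = survivors
        trace_survivors.append(int(retained.size))
        rmsecv = cv_rmse(
            X[:, retained], y,
            min(n_lv0, max_components(n, retained.size)),
            settings.cv_folds, seed,
        )
        trace_rmsecv.append(rmsecv)
        if best is None or rmsecv < best[0] - 1e-15:
            best = (rmsecv, retained.copy())
    if best is None:
        raise ValueError("every CARS iteration failed (fewer than 2 survivors)")
    idx = np.sort(best[1])
    return WavelengthSubset(
        idx,
        np.asarray(wavelengths_nm)[idx],
        "cars",
        {
            "rmsecv": trace_rmsecv,
            "edf_retained": trace_edf_count,
            "ars_survivors": trace_survivors,
            "best_rmsecv": best[0],
            "retention_schedule": r.tolist(),
        },
    )


def _spa_chain(Xc: np.ndarray, start: int, max_vars: int, tol: float) -> list[int]:
    """One SPA projection chain from a starting column."""
    p = Xc.shape[1]
    residual = Xc.copy()
    chain = [start]
    selected = np.zeros(p, dtype=bool)
    selected[start] = True
    for _ in range(max_vars - 1):
        v = residual[:, chain[-1]]
        nv = v @ v
        if nv <= tol:
            break
        # project all columns onto the orthogonal complement of v
        residual = residual - np.outer(v, (v @ residual) / nv)
        norms = np.einsum("ij,ij->j", residual, residual)
        norms[selected] = -1.0
        nxt = int(np.argmax(norms))  # first maximizer -> lowest index on ties
        if norms[nxt] <= tol:
            break
        chain.append(nxt)
        selected[nxt] = True
    return chain


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths_nm: np.ndarray,
    settings: SpaSettings | None = None,
) -> WavelengthSubset:
    """Successive projections algorithm with OLS chain scoring.

    Chains are grown from the ``n_start_candidates`` highest-norm columns
    (after mean-centering); each chain prefix is scored by the RMSE of an
    ordinary least-squares model on a deterministic Kennard–Stone
    calibration/validation split of the training rows.
    """
    settings = settings or SpaSettings()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    max_vars = min(settings.max_vars, n - 2, p)
    if max_vars < 1:
        raise ValueError("too few samples/channels for SPA")
    Xc = X - X.mean(axis=0)
    tol = 1e-12 * max(1.0, float(np.max(np.einsum("ij,ij->j", Xc, Xc))))

    norms = np.einsum("ij,ij->j", Xc, Xc)
    order = np.argsort(-norms, kind="stable")
    starts = [int(s) for s in order[: settings.n_start_candidates]]

    split = ks_split(X, settings.validation_ratio)
    cal = np.asarray(split.train_indices)
    val = np.asarray(split.test_indices)

    best: tuple[float, int, tuple[int, ...]] | None = None  # (rmse, len, chain)
    chains: dict[int, list[int]] = {}
    for start in starts:
        chain = _spa_chain(Xc, start, max_vars, tol)
        chains[start] = chain
        for L in range(1, len(chain) + 1):
            cols = chain[:L]
            A = np.column_stack([np.ones(cal.size), X[np.ix_(cal, cols)]])
            coef, *_ = np.linalg.lstsq(A, y[cal], rcond=None)
            Av = np.column_stack([np.ones(val.size), X[np.ix_(val, cols)]])
            rmse = float(np.sqrt(np.mean((Av @ coef - y[val]) ** 2)))
            key = (rmse, L, tuple(sorted(cols)))
            if best is None or key < best:
                best = key
    assert best is not None
    idx = np.sort(np.asarray(best[2], dtype=int))
    return WavelengthSubset(
        idx,
        np.asarray(wavelengths_nm)[idx],
        "spa",
        {
            "validation_rmse": best[0],
            "chain_length": best[1],
            "chains": {str(s): c for s, c in chains.items()},
        },
    )


def uve_select(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths_nm: np.ndarray,
    settings: UveSettings | None = None,
    seed: int = 0,
) -> WavelengthSubset:
    """Uninformative variable elimination with a noise-matrix cutoff.

    The retained set may be empty when no channel beats the noise
    cutoff (e.g. when y carries no spectral information); callers that
    require a nonempty subset should treat that as a failed selection.

    With ``n_lv=None`` the latent-variable count is the CV-optimal one on
    the real channels; over-sized models destabilize the leave-one-out
    coefficients and depress the reliability of genuinely informative
    channels.
    """
    settings = settings or UveSettings()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    n_noise = settings.n_noise_vars if settings.n_noise_vars is not None else p
    rng = np.random.default_rng(seed)
    amp = settings.noise_amplitude * float(np.mean(np.abs(X)))
    noise = amp * (rng.random((n, n_noise)) - 0.5)
    Xa = np.hstack([X, noise])
    if settings.n_lv is None:
        from ._pls import best_lv_by_cv

        n_lv, _, _ = best_lv_by_cv(X, y, settings.max_lv, seed=seed)
    else:
        n_lv = settings.n_lv
    n_lv = min(n_lv, max_components(n - 1, Xa.shape[1]))

    coefs = np.empty((n, Xa.shape[1]))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_pls1(Xa[mask], y[mask], n_lv)
        coefs[i] = np.asarray(model.coef_).ravel()
        mask[i] = True

    mean_b = coefs.mean(axis=0)
    sd_b = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(sd_b > 0, mean_b / sd_b,
                     np.where(mean_b != 0, np.inf, 0.0))
    c_noise = np.abs(c[p:])
    degenerate = sd_b[p:] == 0.0
    if degenerate.any():
        warnings.warn(
            f"UVE: {int(degenerate.sum())} noise columns with constant "
            "coefficients excluded from the cutoff",
            stacklevel=2,
        )
        c_noise = c_noise[~degenerate]
    if c_noise.size == 0:
        raise ValueError("no valid noise columns to derive a UVE cutoff from")
    cutoff = float(np.max(c_noise))
    idx = np.flatnonzero(np.abs(c[:p]) > cutoff)
    return WavelengthSubset(
        idx,
        np.asarray(wavelengths_nm)[idx],
        "uve",
        {
            "reliability": c[:p].tolist(),
            "cutoff": cutoff,
            "n_noise_vars": int(n_noise),
            "n_lv": int(n_lv),
        },
    )
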