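"""Abnormal-spectrum screening by Mahalanobis distance in PCA score space.

Each sample's distance is

    D_i = sqrt( (t_i − T̄) M⁻¹ (t_i − T̄)ᵀ )

where t_i are its leading principal-component scores, T̄ the mean score
vector and M the (n−1)-denominator covariance matrix of the score
matrix.  A sample is removed when D_i ≥ D_th with

    D_th = D_m + e · σ_d

(D_m, σ_d: mean and standard deviation of the distances).  The weight
coefficient e tunes the strictness of the screen; it is chosen on a grid
by refitting a PLS calibration on the survivors for each candidate e and
keeping the e with the smallest cross-validated RMSE, ties broken toward
smaller e (fewer survivors removed).  Screening is single-pass: one
removal round, no iterative re-screening.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from ._pls import best_lv_by_cv
from .core import ReferenceTable, SpectraSet

__all__ = [
    "OutlierReport",
    "ScoreModel",
    "mahalanobis_distances",
    "select_threshold",
    "remove_outliers",
    "DEFAULT_E_GRID",
]

DEFAULT_E_GRID = tuple(float(e) for e in np.arange(0.5, 5.0 + 1e-9, 0.25))


@dataclass
class ScoreModel:
    """Frozen PCA score model backing a set of Mahalanobis distances."""

    pca: PCA
    n_pcs: int
    mean_score: np.ndarray
    covariance: np.ndarray


@dataclass
class OutlierReport:
    """Result of one screening round, serializable to JSON."""

    distances: np.ndarray
    d_mean: float
    d_sd: float
    e: float
    d_threshold: float
    removed_ids: list
    n_pcs: int
    e_grid_trace: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("Mahalanobis distances must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "d_mean": self.d_mean,
                "d_sd": self.d_sd,
                "e": self.e,
                "d_threshold": self.d_threshold,
                "n_pcs": self.n_pcs,
                "removed_ids": [str(s) for s in self.removed_ids],
                "distances": self.distances.tolist(),
                "e_grid_trace": [[float(e), float(r)] for e, r in self.e_grid_trace],
            },
            indent=2,
        )


def _choose_n_pcs(explained_ratio: np.ndarray, cap: int = 10) -> int:
    """Smallest PC count explaining >= 99% variance, capped."""
    cum = np.cumsum(explained_ratio)
    k = int(np.searchsorted(cum, 0.99) + 1)
    return max(1, min(k, cap, explained_ratio.size))


def mahalanobis_distances(
    spectra: SpectraSet, n_pcs: int | None = None
) -> tuple[np.ndarray, ScoreModel]:
    """Per-sample Mahalanobis distances in truncated PCA score space.

    When ``n_pcs`` is None, the smallest count explaining >= 99% of the
    variance is used, capped at 10.
    """
    X = spectra.absorbance
    n = X.shape[0]
    full = PCA(n_components=min(n - 1, X.shape[1]))
    scores_full = full.fit_transform(X)
    if n_pcs is None:
        n_pcs = _choose_n_pcs(full.explained_variance_ratio_)
    if not (1 <= n_pcs < n):
        raise ValueError("need n_samples > n_pcs >= 1")
    T = scores_full[:, :n_pcs]
    t_bar = T.mean(axis=0)
    M = np.cov(T, rowvar=False, ddof=1).reshape(n_pcs, n_pcs)
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular score covariance; retry with fewer principal components"
        ) from None
    diff = T - t_bar
    d2 = np.einsum("ij,jk,ik->i", diff, Minv, diff)
    distances = np.sqrt(np.maximum(d2, 0.0))
    return distances, ScoreModel(full, n_pcs, t_bar, M)


def threshold_report(
    distances: np.ndarray, e: float, sample_ids
) -> OutlierReport:
    """Apply D_th = D_m + e·σ_d to a fixed distance vector."""
    distances = np.asarray(distances, dtype=float)
    d_m = float(distances.mean())
    sigma = float(distances.std(ddof=1)) if distances.size > 1 else 0.0
    d_th = d_m + e * sigma
    removed = [sample_ids[i] for i in np.flatnonzero(distances >= d_th)]
    return OutlierReport(distances, d_m, sigma, float(e), d_th, removed, n_pcs=0)


def select_threshold(
    distances: np.ndarray,
    e_grid,
    spectra: SpectraSet,
    reference: ReferenceTable,
    target: str = "tvbn",
    max_lv: int = 10,
    cv_folds: int = 5,
    n_pcs: int = 0,
    seed: int = 0,
) -> OutlierReport:
    """Choose the threshold weight e by minimum cross-validated PLS RMSE.

    For every e in ``e_grid`` the screen is applied, a PLS calibration is
    cross-validated on the survivors, and the e with the smallest RMSE
    wins; ties go to the smaller e.  Grid points leaving fewer than
    ``2 * max_lv`` survivors are skipped with a warning.
    """
    e_grid = sorted(float(e) for e in e_grid)
    if not e_grid:
        raise ValueError("e_grid must be nonempty")
    distances = np.asarray(distances, dtype=float)
    if distances.size != spectra.n_samples:
        raise ValueError("one distance per sample is required")
    y_all = reference.values_for(target, spectra.sample_ids)

    trace: list[tuple[float, float]] = []
    best: tuple[float, float] | None = None  # (rmse, e)
    for e in e_grid:
        rep = threshold_report(distances, e, spectra.sample_ids)
        keep = distances < rep.d_threshold
        if keep.sum() < 2 * max_lv:
            warnings.warn(
                f"e={e}: only {int(keep.sum())} survivors (< {2 * max_lv}); skipped",
                stacklevel=2,
            )
            continue
        _, rmse, _ = best_lv_by_cv(
            spectra.absorbance[keep], y_all[keep], max_lv, cv_folds, seed
        )
        trace.append((e, rmse))
        if best is None or rmse < best[0] - 1e-15:
            best = (rmse, e)
    if best is None:
        raise ValueError("every e in the grid left too few survivors")
    report = threshold_report(distances, best[1], spectra.sample_ids)
    report.n_pcs = n_pcs
    report.e_grid_trace = trace
    return report


def remove_outliers(
    spectra: SpectraSet, reference: ReferenceTable, report: OutlierReport
) -> tuple[SpectraSet, ReferenceTable]:
    """Drop the report's removed ids from both containers, order preserved."""
    removed = set(report.removed_ids)
    unknown = removed - set(spectra.sample_ids)
    if unknown:
        raise KeyError(f"removed ids not present in spectra: {sorted(unknown)[:5]}")
    keep = [s for s in spectra.sample_ids if s not in removed]
    return spectra.select_samples(keep), reference.select_samples(keep)
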