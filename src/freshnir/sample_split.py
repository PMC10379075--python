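"""Calibration / prediction set partitioning: random, Kennard–Stone, SPXY.

Kennard–Stone (KS) seeds the calibration set with the two samples at
maximum Euclidean distance, then repeatedly adds the sample whose
minimum distance to the current calibration set is largest (max–min
rule) until the requested size is reached.  SPXY applies the same greedy
rule to the combined distance

    d_xy(p, q) = d_x(p, q) / max d_x  +  d_y(p, q) / max d_y,

which balances spectral and reference-value coverage.  Both are
deterministic; every tie breaks toward the lowest sample index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitResult", "random_split", "ks_split", "spxy_split"]

DEFAULT_TRAIN_RATIO = 0.7  # the study's 7:3 convention


@dataclass(frozen=True)
class SplitResult:
    """A train/test partition by position and id."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    method: str
    ratio: float
    seed: int | None = None

    def __post_init__(self) -> None:
        tr, te = set(self.train_indices), set(self.test_indices)
        if tr & te:
            raise ValueError("train and test sets overlap")

    @property
    def n_total(self) -> int:
        return len(self.train_indices) + len(self.test_indices)

    def ids(self, sample_ids) -> tuple[list, list]:
        sample_ids = list(sample_ids)
        return (
            [sample_ids[i] for i in self.train_indices],
            [sample_ids[i] for i in self.test_indices],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "ratio": self.ratio,
                "seed": self.seed,
                "train_indices": list(self.train_indices),
                "test_indices": list(self.test_indices),
            }
        )


def _train_size(n: int, ratio: float) -> int:
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must lie strictly between 0 and 1")
    size = int(round(n * ratio))
    return min(max(size, 1), n - 1)


def random_split(n_or_ids, ratio: float = DEFAULT_TRAIN_RATIO, seed: int = 0) -> SplitResult:
    """Seeded uniform random partition."""
    n = n_or_ids if isinstance(n_or_ids, (int, np.integer)) else len(n_or_ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = _train_size(n, ratio)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitResult(
        tuple(sorted(int(i) for i in perm[:n_train])),
        tuple(sorted(int(i) for i in perm[n_train:])),
        "random",
        ratio,
        seed,
    )


def _ks_greedy(D: np.ndarray, n_train: int) -> list[int]:
    """Max–min greedy selection on a dense distance matrix.

    Ties break toward the lowest index (np.argmax returns the first
    maximizer, which is the lowest index).
    """
    n = D.shape[0]
    # seed pair: maximum distance, lowest (i, j) in row-major order on ties
    flat = np.argmax(D)
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    in_train = np.zeros(n, dtype=bool)
    in_train[selected] = True
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_train:
        min_dist[in_train] = -np.inf
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        in_train[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])
    return selected


def ks_split(X: np.ndarray, ratio: float = DEFAULT_TRAIN_RATIO) -> SplitResult:
    """Deterministic Kennard–Stone partition on Euclidean distances in X."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = max(_train_size(n, ratio), 2)
    D = squareform(pdist(X, metric="euclidean"))
    selected = _ks_greedy(D, n_train)
    rest = sorted(set(range(n)) - set(selected))
    return SplitResult(tuple(sorted(selected)), tuple(rest), "ks", ratio)


def spxy_split(
    X: np.ndarray, y: np.ndarray, ratio: float = DEFAULT_TRAIN_RATIO
) -> SplitResult:
    """SPXY partition: KS greedy on normalized-sum x/y distances.

    A constant y makes the y-distance degenerate; the split then falls
    back to plain Kennard–Stone on X with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise ValueError("y must align with the rows of X")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    Dy = squareform(pdist(y[:, None], metric="euclidean"))
    if Dy.max() == 0.0:
        warnings.warn("constant y: SPXY falls back to Kennard–Stone on X",
                      stacklevel=2)
        result = ks_split(X, ratio)
        return SplitResult(result.train_indices, result.test_indices, "spxy", ratio)
    Dx = squareform(pdist(X, metric="euclidean"))
    if Dx.max() == 0.0:
        raise ValueError("all spectra identical: SPXY distance undefined")
    D = Dx / Dx.max() + Dy / Dy.max()
    n_train = max(_train_size(n, ratio), 2)
    selected = _ks_greedy(D, n_train)
    rest = sorted(set(range(n)) - set(selected))
    return SplitResult(tuple(sorted(selected)), tuple(rest), "spxy", ratio)


def ks_selection_order(X: np.ndarray, n_train: int) -> list[int]:
    """The greedy selection sequence itself (diagnostic / oracle hook)."""
    X = np.asarray(X, dtype=float)
    D = squareform(pdist(X, metric="euclidean"))
    return _ks_greedy(D, n_train)
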