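"""Spectral preprocessing: scatter correction, standardization, derivatives.

Six methods are available, named as chemometricians name them:

``msc``   multiplicative scatter correction — per-spectrum affine
          regression against a reference spectrum, then inversion;
``snv``   standard normal variate — per-spectrum standardization;
``norm``  per-spectrum min-max scaling to [0, 1];
``sg``    Savitzky–Golay smoothing;
``sg1``   Savitzky–Golay first derivative (per nm);
``sg2``   Savitzky–Golay second derivative (per nm²);
``none``  identity.

MSC is the only stateful method: its reference spectrum is frozen from
the set it is fitted on (by default the training-set mean) and reused to
transform later prediction sets, so no test statistics leak into the
transform.  All methods are deterministic and shape-preserving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .core import SpectraSet

__all__ = [
    "PreprocessSpec",
    "FittedPreprocessor",
    "apply_msc",
    "apply_snv",
    "apply_minmax_norm",
    "apply_unitnorm",
    "apply_savgol",
    "fit_preprocessor",
    "METHOD_NAMES",
]

METHOD_NAMES = ("none", "msc", "snv", "norm", "sg", "sg1", "sg2")


@dataclass(frozen=True)
class PreprocessSpec:
    """Declarative description of a preprocessing chain.

    ``method`` is a single method name; ``chain`` (if given) is an ordered
    list of method names applied left to right, overriding ``method``.
    """

    method: str = "none"
    sg_window: int = 11
    sg_polyorder: int = 2
    chain: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHOD_NAMES:
                raise ValueError(f"unknown preprocessing method {m!r}")
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be smaller than sg_window")

    @property
    def methods(self) -> tuple[str, ...]:
        return self.chain if self.chain is not None else (self.method,)

    @property
    def label(self) -> str:
        names = {"sg1": "SG-1st", "sg2": "SG-2nd", "msc": "MSC", "snv": "SNV",
                 "norm": "Nor", "sg": "SG", "none": "none"}
        return "+".join(names[m] for m in self.methods)


def _msc_correct(
    X: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit of each row as a + b·reference, then invert.

    Rows with fitted b == 0 (constant spectra) are passed through with a
    warning rather than dividing by zero.
    """
    ref = reference - reference.mean()
    denom = float(ref @ ref)
    if denom == 0.0:
        raise ValueError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref / denom
    a = X.mean(axis=1) - b * reference.mean()
    out = np.empty_like(X, dtype=float)
    degenerate = b == 0.0
    if degenerate.any():
        warnings.warn(
            f"MSC: {int(degenerate.sum())} constant spectra passed through "
            "uncorrected (fitted slope b = 0)",
            stacklevel=3,
        )
        out[degenerate] = X[degenerate]
    ok = ~degenerate
    out[ok] = (X[ok] - a[ok, None]) / b[ok, None]
    return out, a, b


def apply_msc(
    spectra: SpectraSet, reference: np.ndarray | None = None
) -> SpectraSet:
    """Multiplicative scatter correction against ``reference``.

    When ``reference`` is absent it defaults to the mean spectrum of the
    set itself (which then requires at least two samples).
    """
    if reference is None:
        if spectra.n_samples < 2:
            raise ValueError("MSC without an explicit reference needs >= 2 samples")
        reference = spectra.absorbance.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (spectra.n_channels,):
        raise ValueError("reference spectrum length must match channel count")
    corrected, _, _ = _msc_correct(spectra.absorbance, reference)
    return spectra.with_absorbance(corrected)


def apply_snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-spectrum (x − mean) / sd, sd with n−1."""
    X = spectra.absorbance
    sd = X.std(axis=1, ddof=1)
    zero = sd == 0.0
    if zero.any():
        bad = spectra.sample_ids[zero][0]
        raise ValueError(f"SNV undefined for zero-variance spectrum {bad!r}")
    return spectra.with_absorbance((X - X.mean(axis=1, keepdims=True)) / sd[:, None])


def apply_minmax_norm(spectra: SpectraSet) -> SpectraSet:
    """Per-spectrum min-max scaling to [0, 1]."""
    X = spectra.absorbance
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    if np.any(span == 0.0):
        bad = spectra.sample_ids[(span == 0.0).ravel()][0]
        raise ValueError(f"min-max normalization undefined for constant spectrum {bad!r}")
    return spectra.with_absorbance((X - lo) / span)


def apply_unitnorm(spectra: SpectraSet) -> SpectraSet:
    """Per-spectrum scaling to unit Euclidean norm (alternative 'norm')."""
    X = spectra.absorbance
    nrm = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(nrm == 0.0):
        raise ValueError("unit-norm scaling undefined for an all-zero spectrum")
    return spectra.with_absorbance(X / nrm)


def apply_savgol(
    spectra: SpectraSet, window: int = 11, polyorder: int = 2, deriv: int = 0
) -> SpectraSet:
    """Savitzky–Golay smoothing / derivative along the wavelength axis.

    Derivatives are scaled by the wavelength step, so ``deriv=1`` output is
    absorbance per nm.  Edges are handled by fitting the edge polynomial
    (``mode="interp"``), keeping the output length equal to the input.
    """
    if window % 2 == 0:
        raise ValueError("Savitzky–Golay window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than the window")
    if deriv > polyorder:
        raise ValueError("derivative order must not exceed polyorder")
    if window > spectra.n_channels:
        raise ValueError("window larger than the number of channels")
    step = float(np.diff(spectra.wavelengths_nm).mean()) if spectra.n_channels > 1 else 1.0
    out = savgol_filter(
        spectra.absorbance, window, polyorder, deriv=deriv, delta=step,
        axis=1, mode="interp",
    )
    return spectra.with_absorbance(out)


@dataclass
class FittedPreprocessor:
    """A preprocessing chain with its training statistics frozen.

    Stateless methods are applied as-is; MSC stores the reference spectrum
    seen at fit time.  ``transform`` may be called on any later set with
    the same wavelength axis and is deterministic.
    """

    spec: PreprocessSpec
    msc_references: dict[int, np.ndarray] = field(default_factory=dict)

    def _apply_single(self, spectra: SpectraSet, pos: int) -> SpectraSet:
        m = self.spec.methods[pos]
        w, k = self.spec.sg_window, self.spec.sg_polyorder
        if m == "none":
            return spectra
        if m == "msc":
            return apply_msc(spectra, self.msc_references[pos])
        if m == "snv":
            return apply_snv(spectra)
        if m == "norm":
            return apply_minmax_norm(spectra)
        if m == "sg":
            return apply_savgol(spectra, w, k, 0)
        if m == "sg1":
            return apply_savgol(spectra, w, k, 1)
        if m == "sg2":
            return apply_savgol(spectra, w, max(k, 2), 2)
        raise ValueError(m)

    def transform(self, spectra: SpectraSet) -> SpectraSet:
        out = spectra
        for pos in range(len(self.spec.methods)):
            out = self._apply_single(out, pos)
        return out


def fit_preprocessor(spec: PreprocessSpec, spectra: SpectraSet) -> FittedPreprocessor:
    """Freeze the chain's statistics (MSC references) on ``spectra``."""
    fitted = FittedPreprocessor(spec)
    out = spectra
    for pos, m in enumerate(spec.methods):
        if m == "msc":
            fitted.msc_references[pos] = out.absorbance.mean(axis=0)
        out = fitted._apply_single(out, pos)
    return fitted
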