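"""Core data containers shared by every pipeline stage.

A :class:`SpectraSet` holds an absorbance matrix with its wavelength axis
and per-sample storage metadata; a :class:`ReferenceTable` holds the
wet-chemistry reference values (texture rebound, TVB-N) aligned to the
same sample ids.  Every stage of the calibration chain consumes and
returns these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "ReferenceTable", "TVBN_FRESHNESS_LIMIT_MG_PER_100G"]

#: Regulatory first-grade freshness bound for chilled meat (mg TVB-N / 100 g).
TVBN_FRESHNESS_LIMIT_MG_PER_100G = 15.0


@dataclass
class SpectraSet:
    """Absorbance spectra for a set of samples.

    Parameters
    ----------
    absorbance
        ``(n_samples, n_channels)`` matrix of absorbance values.
    wavelengths_nm
        Strictly increasing wavelength axis, length ``n_channels``.
    sample_ids
        One id per row; must be unique.
    metadata
        Optional per-sample frame (``group``, ``day``, ``temperature_C``)
        indexed by sample id.
    """

    absorbance: np.ndarray
    wavelengths_nm: np.ndarray
    sample_ids: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D (samples x channels) matrix")
        n, p = self.absorbance.shape
        if self.wavelengths_nm.shape != (p,):
            raise ValueError(
                f"wavelength axis length {self.wavelengths_nm.size} does not match "
                f"{p} spectral channels"
            )
        if p >= 2 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if self.sample_ids.shape != (n,):
            raise ValueError("one sample_id per spectrum is required")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise ValueError(
                f"non-finite absorbance at sample {self.sample_ids[bad[0]]!r}, "
                f"wavelength {self.wavelengths_nm[bad[1]]} nm"
            )
        if self.metadata is not None:
            missing = [s for s in self.sample_ids if s not in self.metadata.index]
            if missing:
                raise ValueError(f"metadata missing sample ids: {missing[:5]}")
            self.metadata = self.metadata.loc[list(self.sample_ids)]

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.absorbance.copy(),
            self.wavelengths_nm.copy(),
            self.sample_ids.copy(),
            None if self.metadata is None else self.metadata.copy(),
        )

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Same samples and axis, new absorbance matrix (shape-checked)."""
        return SpectraSet(
            np.asarray(absorbance, dtype=float),
            self.wavelengths_nm.copy(),
            self.sample_ids.copy(),
            None if self.metadata is None else self.metadata.copy(),
        )

    def select_samples(self, ids) -> "SpectraSet":
        """Row subset by sample id, preserving the given order."""
        idx = self._indices_of(ids)
        return SpectraSet(
            self.absorbance[idx],
            self.wavelengths_nm.copy(),
            self.sample_ids[idx],
            None if self.metadata is None else self.metadata.iloc[idx].copy(),
        )

    def select_channels(self, channel_indices) -> "SpectraSet":
        idx = np.asarray(channel_indices, dtype=int)
        return SpectraSet(
            self.absorbance[:, idx],
            self.wavelengths_nm[idx],
            self.sample_ids.copy(),
            None if self.metadata is None else self.metadata.copy(),
        )

    def _indices_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None


@dataclass
class ReferenceTable:
    """Per-sample reference values aligned to a :class:`SpectraSet`.

    ``table`` is indexed by sample id with numeric columns, by convention
    ``rebound`` (unitless, from texture profile analysis) and ``tvbn``
    (mg / 100 g).
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in reference table")

    @property
    def sample_ids(self) -> np.ndarray:
        return np.asarray(self.table.index, dtype=object)

    def values_for(self, target: str, ids) -> np.ndarray:
        """Reference values of ``target`` for ``ids``, in that order."""
        if target not in self.table.columns:
            raise KeyError(
                f"target {target!r} not in reference table "
                f"(have {list(self.table.columns)})"
            )
        sub = self.table.loc[list(ids), target]
        if sub.isna().any():
            raise ValueError(f"missing {target!r} values for some samples")
        return sub.to_numpy(dtype=float)

    def select_samples(self, ids) -> "ReferenceTable":
        return ReferenceTable(self.table.loc[list(ids)].copy())

    def copy(self) -> "ReferenceTable":
        return ReferenceTable(self.table.copy())
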