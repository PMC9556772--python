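"""Core in-memory containers for drug-response and lesion data.

All three containers wrap a pandas DataFrame so that downstream code can
rely on labelled, order-stable axes:

* :class:`ResponseMatrix` — drugs x patients, IC50 in µM on (0, 10],
  ``NaN`` marks a missing measurement;
* :class:`NormalizedMatrix` — drugs x patients IC50* scores (dimensionless,
  log10-µM scale), complete, every value <= 0 with a per-drug maximum of 0;
* :class:`LesionMatrix` — binary lesions x patients carrier status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix", "NormalizedMatrix", "LesionMatrix"]

#: numeric tolerance for the "per-drug maximum is exactly 0" invariant
_ROWMAX_TOL = 1e-9


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class ResponseMatrix:
    """Drug-response screen: IC50 (µM) per (drug, patient), NaN = missing."""

    values: pd.DataFrame  # rows = drugs, columns = patients

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "drug")
        _check_unique(self.values.columns, "patient")
        vals = self.values.to_numpy(dtype=float)
        bad = vals[np.isfinite(vals) & (vals <= 0)]
        if bad.size:
            raise ValueError(f"IC50 values must be > 0 µM; found {bad.min()!r}")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(self.values.copy())


@dataclass
class NormalizedMatrix:
    """IC50* scores: complete, all <= 0.

    The normalization step additionally guarantees a per-drug row maximum
    of exactly 0; the container itself only demands non-positive scores so
    that sub-cohorts and externally supplied score matrices remain valid
    optimization inputs.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "drug")
        _check_unique(self.values.columns, "patient")
        vals = self.values.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("IC50* matrix must not contain missing values")
        if vals.size and vals.max() > _ROWMAX_TOL:
            raise ValueError("IC50* values must all be <= 0")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]


@dataclass
class LesionMatrix:
    """Binary lesion carrier status: rows = lesions, columns = patients."""

    status: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.status.index, "lesion")
        _check_unique(self.status.columns, "patient")
        vals = self.status.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("lesion status must be strictly 0/1")
        self.status = self.status.astype(np.int8)

    @property
    def lesion_ids(self) -> list[str]:
        return list(self.status.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.status.columns)

    @property
    def prevalence(self) -> pd.Series:
        """Carrier count per lesion."""
        return self.status.sum(axis=1)

    @property
    def n_patients(self) -> int:
        return self.status.shape[1]

    def carriers(self, lesion_id: str) -> list[str]:
        row = self.status.loc[lesion_id]
        return list(row.index[row.to_numpy() == 1])
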