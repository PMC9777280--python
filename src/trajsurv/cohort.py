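"""Data model for two-time-step clinical cohorts.

A cohort couples a patient-by-column covariate matrix with right-censored
survival outcomes.  Covariates are either *invariant* (measured once, e.g.
age) or *time-varying* (measured at hospital admission and again at
discharge, e.g. heart rate).  Time-varying covariates occupy two columns,
``<name>_A`` (admission) and ``<name>_D`` (discharge).  Missing values are
carried in an explicit boolean mask, never as sentinel numbers.

Follow-up time is measured in months from discharge; ``event`` is 1 for
death during follow-up and 0 for censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSpec",
    "CohortTable",
    "SchemaError",
    "CohortParseError",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_schema",
    "write_schema",
    "temporal_split",
    "expand_time_varying",
]

CONTINUOUS = "continuous"
BINARY = "binary"
INVARIANT = "invariant"
TIME_VARYING = "time_varying"

ADMISSION_SUFFIX = "_A"
DISCHARGE_SUFFIX = "_D"


class SchemaError(ValueError):
    """A CSV or cohort does not match the declared covariate schema."""


class CohortParseError(ValueError):
    """A cell in the CSV could not be interpreted as a number."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of one clinical covariate.

    Parameters
    ----------
    name : str
        Unique covariate name (e.g. ``"age"``, ``"HR"``).
    kind : {"continuous", "binary"}
        Binary covariates are stored as 0/1 reals.
    timing : {"invariant", "time_varying"}
        Time-varying covariates have exactly two measurement slots,
        admission and discharge.
    """

    name: str
    kind: str = CONTINUOUS
    timing: str = INVARIANT

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.timing not in (INVARIANT, TIME_VARYING):
            raise ValueError(f"unknown covariate timing {self.timing!r}")

    @property
    def columns(self) -> list[str]:
        """Column labels this covariate occupies in a cohort matrix."""
        if self.timing == TIME_VARYING:
            return [self.name + ADMISSION_SUFFIX, self.name + DISCHARGE_SUFFIX]
        return [self.name]


def _columns_for(specs: Sequence[CovariateSpec]) -> list[str]:
    cols: list[str] = []
    for s in specs:
        cols.extend(s.columns)
    return cols


@dataclass
class CohortTable:
    """Patients x (covariate, slot) matrix with survival outcomes.

    Attributes
    ----------
    specs : list of CovariateSpec
        Covariate declarations; column order follows this list, with a
        time-varying covariate contributing ``_A`` then ``_D``.
    values : ndarray, shape (n_patients, n_columns)
        Covariate values; entries under the mask are meaningless.
    mask : ndarray of bool, same shape
        True marks a missing cell.
    time : ndarray, shape (n_patients,)
        Follow-up in months, non-negative.
    event : ndarray of int, shape (n_patients,)
        1 = death observed, 0 = censored.
    patient_ids : ndarray of str
    admission_date : ndarray of datetime64[D] or None
        Optional, needed only for temporal splitting.
    """

    specs: list[CovariateSpec]
    values: np.ndarray
    mask: np.ndarray
    time: np.ndarray
    event: np.ndarray
    patient_ids: np.ndarray
    admission_date: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        n = self.values.shape[0] if self.values.ndim == 2 else 0
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SchemaError("covariate names must be unique")
        ncol = len(self.columns)
        if self.values.shape[1] != ncol:
            raise SchemaError(
                f"values has {self.values.shape[1]} columns, schema declares {ncol}"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        for arr, what in ((self.time, "time"), (self.event, "event"),
                          (self.patient_ids, "patient_ids")):
            if arr.shape != (n,):
                raise ValueError(f"{what} length must equal patient count {n}")
        if np.any(self.time < 0):
            raise ValueError("follow-up times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if self.admission_date is not None:
            self.admission_date = np.asarray(self.admission_date, dtype="datetime64[D]")
            if self.admission_date.shape != (n,):
                raise ValueError("admission_date length must equal patient count")

    # -- basic introspection -------------------------------------------------

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def columns(self) -> list[str]:
        return _columns_for(self.specs)

    @property
    def covariate_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> CovariateSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def column_index(self, label: str) -> int:
        try:
            return self.columns.index(label)
        except ValueError:
            raise KeyError(f"no column {label!r} in cohort") from None

    def column_indices(self, spec: CovariateSpec) -> list[int]:
        return [self.column_index(c) for c in spec.columns]

    def column(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, missing-mask) for one column."""
        j = self.column_index(label)
        return self.values[:, j], self.mask[:, j]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    # -- derived tables ------------------------------------------------------

    def copy(self) -> "CohortTable":
        return CohortTable(
            specs=list(self.specs),
            values=self.values.copy(),
            mask=self.mask.copy(),
            time=self.time.copy(),
            event=self.event.copy(),
            patient_ids=self.patient_ids.copy(),
            admission_date=None if self.admission_date is None
            else self.admission_date.copy(),
        )

    def subset_rows(self, idx: np.ndarray) -> "CohortTable":
        idx = np.asarray(idx)
        return CohortTable(
            specs=list(self.specs),
            values=self.values[idx],
            mask=self.mask[idx],
            time=self.time[idx],
            event=self.event[idx],
            patient_ids=self.patient_ids[idx],
            admission_date=None if self.admission_date is None
            else self.admission_date[idx],
        )

    def select_covariates(self, names: Iterable[str]) -> "CohortTable":
        """Restrict to the named covariates, preserving schema order."""
        wanted = set(names)
        unknown = wanted - set(self.covariate_names)
        if unknown:
            raise KeyError(f"unknown covariates: {sorted(unknown)}")
        specs = [s for s in self.specs if s.name in wanted]
        cols = [self.column_index(c) for s in specs for c in s.columns]
        return CohortTable(
            specs=specs,
            values=self.values[:, cols],
            mask=self.mask[:, cols],
            time=self.time,
            event=self.event,
            patient_ids=self.patient_ids,
            admission_date=self.admission_date,
        )

    def drop_covariates(self, names: Iterable[str]) -> "CohortTable":
        drop = set(names)
        return self.select_covariates([n for n in self.covariate_names if n not in drop])

    def complete_values(self) -> np.ndarray:
        """Covariate matrix, raising if any cell is missing."""
        if self.mask.any():
            bad = [self.columns[j] for j in np.unique(np.where(self.mask)[1])]
            raise ValueError(f"cohort has missing values in columns {bad}; impute first")
        return self.values

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df = df.mask(pd.DataFrame(self.mask, columns=self.columns))
        df.insert(0, "event", self.event)
        df.insert(0, "time", self.time)
        df.insert(0, "patient_id", self.patient_ids)
        if self.admission_date is not None:
            df["admission_date"] = self.admission_date
        return df


# -- CSV + schema I/O --------------------------------------------------------

def write_schema(specs: Sequence[CovariateSpec], path) -> None:
    """Write the covariate schema as a JSON sidecar file."""
    payload = [{"name": s.name, "kind": s.kind, "timing": s.timing} for s in specs]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_schema(path) -> list[CovariateSpec]:
    with open(path) as fh:
        payload = json.load(fh)
    return [CovariateSpec(**entry) for entry in payload]


def read_cohort_csv(path, schema: Sequence[CovariateSpec]) -> CohortTable:
    """Read a cohort CSV against a declared schema.

    The CSV must have one row per patient with columns ``time``, ``event``,
    one column per invariant covariate, and ``<name>_A`` / ``<name>_D`` per
    time-varying covariate.  Empty cells denote missing values.  Optional
    columns ``patient_id`` and ``admission_date`` are honoured.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    needed = ["time", "event"] + _columns_for(schema)
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"CSV is missing mandatory column {col!r}")

    n = len(df)

    def numeric(col: str, allow_empty: bool) -> tuple[np.ndarray, np.ndarray]:
        raw = df[col].str.strip()
        empty = raw == ""
        if empty.any() and not allow_empty:
            row = int(np.flatnonzero(empty.to_numpy())[0])
            raise CohortParseError(f"column {col!r} empty at row {row}")
        out = np.full(n, np.nan)
        nonempty = ~empty
        try:
            out[nonempty.to_numpy()] = raw[nonempty].astype(float).to_numpy()
        except ValueError:
            for i, (v, e) in enumerate(zip(raw, empty)):
                if not e:
                    try:
                        float(v)
                    except ValueError:
                        raise CohortParseError(
                            f"non-numeric value {v!r} in column {col!r} at row {i}"
                        ) from None
            raise
        return out, empty.to_numpy()

    time, _ = numeric("time", allow_empty=False)
    event, _ = numeric("event", allow_empty=False)
    cols = _columns_for(schema)
    values = np.empty((n, len(cols)))
    mask = np.zeros((n, len(cols)), dtype=bool)
    for j, col in enumerate(cols):
        values[:, j], mask[:, j] = numeric(col, allow_empty=True)
    values[mask] = 0.0

    if "patient_id" in df.columns:
        ids = df["patient_id"].to_numpy(dtype=object)
    else:
        ids = np.array([f"P{i:05d}" for i in range(n)], dtype=object)
    dates = None
    if "admission_date" in df.columns:
        raw = df["admission_date"].str.strip()
        empty = raw == ""
        if empty.all():
            dates = None
        elif empty.any():
            rows = np.flatnonzero(empty.to_numpy()).tolist()
            raise CohortParseError(f"admission_date empty at rows {rows}")
        else:
            dates = raw.to_numpy().astype("datetime64[D]")

    return CohortTable(
        specs=list(schema), values=values, mask=mask,
        time=time, event=event.astype(int), patient_ids=ids,
        admission_date=dates,
    )


def write_cohort_csv(cohort: CohortTable, path):
    """Write a cohort in the CSV dialect accepted by :func:`read_cohort_csv`.

    Missing covariate cells become empty fields; round-tripping through
    :func:`read_cohort_csv` reproduces values, mask and outcomes exactly.
    """
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, na_rep="")
    return path


# -- structural transforms ---------------------------------------------------

def temporal_split(cohort: CohortTable, cutoff_date) -> tuple[CohortTable, CohortTable]:
    """Partition a cohort by admission date.

    Patients admitted strictly before ``cutoff_date`` form the development
    table; those admitted on or after it form the (temporal) validation
    table.
    """
    if cohort.admission_date is None:
        raise ValueError(
            "temporal_split requires admission dates for every patient; "
            f"all {cohort.n_patients} patients lack one"
        )
    cutoff = np.datetime64(cutoff_date, "D")
    before = cohort.admission_date < cutoff
    return cohort.subset_rows(np.flatnonzero(before)), \
        cohort.subset_rows(np.flatnonzero(~before))


def expand_time_varying(cohort: CohortTable) -> CohortTable:
    """Flatten time-varying covariates into independent invariant columns.

    Each time-varying covariate ``x`` becomes two invariant covariates
    ``x_A`` and ``x_D``; values and missingness are untouched.  This is the
    data view consumed by static models (the feed-forward network and the
    Cox model), which cannot represent temporal structure themselves.
    """
    new_specs: list[CovariateSpec] = []
    for s in cohort.specs:
        if s.timing == TIME_VARYING:
            new_specs.append(CovariateSpec(s.name + ADMISSION_SUFFIX, s.kind, INVARIANT))
            new_specs.append(CovariateSpec(s.name + DISCHARGE_SUFFIX, s.kind, INVARIANT))
        else:
            new_specs.append(s)
    return replace(cohort.copy(), specs=new_specs)
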