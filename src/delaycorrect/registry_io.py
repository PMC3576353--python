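"""Reading, cleaning and windowing of rare-disease registry tables.

A registry extract is one row per registration with a patient identifier, a
(suspected) onset date and a diagnosis date, plus optional stratification
columns (region, gender, age group). This module turns such a table into the
right-truncated delay sample consumed by the estimation code: delays
``t_i = diagnosis - onset`` in whole days, paired with truncation horizons
``tau_i = t_end - onset`` where ``t_end`` is the archive-closure date. A case
is observable only if its diagnosis occurred by ``t_end``, i.e. ``t_i <=
tau_i``; cases with longer delays are entirely absent from the registry
(right truncation, not censoring).

The canonical in-memory container for raw records is a :class:`pandas.DataFrame`
with the columns listed in :data:`REQUIRED_COLUMNS` / :data:`OPTIONAL_COLUMNS`;
:class:`RegistryRecord` is a row-wise convenience view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DataError

__all__ = [
    "AGE_GROUPS",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "DEFAULT_T_END",
    "DEFAULT_MIN_DIAGNOSIS_YEAR",
    "RegistryRecord",
    "TruncatedDelaySample",
    "load_registry",
    "deduplicate",
    "build_truncated_sample",
    "assign_onset_cohort",
    "cohort_label",
]

#: Age-at-onset classes used for stratified analyses.
AGE_GROUPS = ("0-17", "18-48", "49-64", "65-74", "75+")

REQUIRED_COLUMNS = ("patient_id", "onset_date", "diagnosis_date")
OPTIONAL_COLUMNS = ("region", "gender", "age_group")

#: Archive closure of the registry extract the defaults emulate (21 Dec 2009).
DEFAULT_T_END = pd.Timestamp("2009-12-21")
#: Diagnoses before this year are dropped by default (registry quality cutoff).
DEFAULT_MIN_DIAGNOSIS_YEAR = 1993


class RegistryRecord(NamedTuple):
    """One cleaned registry case."""

    patient_id: str
    onset_date: pd.Timestamp
    diagnosis_date: pd.Timestamp
    region: str | None = None
    gender: str | None = None
    age_group: str | None = None


@dataclass
class TruncatedDelaySample:
    """Paired delays and truncation horizons, with multiplicities.

    Parameters
    ----------
    t : ndarray of int
        Delay to diagnosis in whole days, ``>= 0``.
    tau : ndarray of int
        Truncation horizon ``t_end - onset`` in whole days. The truncation
        condition ``t <= tau`` must hold for every unit.
    n : ndarray of int, optional
        Multiplicities (units sharing the same delay/horizon); default all 1.
    stratum : ndarray, optional
        Per-unit stratum label.
    t_end : pandas.Timestamp, optional
        Archive-closure date the horizons were computed against.
    """

    t: np.ndarray
    tau: np.ndarray
    n: np.ndarray | None = None
    stratum: np.ndarray | None = None
    t_end: pd.Timestamp | None = field(default=None)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.tau = np.asarray(self.tau, dtype=np.int64)
        if self.t.ndim != 1 or self.tau.shape != self.t.shape:
            raise ConfigurationError("t and tau must be 1-d arrays of equal length")
        if self.n is None:
            self.n = np.ones_like(self.t)
        else:
            self.n = np.asarray(self.n, dtype=np.int64)
            if self.n.shape != self.t.shape:
                raise ConfigurationError("multiplicities must match t in shape")
            if np.any(self.n < 1):
                raise DataError("multiplicities must be positive integers")
        if np.any(self.t < 0):
            raise DataError("negative delay: diagnosis precedes onset")
        if np.any(self.t > self.tau):
            bad = int(np.argmax(self.t > self.tau))
            raise DataError(
                f"truncation violated at unit {bad}: t={self.t[bad]} > tau={self.tau[bad]}"
            )
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum, dtype=object)
            if self.stratum.shape != self.t.shape:
                raise ConfigurationError("stratum labels must match t in shape")
        if self.t_end is not None:
            self.t_end = pd.Timestamp(self.t_end)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def tau_star(self) -> int:
        """Largest horizon, the upper end of the identifiable time range."""
        return int(self.tau.max()) if len(self.t) else 0

    @property
    def n_total(self) -> int:
        """Number of units counting multiplicities."""
        return int(self.n.sum())

    def expanded(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit-level ``(t, tau)`` arrays with multiplicities unrolled."""
        return np.repeat(self.t, self.n), np.repeat(self.tau, self.n)

    def subset(self, mask: np.ndarray) -> "TruncatedDelaySample":
        return TruncatedDelaySample(
            t=self.t[mask],
            tau=self.tau[mask],
            n=self.n[mask],
            stratum=None if self.stratum is None else self.stratum[mask],
            t_end=self.t_end,
        )


def _parse_dates(series: pd.Series, date_format: str | None) -> pd.Series:
    return pd.to_datetime(series, format=date_format, errors="coerce")


def load_registry(
    path,
    date_format: str = "%Y-%m-%d",
) -> tuple[pd.DataFrame, dict]:
    """Read a registry CSV, dropping rows with unusable dates.

    Rows whose onset or diagnosis date is missing or does not parse under
    ``date_format`` are dropped, as are rows with a diagnosis before the
    onset; counts by reason are returned in the exclusion report.

    Returns
    -------
    records : DataFrame
        Parsed records with ``onset_date`` / ``diagnosis_date`` as datetimes.
    report : dict
        ``{"n_input", "n_retained", "excluded": {reason: count}}``.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"registry file missing required column(s): {missing}")
    if raw.empty:
        warnings.warn("registry file contains no records", stacklevel=2)

    df = raw.copy()
    df["onset_date"] = _parse_dates(df["onset_date"], date_format)
    df["diagnosis_date"] = _parse_dates(df["diagnosis_date"], date_format)

    excluded: dict[str, int] = {}
    bad_onset = df["onset_date"].isna()
    bad_diag = df["diagnosis_date"].isna()
    excluded["missing_or_unparseable_onset"] = int(bad_onset.sum())
    excluded["missing_or_unparseable_diagnosis"] = int((bad_diag & ~bad_onset).sum())
    df = df[~(bad_onset | bad_diag)]
    negative = df["diagnosis_date"] < df["onset_date"]
    excluded["diagnosis_before_onset"] = int(negative.sum())
    df = df[~negative]

    if "age_group" in df.columns:
        bad_age = df["age_group"].notna() & ~df["age_group"].isin(AGE_GROUPS)
        if bad_age.any():
            excluded["invalid_age_group_blanked"] = int(bad_age.sum())
            df.loc[bad_age, "age_group"] = pd.NA

    report = {
        "n_input": int(len(raw)),
        "n_retained": int(len(df)),
        "excluded": {k: v for k, v in excluded.items() if v},
    }
    return df.reset_index(drop=True), report


def deduplicate(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse repeat registrations, keeping the earliest diagnosis per patient.

    A patient registered in two presidiums or regions appears twice; only the
    first (least recent) diagnosis is retained. Ties on the diagnosis date are
    broken by stable input order. Idempotent.

    Returns ``(deduplicated, removed)`` with original row order preserved.
    """
    ordered = records.sort_values("diagnosis_date", kind="stable")
    keep_mask = ~ordered.duplicated("patient_id", keep="first")
    keep_idx = ordered.index[keep_mask]
    kept = records.loc[records.index.isin(keep_idx)]
    removed = records.loc[~records.index.isin(keep_idx)]
    return kept.reset_index(drop=True), removed.reset_index(drop=True)


def build_truncated_sample(
    records: pd.DataFrame,
    t_end=DEFAULT_T_END,
    min_diagnosis_year: int = DEFAULT_MIN_DIAGNOSIS_YEAR,
    cohort_window: tuple | None = None,
    stratum_col: str | None = None,
) -> TruncatedDelaySample:
    """Derive the right-truncated delay sample from cleaned records.

    Parameters
    ----------
    records : DataFrame
        Cleaned (deduplicated) registry records.
    t_end : date-like
        Archive-closure date; every retained diagnosis must be on or before it.
    min_diagnosis_year : int
        Records diagnosed in an earlier calendar year are excluded.
    cohort_window : (date-like, date-like), optional
        If given, only records with onset inside the closed interval are kept.
    stratum_col : str, optional
        Column carried into the sample as per-unit stratum label.
    """
    t_end = pd.Timestamp(t_end)
    df = records
    late = df["diagnosis_date"] > t_end
    if late.any():
        raise DataError(
            f"{int(late.sum())} record(s) have a diagnosis after t_end={t_end.date()}; "
            "such cases could not have been registered"
        )
    df = df[df["diagnosis_date"].dt.year >= min_diagnosis_year]
    if cohort_window is not None:
        lo, hi = (pd.Timestamp(cohort_window[0]), pd.Timestamp(cohort_window[1]))
        df = df[(df["onset_date"] >= lo) & (df["onset_date"] <= hi)]
    t = (df["diagnosis_date"] - df["onset_date"]).dt.days.to_numpy()
    tau = (t_end - df["onset_date"]).dt.days.to_numpy()
    stratum = None
    if stratum_col is not None:
        if stratum_col not in df.columns:
            raise ConfigurationError(f"stratum column {stratum_col!r} not present")
        stratum = df[stratum_col].to_numpy(dtype=object)
    return TruncatedDelaySample(t=t, tau=tau, stratum=stratum, t_end=t_end)


def cohort_label(start_year: int, end_year: int) -> str:
    """Label a cohort of onset years, e.g. ``(2001, 2003) -> '2001-03'``."""
    return f"{start_year}-{end_year % 100:02d}"


def assign_onset_cohort(
    records: pd.DataFrame,
    cohort_breaks: Sequence[tuple[int, int]] = ((2001, 2003), (2004, 2006), (2007, 2009)),
    other_label: str = "other",
) -> pd.DataFrame:
    """Label each record with the onset cohort containing its onset year.

    ``cohort_breaks`` are closed year ranges which must not overlap; records
    outside every range get ``other_label``. Returns a copy with an
    ``onset_cohort`` column.
    """
    ranges = sorted(cohort_breaks)
    for lo, hi in ranges:
        if hi < lo:
            raise ConfigurationError(f"cohort range {(lo, hi)} has end before start")
    for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
        if b0 <= a1:
            raise ConfigurationError(f"overlapping cohort ranges {(a0, a1)} and {(b0, b1)}")
    out = records.copy()
    years = out["onset_date"].dt.year
    labels = pd.Series(other_label, index=out.index, dtype=object)
    for lo, hi in ranges:
        labels[(years >= lo) & (years <= hi)] = cohort_label(lo, hi)
    out["onset_cohort"] = labels
    return out
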