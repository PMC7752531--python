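"""CSV readers/writers for rosters, weekly reports and the reference series.

All loaders validate eagerly and fail with row-numbered messages (row numbers
are 1-based data rows, header excluded).  Writers are exact inverses: a
write/load round trip reproduces the typed frame.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .datatypes import (
    BOOLEAN_FIELDS,
    CATEGORICAL_LEVELS,
    REFERENCE_COLUMNS,
    REPORT_COLUMNS,
    ROSTER_COLUMNS,
    SYMPTOM_COLUMNS,
)
from .studycalendar import StudyCalendar

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


class SchemaError(ValueError):
    """A CSV file does not match its documented schema."""


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _first_bad(mask: pd.Series):
    """1-based data-row number of the first True in a boolean mask, or None."""
    idx = np.flatnonzero(mask.to_numpy())
    return None if idx.size == 0 else int(idx[0]) + 1


def _parse_bool(series: pd.Series, column: str, path) -> pd.Series:
    low = series.str.strip().str.lower()
    bad = ~(low.isin(_TRUE) | low.isin(_FALSE))
    row = _first_bad(bad)
    if row is not None:
        raise SchemaError(
            f"{path}: row {row}: column {column!r} has unparseable boolean "
            f"{series.iloc[row - 1]!r}"
        )
    return low.isin(_TRUE)


def _parse_date(series: pd.Series, column: str, path) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    row = _first_bad(parsed.isna())
    if row is not None:
        raise SchemaError(
            f"{path}: row {row}: column {column!r} has unparseable date "
            f"{series.iloc[row - 1]!r}"
        )
    return parsed


def _parse_categorical(series: pd.Series, column: str, levels, path) -> pd.Series:
    bad = ~series.isin(levels)
    row = _first_bad(bad)
    if row is not None:
        raise SchemaError(
            f"{path}: row {row}: column {column!r} has unknown level "
            f"{series.iloc[row - 1]!r}; expected one of {tuple(levels)}"
        )
    return series


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def load_roster(path, calendar: StudyCalendar) -> pd.DataFrame:
    """Load a participant roster; adds derived enrollment/study-end weeks."""
    raw = _read_csv(path)
    _check_columns(raw, ROSTER_COLUMNS, path)
    df = pd.DataFrame({"participant_id": raw["participant_id"].astype(str)})
    for column, levels in CATEGORICAL_LEVELS.items():
        df[column] = _parse_categorical(raw[column], column, levels, path)
    for column in BOOLEAN_FIELDS:
        df[column] = _parse_bool(raw[column], column, path)
    for column in ("enrollment_date", "study_end_date"):
        df[column] = _parse_date(raw[column], column, path).dt.date
    if len(df):
        df["enrollment_week"] = [calendar.week_of(d) for d in df["enrollment_date"]]
        df["study_end_week"] = [calendar.week_of(d) for d in df["study_end_date"]]
        row = _first_bad(df["study_end_week"] <= df["enrollment_week"])
        if row is not None:
            raise SchemaError(
                f"{path}: row {row}: study_end_date does not follow enrollment_date"
            )
    else:
        df["enrollment_week"] = pd.Series([], dtype=int)
        df["study_end_week"] = pd.Series([], dtype=int)
    return df[list(ROSTER_COLUMNS) + ["enrollment_week", "study_end_week"]]


def write_roster(roster: pd.DataFrame, path) -> None:
    out = roster[list(ROSTER_COLUMNS)].copy()
    for column in BOOLEAN_FIELDS:
        out[column] = np.where(out[column], "true", "false")
    out.to_csv(path, index=False)


def load_reports(path, calendar: StudyCalendar) -> pd.DataFrame:
    """Load weekly symptom reports; derives the surveillance week and flags
    submissions timestamped inside the maintenance window (retained on load;
    downstream stages decide inclusion)."""
    raw = _read_csv(path)
    _check_columns(raw, REPORT_COLUMNS, path)
    df = pd.DataFrame({"participant_id": raw["participant_id"].astype(str)})
    submitted = pd.to_datetime(raw["submitted_at"], format="ISO8601", errors="coerce")
    row = _first_bad(submitted.isna())
    if row is not None:
        raise SchemaError(
            f"{path}: row {row}: column 'submitted_at' has unparseable timestamp "
            f"{raw['submitted_at'].iloc[row - 1]!r}"
        )
    df["submitted_at"] = submitted
    for column in SYMPTOM_COLUMNS:
        df[column] = _parse_bool(raw[column], column, path)
    df["week"] = (
        [calendar.week_of(t) for t in df["submitted_at"]] if len(df) else
        pd.Series([], dtype=int)
    )
    df["in_maintenance"] = df["week"].isin(calendar.maintenance_weeks)
    return df


def write_reports(reports: pd.DataFrame, path) -> None:
    out = reports[list(REPORT_COLUMNS)].copy()
    out["submitted_at"] = pd.to_datetime(out["submitted_at"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    for column in SYMPTOM_COLUMNS:
        out[column] = np.where(out[column], "true", "false")
    out.to_csv(path, index=False)


def load_reference(path, calendar: StudyCalendar) -> pd.DataFrame:
    """Load the sentinel (reference) weekly ILI series.

    The week-start dates need not match the configured convention exactly;
    each date is assigned to the surveillance week containing it.
    """
    raw = _read_csv(path)
    _check_columns(raw, REFERENCE_COLUMNS, path)
    dates = _parse_date(raw["week_start_date"], "week_start_date", path).dt.date
    probe = pd.to_numeric(raw["ili_pct"], errors="coerce")
    row = _first_bad(probe.isna())
    if row is not None:
        raise SchemaError(
            f"{path}: row {row}: column 'ili_pct' has unparseable value "
            f"{raw['ili_pct'].iloc[row - 1]!r}"
        )
    # astype is correctly rounded (to_numeric is not), keeping round trips exact
    pct = raw["ili_pct"].astype(float)
    row = _first_bad((pct < 0) | (pct > 100))
    if row is not None:
        raise SchemaError(
            f"{path}: row {row}: ili_pct {pct.iloc[row - 1]} outside [0, 100]"
        )
    weeks = pd.Series([calendar.week_of(d) for d in dates], dtype=int)
    if len(weeks) > 1:
        row = _first_bad(weeks.diff().fillna(1) <= 0)
        if row is not None:
            raise SchemaError(
                f"{path}: row {row}: weeks must be strictly increasing with no "
                f"duplicates"
            )
    return pd.DataFrame({"week": weeks, "ili_pct": pct.astype(float)})


def write_reference(reference: pd.DataFrame, path, calendar: StudyCalendar) -> None:
    out = pd.DataFrame(
        {
            "week_start_date": [
                calendar.week_start_date(w).isoformat() for w in reference["week"]
            ],
            "ili_pct": reference["ili_pct"].to_numpy(),
        }
    )
    # shortest round-trip repr so write/load reproduces every float exactly
    out.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
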