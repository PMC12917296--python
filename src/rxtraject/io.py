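"""Reading, validation and normalisation of dispensing and patient tables.

Canonical on-disk format is plain CSV with ISO-8601 dates:

* dispensing table: ``patient_id,date,atc,strength_mg,units,days_supplied``
* patient table:    ``patient_id,birth_date,sex``
* labels table (simulation ground truth): written by :mod:`rxtraject.simulate`

Internally every date is also carried as an integer day offset (days since
1970-01-01, column ``day`` / ``birth_day``); all intervals in the package are
half-open ``[start, end)`` on that day grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DISPENSING_COLUMNS = ["patient_id", "date", "atc", "strength_mg", "units", "days_supplied"]
PATIENT_COLUMNS = ["patient_id", "birth_date", "sex"]

_EPOCH = np.datetime64("1970-01-01", "D")


class SchemaError(ValueError):
    """A required column is missing or a row violates a field invariant."""


def to_day(dates) -> np.ndarray:
    """Convert datetimes (or ISO strings) to integer days since 1970-01-01."""
    arr = pd.to_datetime(pd.Series(dates)).to_numpy().astype("datetime64[D]")
    return (arr - _EPOCH).astype(np.int64)


def from_day(days) -> pd.Series:
    return pd.Series(pd.to_datetime(np.asarray(days, dtype=np.int64), unit="D"))


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def _parse_dates(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df[col].notna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # header = line 1
        raise SchemaError(f"unparseable {col} in {what} at line(s) {lines[:20]}")
    if parsed.isna().any():
        lines = (np.flatnonzero(parsed.isna().to_numpy()) + 2).tolist()
        raise SchemaError(f"missing {col} in {what} at line(s) {lines[:20]}")
    return parsed


def normalise_dispensing(df: pd.DataFrame, study_window=None) -> pd.DataFrame:
    """Validate and sort an in-memory dispensing table.

    Ensures the schema, parses dates, enforces ``days_supplied >= 1`` and a
    non-empty ATC code, optionally checks dates against the study window,
    and returns rows sorted by ``(patient_id, date)`` with an integer ``day``
    column added.  Duplicate identical rows are retained: they are distinct
    dispensings.
    """
    _require_columns(df, DISPENSING_COLUMNS, "dispensing table")
    out = df.copy()
    out["date"] = _parse_dates(out, "date", "dispensing table")
    out["atc"] = out["atc"].astype(str)
    if (out["atc"].str.len() == 0).any() or (out["atc"] == "nan").any():
        bad = np.flatnonzero(((out["atc"].str.len() == 0) | (out["atc"] == "nan")).to_numpy())
        raise SchemaError(f"empty atc code at row(s) {bad[:20].tolist()}")
    out["days_supplied"] = pd.to_numeric(out["days_supplied"], errors="coerce")
    bad = out["days_supplied"].isna() | (out["days_supplied"] < 1)
    if bad.any():
        raise SchemaError(
            f"days_supplied must be >= 1; violated at row(s) "
            f"{np.flatnonzero(bad.to_numpy())[:20].tolist()}"
        )
    out["days_supplied"] = out["days_supplied"].astype(np.int64)
    out["strength_mg"] = pd.to_numeric(out["strength_mg"], errors="coerce")
    out["units"] = pd.to_numeric(out["units"], errors="coerce")
    if study_window is not None:
        lo, hi = (to_day([study_window[0]])[0], to_day([study_window[1]])[0])
        day = to_day(out["date"])
        bad = (day < lo) | (day > hi)
        if bad.any():
            raise SchemaError(
                f"dispensing date outside study window at row(s) "
                f"{np.flatnonzero(bad)[:20].tolist()}"
            )
    out = out.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    out["day"] = to_day(out["date"])
    return out


def read_dispensing_table(path, study_window=None) -> pd.DataFrame:
    """Read a dispensing CSV, validate and return it sorted by (patient, date)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "atc": str})
    return normalise_dispensing(df, study_window=study_window)


def normalise_patients(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, PATIENT_COLUMNS, "patient table")
    out = df.copy()
    out["birth_date"] = _parse_dates(out, "birth_date", "patient table")
    sex = out["sex"].astype(str).str.lower()
    if not sex.isin(["male", "female"]).all():
        raise SchemaError("sex must be 'male' or 'female'")
    out["sex"] = sex
    if out["patient_id"].duplicated().any():
        dup = out.loc[out["patient_id"].duplicated(), "patient_id"].unique()
        raise SchemaError(f"duplicate patient_id(s): {dup[:10].tolist()}")
    out = out.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    out["birth_day"] = to_day(out["birth_date"])
    return out


def read_patient_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return normalise_patients(df)


def write_dispensing_table(df: pd.DataFrame, path) -> None:
    out = df[DISPENSING_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_patient_table(df: pd.DataFrame, path) -> None:
    out = df[PATIENT_COLUMNS].copy()
    out["birth_date"] = pd.to_datetime(out["birth_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
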