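"""Adherence outcomes from coverage intervals (PDC-style metrics).

Yearly adherence for year ``k`` is the number of covered index-drug days in
``[index+(k-1)*360, index+k*360)`` divided by the fixed 360-day
denominator; it is defined only for patients still on the original
monotherapy beyond ``k`` years (no change event before ``index+k*360``).
The binary classification is high iff adherence >= 0.8 (boundary
inclusive).  With the 90-day stockpile carryover a yearly value may exceed
1; values are never clipped before averaging but are dichotomised as is.

The 3-year window outcome divides covered days during follow-up by total
follow-up days, in patients whose database records span more than 3 years
from index while their time on the original monotherapy is at most 3
years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortRules, YEAR_DAYS, _ensure_day, study_class_series
from .coverage import build_coverage
from .vocab import AtcVocabulary

HIGH_THRESHOLD = 0.8


def yearly_adherence(intervals, k: int, index_day: int = 0, year_days: int = YEAR_DAYS) -> float:
    """Covered days of year ``k`` (1-based) divided by the 360-day year."""
    lo = index_day + (k - 1) * year_days
    hi = index_day + k * year_days
    covered = sum(max(0, min(b, hi) - max(a, lo)) for a, b in intervals)
    return covered / year_days


def index_class_coverage(
    cohort: pd.DataFrame,
    dispensing: pd.DataFrame,
    vocab: AtcVocabulary | None = None,
    rules: CohortRules | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Coverage intervals of the index class per patient, clipped at the
    follow-up cap."""
    vocab = vocab or AtcVocabulary()
    rules = rules or CohortRules()
    dispensing = _ensure_day(dispensing)
    cls = study_class_series(dispensing["atc"], vocab).to_numpy()
    day = dispensing["day"].to_numpy()
    sup = dispensing["days_supplied"].to_numpy()
    groups = dispensing.groupby("patient_id").indices
    caps = cohort["cap_day"] if "cap_day" in cohort.columns else np.minimum(
        rules.study_end_day, cohort["index_day"] + rules.followup_cap_days
    )
    out: dict[str, list[tuple[int, int]]] = {}
    for pid, idx, index_class, cap in zip(
        cohort["patient_id"], cohort["index_day"], cohort["index_class"], caps
    ):
        ix = groups[pid]
        own = (cls[ix] == index_class) & (day[ix] >= int(idx))
        out[pid] = build_coverage(
            day[ix][own], sup[ix][own], cap_day=int(cap), stockpile_cap=rules.stockpile_cap
        )
    return out


def yearly_adherence_table(
    cohort: pd.DataFrame,
    coverages: dict[str, list[tuple[int, int]]],
    persistence: pd.Series,
    n_years: int = 10,
    year_days: int = YEAR_DAYS,
) -> pd.DataFrame:
    """Long table ``patient_id, year, adherence, high`` for years within
    each patient's persistence window.

    ``persistence`` maps patient_id to days on the original monotherapy;
    year ``k`` is reported only when persistence strictly exceeds
    ``k*360`` (the at-risk rule), so patients leave the denominator rather
    than contributing zeros.
    """
    pers_map = persistence.to_dict()
    rows_pid, rows_year, rows_val = [], [], []
    for pid, idx in zip(cohort["patient_id"], cohort["index_day"]):
        idx = int(idx)
        pers = int(pers_map[pid])
        kmax = min(n_years, (pers - 1) // year_days)
        ivals = coverages.get(pid, [])
        for k in range(1, kmax + 1):
            rows_pid.append(pid)
            rows_year.append(k)
            rows_val.append(yearly_adherence(ivals, k, idx, year_days))
    out = pd.DataFrame({"patient_id": rows_pid, "year": rows_year, "adherence": rows_val})
    out["high"] = out["adherence"] >= HIGH_THRESHOLD
    return out


def prevalence_high_adherence(yearly: pd.DataFrame, k: int):
    """(n_high, n_at_risk, proportion) of high adherence in year ``k``.

    The denominator is every patient still at risk (on original
    monotherapy beyond ``k`` years); the proportion is NaN when empty.
    """
    sub = yearly[yearly["year"] == k]
    n_at_risk = len(sub)
    n_high = int(sub["high"].sum())
    prop = n_high / n_at_risk if n_at_risk else float("nan")
    return n_high, n_at_risk, prop


def prevalence_by_year(yearly: pd.DataFrame, n_years: int = 10) -> pd.DataFrame:
    rows = []
    for k in range(1, n_years + 1):
        n_high, n_at_risk, prop = prevalence_high_adherence(yearly, k)
        rows.append({"year": k, "n_high": n_high, "n_at_risk": n_at_risk, "prevalence": prop})
    return pd.DataFrame(rows)


def average_adherence(yearly: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of the continuous yearly adherence across patients."""
    g = yearly.groupby("year")["adherence"]
    return pd.DataFrame({"year": g.mean().index, "mean": g.mean().values, "sd": g.std().values})


def window_adherence_3yr(
    cohort: pd.DataFrame,
    coverages: dict[str, list[tuple[int, int]]],
    persistence: pd.Series,
    year_days: int = YEAR_DAYS,
) -> pd.DataFrame:
    """Follow-up-window adherence for the 3-year analysis population.

    Population: database records span more than 3*360 days from index
    (``last_record_day``) and time on the original monotherapy is at most
    3*360 days.  Value = covered days during follow-up / follow-up days,
    follow-up running from index to the earlier of the follow-up end and
    the 3-year mark; dichotomised at 0.8.
    """
    horizon = 3 * year_days
    pers_map = persistence.to_dict()
    rows = []
    for pid, idx, last_rec, fu_end_day in zip(
        cohort["patient_id"], cohort["index_day"],
        cohort["last_record_day"], cohort["followup_end_day"],
    ):
        idx = int(idx)
        pers = int(pers_map[pid])
        records_span = int(last_rec) - idx
        if records_span <= horizon or pers > horizon:
            continue
        fu_end = min(int(fu_end_day), idx + horizon)
        fu_days = fu_end - idx
        if fu_days <= 0:
            raise ValueError(f"zero-length follow-up for patient {pid}")
        covered = sum(
            max(0, min(b, fu_end) - max(a, idx)) for a, b in coverages.get(pid, [])
        )
        val = covered / fu_days
        rows.append(
            {"patient_id": pid, "followup_days": fu_days, "adherence": val,
             "high": val >= HIGH_THRESHOLD}
        )
    return pd.DataFrame(rows, columns=["patient_id", "followup_days", "adherence", "high"])
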