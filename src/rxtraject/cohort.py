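"""New-user cohort construction: inclusion, exclusion, follow-up, covariates.

Implements an inception (new-user) design: cohort entry at the first-ever
dispensing of a study drug class, with a two-year clean lookback, at least
one year of database presence afterwards, adulthood at index, and at least
three index-class dispensings in the first year.  A "year" is 360 days and
a "half year" 180 days throughout; all windows are half-open ``[a, b)`` on
the integer day grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import from_day, to_day
from .vocab import COMEDICATION_GROUPS, AtcVocabulary

YEAR_DAYS = 180 * 2

AGE_GROUPS = ("18-39", "40-69", ">=70")
CALENDAR_PERIODS = ("1996-2000", "2000-2010", "2010-2020")


@dataclass
class CohortRules:
    """Tunable thresholds of the cohort definition (defaults as published)."""

    min_age: int = 18
    history_days: int = 720
    post_days: int = 360
    min_fills_first_year: int = 3
    baseline_window_days: int = 180
    followup_cap_days: int = 3780
    study_end: str = "2020-12-31"
    antihypertensive_window: tuple[int, int] = (0, 360)
    cardiac_window: tuple[int, int] = (-720, 90)
    cv_event_proxy: bool = True
    stockpile_cap: int = 90
    calendar_bins: tuple[int, ...] = (1996, 2000, 2010, 2021)

    @property
    def study_end_day(self) -> int:
        return int(to_day([self.study_end])[0])


def match_prefix(atc: pd.Series, prefixes) -> np.ndarray:
    """Vectorised 'starts with any of these ATC prefixes'."""
    mask = np.zeros(len(atc), dtype=bool)
    for p in prefixes:
        mask |= atc.str.startswith(p).to_numpy()
    return mask


def study_class_series(atc: pd.Series, vocab: AtcVocabulary) -> pd.Series:
    """Study-class label per row (longest prefix wins), NaN if none."""
    out = pd.Series(np.full(len(atc), None, dtype=object), index=atc.index)
    for label, prefix in sorted(vocab.study_classes.items(), key=lambda kv: len(kv[1])):
        out[atc.str.startswith(prefix)] = label
    return out


def _ensure_day(df: pd.DataFrame) -> pd.DataFrame:
    if "day" not in df.columns:
        df = df.copy()
        df["day"] = to_day(df["date"])
    return df


def assign_strata(age_at_index, index_year, rules: CohortRules | None = None):
    """Age band and calendar period for one entry or arrays of entries.

    Calendar bins are half-open with boundary years assigned to the later
    period (the published period labels overlap at 2000 and 2010).
    """
    age = np.asarray(age_at_index)
    year = np.asarray(index_year)
    age_group = np.select([age < 40, age < 70], AGE_GROUPS[:2], AGE_GROUPS[2])
    period = np.select([year < 2000, year < 2010], CALENDAR_PERIODS[:2], CALENDAR_PERIODS[2])
    if age.ndim == 0:
        return str(age_group), str(period)
    return age_group, period


def identify_new_users(
    dispensing: pd.DataFrame,
    patients: pd.DataFrame,
    vocab: AtcVocabulary | None = None,
    rules: CohortRules | None = None,
) -> pd.DataFrame:
    """Apply the new-user inclusion rules and return one row per entrant.

    Index date is each patient's first study-class dispensing.  A patient
    enters the cohort only if there is no earlier study-class dispensing
    (trivially true at the first), exactly one study class is begun that
    day (same-day initiation of two classes is not monotherapy), age at
    index is >= ``min_age``, the first database record is >= 720 days
    before index with a record >= 360 days after, and the index class is
    dispensed >= 3 times in the first 360 days.
    """
    vocab = vocab or AtcVocabulary()
    rules = rules or CohortRules()
    dispensing = _ensure_day(dispensing)

    missing = set(dispensing["patient_id"]) - set(patients["patient_id"])
    if missing:
        raise ValueError(
            f"patients present in dispensing but absent from patient table: "
            f"{sorted(missing)[:20]}"
        )

    cls = study_class_series(dispensing["atc"], vocab)
    study = dispensing.loc[cls.notna(), ["patient_id", "day", "days_supplied"]].copy()
    study["study_class"] = cls[cls.notna()]
    if study.empty:
        return _empty_cohort()

    g = study.groupby("patient_id", sort=True)
    index_day = g["day"].min().rename("index_day")
    first_rec = dispensing.groupby("patient_id")["day"].min().rename("first_record_day")
    last_rec = dispensing.groupby("patient_id")["day"].max().rename("last_record_day")

    ent = index_day.to_frame().join(first_rec).join(last_rec).reset_index()

    # index-day classes: exclude same-day multi-class initiators
    at_index = study.merge(ent[["patient_id", "index_day"]], on="patient_id")
    at_index = at_index[at_index["day"] == at_index["index_day"]]
    n_classes = at_index.groupby("patient_id")["study_class"].nunique()
    index_class = at_index.groupby("patient_id")["study_class"].first()
    ent = ent.merge(n_classes.rename("n_index_classes"), on="patient_id")
    ent = ent.merge(index_class.rename("index_class"), on="patient_id")

    # first-year fill count of the index class
    fy = study.merge(ent[["patient_id", "index_day", "index_class"]], on="patient_id")
    fy = fy[
        (fy["study_class"] == fy["index_class"])
        & (fy["day"] >= fy["index_day"])
        & (fy["day"] < fy["index_day"] + YEAR_DAYS)
    ]
    ent = ent.merge(
        fy.groupby("patient_id").size().rename("n_fills_first_year"),
        on="patient_id",
        how="left",
    )
    ent["n_fills_first_year"] = ent["n_fills_first_year"].fillna(0).astype(int)

    pt = patients.copy()
    if "birth_day" not in pt.columns:
        pt["birth_day"] = to_day(pt["birth_date"])
    ent = ent.merge(pt[["patient_id", "birth_day", "sex"]], on="patient_id")
    ent["age_at_index"] = ((ent["index_day"] - ent["birth_day"]) / 365.25).astype(int)

    keep = (
        (ent["n_index_classes"] == 1)
        & (ent["age_at_index"] >= rules.min_age)
        & (ent["index_day"] - ent["first_record_day"] >= rules.history_days)
        & (ent["last_record_day"] - ent["index_day"] >= rules.post_days)
        & (ent["n_fills_first_year"] >= rules.min_fills_first_year)
    )
    ent = ent[keep].drop(columns=["n_index_classes"]).reset_index(drop=True)

    ent["index_date"] = from_day(ent["index_day"]).values
    year = ent["index_date"].dt.year.to_numpy()
    ent["age_group"], ent["calendar_period"] = assign_strata(
        ent["age_at_index"].to_numpy(), year, rules
    )
    return ent


def _empty_cohort() -> pd.DataFrame:
    cols = [
        "patient_id", "index_day", "first_record_day", "last_record_day",
        "index_class", "n_fills_first_year", "birth_day", "sex",
        "age_at_index", "index_date", "age_group", "calendar_period",
    ]
    return pd.DataFrame(columns=cols)


def apply_exclusions(
    entries: pd.DataFrame,
    dispensing: pd.DataFrame,
    vocab: AtcVocabulary | None = None,
    rules: CohortRules | None = None,
):
    """Drop entries violating the exclusion rules; return (entries, attrition).

    Rules (windows relative to index, half-open): any antihypertensive or
    fixed-combination dispensing in the first year after index, and any
    acute/chronic cardiac-list dispensing in the two years before through
    90 days after index.  The attrition table has columns
    ``rule, n_excluded, n_remaining``, applied sequentially.
    """
    vocab = vocab or AtcVocabulary()
    rules = rules or CohortRules()
    dispensing = _ensure_day(dispensing)

    windows = {
        "antihypertensive_first_year": rules.antihypertensive_window,
        "cardiac_window": rules.cardiac_window,
    }
    rows = []
    current = entries.copy()
    for rule, prefixes in vocab.exclusion_map.items():
        lo, hi = windows.get(rule, (0, YEAR_DAYS))
        hit = dispensing[match_prefix(dispensing["atc"], prefixes)]
        merged = hit.merge(current[["patient_id", "index_day"]], on="patient_id")
        in_win = merged[
            (merged["day"] >= merged["index_day"] + lo)
            & (merged["day"] < merged["index_day"] + hi)
        ]
        bad = set(in_win["patient_id"])
        n_before = len(current)
        current = current[~current["patient_id"].isin(bad)]
        rows.append(
            {"rule": rule, "n_excluded": n_before - len(current), "n_remaining": len(current)}
        )
    return current.reset_index(drop=True), pd.DataFrame(rows)


def baseline_flags(
    entries: pd.DataFrame,
    dispensing: pd.DataFrame,
    vocab: AtcVocabulary | None = None,
    rules: CohortRules | None = None,
) -> pd.DataFrame:
    """One boolean per co-medication group: any mapped dispensing in
    ``[index, index+180)``."""
    vocab = vocab or AtcVocabulary()
    rules = rules or CohortRules()
    dispensing = _ensure_day(dispensing)
    out = entries.copy()
    win = rules.baseline_window_days
    merged = dispensing.merge(entries[["patient_id", "index_day"]], on="patient_id")
    in_win = merged[
        (merged["day"] >= merged["index_day"]) & (merged["day"] < merged["index_day"] + win)
    ]
    for group in COMEDICATION_GROUPS:
        prefixes = vocab.comedication_map.get(group, [])
        hit = set(in_win.loc[match_prefix(in_win["atc"], prefixes), "patient_id"])
        out[f"flag_{group}"] = out["patient_id"].isin(hit)
    return out


def determine_followup_end(
    entries: pd.DataFrame,
    dispensing: pd.DataFrame,
    vocab: AtcVocabulary | None = None,
    rules: CohortRules | None = None,
) -> pd.DataFrame:
    """Per-entry follow-up end day and reason.

    Earliest of: study end (incl. the ~10-year cap at index+3780, reported
    as ``study_end``), the first cardiac-proxy dispensing after index
    (``cv_event_proxy``, optional), the run-out of the final index-class
    dispensing (``last_prescription``), and the first dispensing of a
    different study class or fixed combination (``pattern_change``).  Ties
    are resolved in that order.
    """
    from .coverage import build_coverage

    vocab = vocab or AtcVocabulary()
    rules = rules or CohortRules()
    dispensing = _ensure_day(dispensing)

    cls = study_class_series(dispensing["atc"], vocab)
    combo = pd.Series(match_prefix(dispensing["atc"], vocab.fixed_combo_prefixes),
                      index=dispensing.index)
    cardiac = pd.Series(
        match_prefix(dispensing["atc"], vocab.exclusion_map.get("cardiac_window", [])),
        index=dispensing.index,
    )

    day = dispensing["day"].to_numpy()
    sup = dispensing["days_supplied"].to_numpy()
    cls_arr = cls.to_numpy()
    combo_arr = combo.to_numpy() if hasattr(combo, "to_numpy") else np.asarray(combo)
    cardiac_arr = cardiac.to_numpy() if hasattr(cardiac, "to_numpy") else np.asarray(cardiac)
    groups = dispensing.groupby("patient_id").indices

    end_days, reasons = [], []
    study_end_day = rules.study_end_day
    for pid, idx, index_class in zip(
        entries["patient_id"], entries["index_day"], entries["index_class"]
    ):
        ix = groups[pid]
        d_g, s_g = day[ix], sup[ix]
        c_g, combo_g, card_g = cls_arr[ix], combo_arr[ix], cardiac_arr[ix]
        idx = int(idx)
        cap = min(study_end_day, idx + rules.followup_cap_days)
        candidates: list[tuple[int, str]] = [(cap, "study_end")]
        if rules.cv_event_proxy:
            cv = d_g[card_g & (d_g > idx)]
            if len(cv):
                candidates.append((int(cv.min()), "cv_event_proxy"))
        own = (c_g == index_class) & (d_g >= idx)
        ivals = build_coverage(
            d_g[own], s_g[own], cap_day=cap, stockpile_cap=rules.stockpile_cap
        )
        if ivals:
            candidates.append((ivals[-1][1], "last_prescription"))
        other_mask = (d_g > idx) & (
            combo_g | ((c_g != None) & (c_g != index_class))  # noqa: E711
        )
        if other_mask.any():
            candidates.append((int(d_g[other_mask].min()), "pattern_change"))
        best = min(candidates, key=lambda c: c[0])
        end_days.append(best[0])
        reasons.append(best[1])

    out = entries.copy()
    out["followup_end_day"] = np.asarray(end_days, dtype=np.int64)
    out["end_reason"] = reasons
    out["followup_end"] = from_day(out["followup_end_day"]).values
    out["cap_day"] = np.minimum(study_end_day, out["index_day"] + rules.followup_cap_days)
    return out


def build_cohort(
    dispensing: pd.DataFrame,
    patients: pd.DataFrame,
    vocab: AtcVocabulary | None = None,
    rules: CohortRules | None = None,
):
    """Full cohort pipeline: inclusion -> exclusions -> follow-up -> flags.

    Returns ``(cohort, attrition)``.
    """
    vocab = vocab or AtcVocabulary()
    rules = rules or CohortRules()
    dispensing = _ensure_day(dispensing)
    ent = identify_new_users(dispensing, patients, vocab, rules)
    n0 = len(ent)
    ent, attrition = apply_exclusions(ent, dispensing, vocab, rules)
    attrition = pd.concat(
        [pd.DataFrame([{"rule": "new_users", "n_excluded": 0, "n_remaining": n0}]), attrition],
        ignore_index=True,
    )
    ent = determine_followup_end(ent, dispensing, vocab, rules)
    ent = baseline_flags(ent, dispensing, vocab, rules)
    return ent, attrition
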