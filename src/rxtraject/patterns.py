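"""Drug-utilisation pattern classification: continuation, discontinuation,
switch and add-on.

Definitions (all relative to the index monotherapy, windows on the integer
day grid):

* discontinuation — a supply gap of the index class strictly longer than
  180 days, measured from a run-out (end of a coverage interval) to the
  next index-class dispensing or, for the final run-out, to the follow-up
  cap; the discontinuation date is the run-out opening the gap;
* switch — a dispensing of a *different* study class or a fixed-dose
  combination within 180 days after the discontinuation date (inclusive);
* add-on — a dispensing of a different study class or fixed combination
  while index supply is active (strictly inside a coverage interval) and
  before any discontinuation;
* continuation — none of the above through the end of follow-up.

The flags are non-exclusive except that continuation excludes everything
and a switch implies a discontinuation.  Patients are flagged ``eligible``
when they persisted on the original monotherapy for more than one 360-day
year (no change event before index+360).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortRules, YEAR_DAYS, _ensure_day, match_prefix, study_class_series
from .coverage import build_coverage
from .vocab import AtcVocabulary

PATTERN_FLAGS = ("continuation", "discontinuation", "switch", "add_on")


@dataclass
class PatternOptions:
    """Classification conventions (defaults follow the published rules)."""

    gap_days: int = 180
    gap_strict: bool = True            # gap must strictly exceed gap_days
    gap_from_runout: bool = True       # False: measure from dispensing dates
    switch_window_days: int = 180
    switch_inclusive: bool = True      # day gap_date+180 still counts
    addon_requires_coverage: bool = True


def detect_discontinuation(
    intervals: list[tuple[int, int]],
    cap_day: int,
    opts: PatternOptions | None = None,
) -> tuple[bool, int | None]:
    """First >180-day supply gap; returns (found, run-out day opening it)."""
    opts = opts or PatternOptions()
    if not intervals:
        return False, None
    exceeds = (lambda g: g > opts.gap_days) if opts.gap_strict else (lambda g: g >= opts.gap_days)
    for (a0, b0), (a1, _b1) in zip(intervals, intervals[1:]):
        if exceeds(a1 - b0):
            return True, b0
    last_end = intervals[-1][1]
    if exceeds(cap_day - last_end):
        return True, last_end
    return False, None


def detect_switch(
    disc_day: int | None,
    event_days,
    event_classes,
    opts: PatternOptions | None = None,
) -> tuple[bool, int | None, str | None]:
    """First different-class / fixed-combo dispensing within the switch
    window after discontinuation.  No discontinuation => no switch.

    ``event_days``/``event_classes`` are parallel, day-sorted sequences of
    non-index study-class (or fixed-combo) dispensings.
    """
    opts = opts or PatternOptions()
    days = np.asarray(event_days)
    if disc_day is None or len(days) == 0:
        return False, None, None
    hi = disc_day + opts.switch_window_days
    sel = (days > disc_day) & ((days <= hi) if opts.switch_inclusive else (days < hi))
    if not sel.any():
        return False, None, None
    first = int(np.flatnonzero(sel)[0])
    return True, int(days[first]), str(event_classes[first])


def detect_addon(
    intervals: list[tuple[int, int]],
    disc_day: int | None,
    event_days,
    event_classes,
    opts: PatternOptions | None = None,
) -> tuple[bool, int | None, str | None]:
    """First different-class / fixed-combo dispensing during active index
    coverage and before any discontinuation."""
    opts = opts or PatternOptions()
    days = np.asarray(event_days)
    if len(days) == 0:
        return False, None, None
    ok = np.ones(len(days), dtype=bool)
    if disc_day is not None:
        ok &= days < disc_day
    if opts.addon_requires_coverage:
        cov = np.zeros(len(days), dtype=bool)
        for a, b in intervals:
            cov |= (days >= a) & (days < b)
        ok &= cov
    if not ok.any():
        return False, None, None
    first = int(np.flatnonzero(ok)[0])
    return True, int(days[first]), str(event_classes[first])


def classify_patterns(
    index_day: int,
    intervals: list[tuple[int, int]],
    event_days,
    event_classes,
    cap_day: int,
    opts: PatternOptions | None = None,
) -> dict:
    """Classify one patient; returns the full assessment dict.

    ``event_days``/``event_classes`` are parallel, day-sorted sequences of
    dispensings of non-index study classes / fixed combos before the
    follow-up cap.
    """
    opts = opts or PatternOptions()
    disc, disc_day = detect_discontinuation(intervals, cap_day, opts)
    sw, sw_day, sw_target = detect_switch(disc_day, event_days, event_classes, opts)
    ad, ad_day, ad_target = detect_addon(intervals, disc_day, event_days, event_classes, opts)
    cont = not disc and not sw and not ad
    events = [d for d in (disc_day, ad_day) if d is not None]
    persistence = (min(events) if events else cap_day) - index_day
    return {
        "continuation": cont,
        "discontinuation": disc,
        "disc_day": disc_day,
        "switch": sw,
        "switch_day": sw_day,
        "switch_target": sw_target,
        "add_on": ad,
        "addon_day": ad_day,
        "addon_target": ad_target,
        "persistence_days": int(persistence),
        "eligible": persistence > YEAR_DAYS,
    }


def classify_patterns_table(
    cohort: pd.DataFrame,
    dispensing: pd.DataFrame,
    vocab: AtcVocabulary | None = None,
    rules: CohortRules | None = None,
    opts: PatternOptions | None = None,
) -> pd.DataFrame:
    """Pattern assessment for every cohort entry.

    The follow-up cap is ``min(study end, index + 3780)``; dispensings on
    or after the cap never influence the classification.
    """
    vocab = vocab or AtcVocabulary()
    rules = rules or CohortRules()
    opts = opts or PatternOptions()
    dispensing = _ensure_day(dispensing)

    cls = study_class_series(dispensing["atc"], vocab).to_numpy()
    combo = match_prefix(dispensing["atc"], vocab.fixed_combo_prefixes)
    cls = np.where(combo & (cls == None), "fixed_combo", cls)  # noqa: E711
    day = dispensing["day"].to_numpy()
    sup = dispensing["days_supplied"].to_numpy()
    groups = dispensing.groupby("patient_id").indices

    caps = cohort["cap_day"] if "cap_day" in cohort.columns else np.minimum(
        rules.study_end_day, cohort["index_day"] + rules.followup_cap_days
    )
    rows = []
    for pid, idx, index_class, cap in zip(
        cohort["patient_id"], cohort["index_day"], cohort["index_class"], caps
    ):
        idx, cap = int(idx), int(cap)
        ix = groups[pid]
        d_g, s_g, c_g = day[ix], sup[ix], cls[ix]
        own = (c_g == index_class) & (d_g >= idx) & (d_g < cap)
        if opts.gap_from_runout:
            ivals = build_coverage(
                d_g[own], s_g[own], cap_day=cap, stockpile_cap=rules.stockpile_cap
            )
        else:
            ivals = [(int(t), int(t)) for t in d_g[own]]
        other = (c_g != None) & (c_g != index_class) & (d_g > idx) & (d_g < cap)  # noqa: E711
        ev_days, ev_cls = d_g[other], c_g[other]
        order = np.argsort(ev_days, kind="stable")
        res = classify_patterns(idx, ivals, ev_days[order], ev_cls[order], cap, opts)
        res["patient_id"] = pid
        rows.append(res)
    out = pd.DataFrame(rows)
    _check_invariants(out)
    return out[
        ["patient_id", "eligible", "persistence_days"] + list(PATTERN_FLAGS)
        + ["disc_day", "switch_day", "switch_target", "addon_day", "addon_target"]
    ]


def _check_invariants(assessments: pd.DataFrame) -> None:
    a = assessments
    if (a["switch"] & ~a["discontinuation"]).any():
        raise AssertionError("switch without discontinuation")
    other = a["discontinuation"] | a["switch"] | a["add_on"]
    if (a["continuation"] & other).any():
        raise AssertionError("continuation must exclude all other flags")


def pattern_rate_table(
    assessments: pd.DataFrame,
    cohort: pd.DataFrame,
    formatted: bool = True,
) -> pd.DataFrame:
    """Counts and percentages of each pattern by index class.

    Restricted to eligible entries (persisted > 1 year).  With
    ``formatted=True`` cells read ``"5044 (38.0%)"`` (percentage =
    count/class-N to one decimal); otherwise numeric counts are returned.
    Classes are ordered by descending N after an overall column.
    """
    df = assessments.merge(cohort[["patient_id", "index_class"]], on="patient_id")
    df = df[df["eligible"]]
    class_n = df["index_class"].value_counts()
    order = ["Overall"] + class_n.index.tolist()

    def column(label):
        sub = df if label == "Overall" else df[df["index_class"] == label]
        n = len(sub)
        cells = {}
        for flag in PATTERN_FLAGS:
            c = int(sub[flag].sum())
            if formatted:
                cells[flag] = f"{c} ({100 * c / n:.1f}%)" if n else ("0" if c == 0 else str(c))
            else:
                cells[flag] = c
        return n, cells

    data, columns = {}, []
    for label in order:
        n, cells = column(label)
        name = f"{label} (N={n})"
        columns.append(name)
        data[name] = [cells[f] for f in PATTERN_FLAGS]
    pretty = {"continuation": "Continuation", "discontinuation": "Discontinuation",
              "switch": "Switch", "add_on": "Add on"}
    return pd.DataFrame(data, index=[pretty[f] for f in PATTERN_FLAGS], columns=columns)
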