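import numpy as np
import pandas as pd
import pytest

from rxtraject import CohortRules, identify_new_users
from rxtraject.cohort import (
    apply_exclusions,
    assign_strata,
    baseline_flags,
    build_cohort,
    determine_followup_end,
)
from rxtraject.io import to_day

from _oracles import DAY0, disp_table, patient_table, standard_records

ADULT = DAY0 - 50 * 365  # born ~50 years before the anchor index day


def _cohort(rows, patients=None):
    d = disp_table(rows)
    p = patients if patients is not None else patient_table([("P1", ADULT)])
    return identify_new_users(d, p)


def fills(pid="P1", start=DAY0, n=4, step=90, atc="C10AA01", sup=90):
    return [(start + i * step, atc, sup) for i in range(n)]


def test_three_prescriptions_rule():
    two = _cohort(standard_records("P1", fills(n=2)))
    three = _cohort(standard_records("P1", fills(n=3)))
    assert len(two) == 0
    assert len(three) == 1
    assert three.loc[0, "index_day"] == DAY0
    assert three.loc[0, "index_class"] == "simvastatin"


def test_minimum_age_at_index():
    minor = patient_table([("P1", DAY0 - 17 * 366)])
    adult18 = patient_table([("P1", DAY0 - int(18.2 * 365.25))])
    rows = standard_records("P1", fills())
    assert len(identify_new_users(disp_table(rows), minor)) == 0
    assert len(identify_new_users(disp_table(rows), adult18)) == 1


def test_same_day_dual_class_initiation_excluded():
    """Starting two study classes on the index day is not monotherapy."""
    rows = standard_records("P1", fills() + [(DAY0, "C10AA05", 30)])
    assert len(_cohort(rows)) == 0


@pytest.mark.parametrize(
    "class_a,class_b",
    [("C10AA01", "C10AA05"), ("C10AA03", "C10AB04"), ("C10AA04", "C10AA07")],
)
def test_same_day_pairs_all_excluded(class_a, class_b):
    rows = standard_records(
        "P1", [(DAY0 + i * 90, class_a, 90) for i in range(4)] + [(DAY0, class_b, 30)],
        first_day=DAY0,
    )
    assert len(_cohort(rows)) == 0


def test_history_window_boundary():
    """First database record must be >= 720 days before index."""
    short = [("P1", DAY0 - 719, "N02BE01", 10), ("P1", DAY0 + 370, "N02BE01", 10)]
    long = [("P1", DAY0 - 720, "N02BE01", 10), ("P1", DAY0 + 370, "N02BE01", 10)]
    f = [(d, a, s) for d, a, s in fills()]
    assert len(_cohort(short + [("P1", d, a, s) for d, a, s in f])) == 0
    assert len(_cohort(long + [("P1", d, a, s) for d, a, s in f])) == 1


def test_followon_window_boundary():
    """A record >= 360 days after index is required."""
    base = [("P1", DAY0 - 730, "N02BE01", 10)]
    f = [("P1", d, a, s) for d, a, s in fills(n=3, step=30, sup=30)]
    assert len(_cohort(base + f + [("P1", DAY0 + 359, "N02BE01", 10)])) == 0
    assert len(_cohort(base + f + [("P1", DAY0 + 360, "N02BE01", 10)])) == 1


def test_dispensing_patient_mismatch_raises():
    d = disp_table(standard_records("P1", fills()))
    with pytest.raises(ValueError, match="P1"):
        identify_new_users(d, patient_table([("P2", ADULT)]))


def test_prior_use_shifts_index_and_fails_history():
    """The index is the first-ever study dispensing, so earlier use means
    the patient is not a new user at the later date."""
    rows = standard_records("P1", [(DAY0 - 400, "C10AA01", 30)] + fills(),
                            first_day=DAY0 - 400)
    ent = _cohort(rows)
    # index lands on the earliest dispensing; only 1 fill in its first year
    assert len(ent) == 0


# ---------------------------------------------------------------- exclusions

def _entry(extra=(), rows=None):
    rows = rows if rows is not None else standard_records("P1", fills(), extra=extra)
    d = disp_table(rows)
    ent = identify_new_users(d, patient_table([("P1", ADULT)]))
    return ent, d


@pytest.mark.parametrize(
    "atc,offset,excluded",
    [
        ("C03AA01", 100, True),    # antihypertensive inside the first year
        ("C03AA01", 360, False),   # at the year boundary (half-open)
        ("C09AA02", 0, True),
        ("C01DA02", 91, False),    # cardiac list just outside +90
        ("C01DA02", 90, False),    # +90 itself is outside the half-open window
        ("C01DA02", 89, True),
        ("B01AC06", -720, True),   # exactly two years before
        ("B01AC06", -721, False),
    ],
)
def test_exclusion_windows(atc, offset, excluded):
    ent, d = _entry(extra=[("P1", DAY0 + offset, atc, 30)])
    kept, _att = apply_exclusions(ent, d)
    assert (len(kept) == 0) == excluded


def test_attrition_counts_planted_violations():
    rows, patients = [], []
    for i in range(10):
        pid = f"P{i}"
        patients.append((pid, ADULT))
        rows += standard_records(pid, [(DAY0 + j * 90, "C10AA01", 90) for j in range(4)])
    # plant 3 violations: two antihypertensive, one cardiac
    rows += [("P0", DAY0 + 50, "C03AA01", 30), ("P4", DAY0 + 200, "C07AB02", 30),
             ("P7", DAY0 - 100, "C01DA02", 30)]
    d = disp_table(rows)
    ent = identify_new_users(d, patient_table(patients))
    kept, att = apply_exclusions(ent, d)
    assert att["n_excluded"].sum() == 3
    assert len(kept) == 7
    assert att["n_remaining"].iloc[-1] == 7


def test_attrition_is_monotone(small_sim):
    patients, dispensing, _ = small_sim
    _cohort_df, att = build_cohort(dispensing, patients)
    assert (att["n_remaining"].diff().dropna() <= 0).all()
    assert att["n_remaining"].iloc[0] <= len(patients)


# ------------------------------------------------------------- follow-up end

def test_followup_study_end():
    """Refills continuing past the study end stop at 2020-12-31."""
    start = int(to_day(["2019-06-01"])[0])
    rows = standard_records(
        "P1", [(start + i * 30, "C10AA01", 30) for i in range(30)], first_day=start
    )
    ent, d = _entry(rows=rows)
    out = determine_followup_end(ent, d)
    assert out.loc[0, "end_reason"] == "study_end"
    assert out.loc[0, "followup_end_day"] == int(to_day(["2020-12-31"])[0])


def test_followup_last_prescription_runout():
    ent, d = _entry()
    out = determine_followup_end(ent, d)
    assert out.loc[0, "end_reason"] == "last_prescription"
    assert out.loc[0, "followup_end_day"] == DAY0 + 3 * 90 + 90  # last fill + supply


def test_followup_pattern_change_at_addon():
    ent, d = _entry(extra=[("P1", DAY0 + 100, "C10AA05", 30)])
    out = determine_followup_end(ent, d)
    assert out.loc[0, "end_reason"] == "pattern_change"
    assert out.loc[0, "followup_end_day"] == DAY0 + 100


def test_followup_cv_event_proxy_toggle():
    ent, d = _entry(extra=[("P1", DAY0 + 150, "C01DA02", 30)])
    out = determine_followup_end(ent, d)
    assert out.loc[0, "end_reason"] == "cv_event_proxy"
    rules = CohortRules(cv_event_proxy=False)
    out2 = determine_followup_end(ent, d, rules=rules)
    assert out2.loc[0, "end_reason"] == "last_prescription"


def test_followup_end_reason_consistency(small_pipeline, small_sim):
    """Recomputing every candidate date and taking the minimum reproduces
    the stored (followup_end, end_reason) pair."""
    res = small_pipeline
    _patients, dispensing, _ = small_sim
    stripped = res.cohort.drop(columns=["followup_end_day", "end_reason", "followup_end"])
    again = determine_followup_end(stripped, dispensing)
    pd.testing.assert_series_equal(
        again["followup_end_day"], res.cohort["followup_end_day"]
    )
    pd.testing.assert_series_equal(again["end_reason"], res.cohort["end_reason"])
    assert (res.cohort["followup_end_day"] > res.cohort["index_day"]).all()


# ------------------------------------------------------------ baseline flags

@pytest.mark.parametrize("offset,expected", [(0, True), (179, True), (180, False)])
def test_baseline_flag_window_boundaries(offset, expected):
    ent, d = _entry(extra=[("P1", DAY0 + offset, "A10BA02", 30)])
    out = baseline_flags(ent, d)
    assert bool(out.loc[0, "flag_diabetes"]) is expected


def test_no_comedication_all_flags_false():
    ent, d = _entry()
    out = baseline_flags(ent, d)
    flag_cols = [c for c in out.columns if c.startswith("flag_")]
    assert len(flag_cols) == 9
    assert not out[flag_cols].any().any()


# ------------------------------------------------------------------- strata

@pytest.mark.parametrize(
    "age,expected",
    [(18, "18-39"), (39, "18-39"), (40, "40-69"), (69, "40-69"), (70, ">=70"), (85, ">=70")],
)
def test_age_bands(age, expected):
    group, _ = assign_strata(age, 2005)
    assert group == expected


@pytest.mark.parametrize(
    "year,expected",
    [
        (1996, "1996-2000"), (1999, "1996-2000"),
        (2000, "2000-2010"), (2009, "2000-2010"),
        (2010, "2010-2020"), (2020, "2010-2020"),
    ],
)
def test_calendar_periods_boundary_years_go_later(year, expected):
    _, period = assign_strata(50, year)
    assert period == expected


def test_cohort_entries_revalidate(small_pipeline, small_sim):
    """Every emitted entry satisfies the inclusion predicates when
    re-checked independently."""
    res = small_pipeline
    _patients, dispensing, _ = small_sim
    c = res.cohort
    assert (c["age_at_index"] >= 18).all()
    assert (c["index_day"] - c["first_record_day"] >= 720).all()
    assert (c["last_record_day"] - c["index_day"] >= 360).all()
    assert (c["n_fills_first_year"] >= 3).all()
    assert (c["followup_end_day"] > c["index_day"]).all()
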