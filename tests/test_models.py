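import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rxtraject.models import (
    AdherenceTransitionCox,
    ModelDesign,
    PatternLogit,
    adherence_transition_table,
    evaluate,
    fit_cox_ipw,
    fit_lasso,
    fit_logistic,
    hosmer_lemeshow,
    ipw_weights,
    km_low_adherence,
    split_train_test,
    standardized_mean_differences,
)

from _oracles import auc_bruteforce, manual_km


def _sim_table(n, seed=0, or_male=1.0, p_base=0.6):
    rng = np.random.default_rng(seed)
    male = rng.random(n) < 0.5
    p = expit(np.log(p_base / (1 - p_base)) + np.log(or_male) * male)
    y = rng.random(n) < p
    return pd.DataFrame(
        {"sex": np.where(male, "male", "female"), "high_adherence": y.astype(int)}
    )


# ------------------------------------------------------------------- split

def test_split_sizes_and_partition():
    t = _sim_table(10)
    train, test = split_train_test(t, 0.7, seed=1)
    assert len(train) == 7 and len(test) == 3
    merged = pd.concat([train, test]).sort_index()
    assert len(merged) == 10


def test_split_deterministic_and_disjoint():
    t = _sim_table(101).reset_index().rename(columns={"index": "rowid"})
    a1, b1 = split_train_test(t, 0.7, seed=9)
    a2, b2 = split_train_test(t, 0.7, seed=9)
    pd.testing.assert_frame_equal(a1, a2)
    assert set(a1["rowid"]).isdisjoint(b1["rowid"])
    assert set(a1["rowid"]) | set(b1["rowid"]) == set(t["rowid"])


def test_split_too_small_errors():
    with pytest.raises(ValueError, match="10"):
        split_train_test(_sim_table(9))


# ---------------------------------------------------------------- logistic

def test_logistic_recovers_planted_or():
    t = _sim_table(20_000, seed=2, or_male=0.79)
    fit = fit_logistic(ModelDesign("high_adherence", covariates=["sex"]), t)
    est = fit.params["sex_male"]
    se = fit.bse["sex_male"]
    assert abs(est - np.log(0.79)) < 3 * se
    row = fit.or_table.set_index("term").loc["sex_male"]
    assert row["ci_low"] < row["OR"] < row["ci_high"]


def test_constant_outcome_errors():
    t = _sim_table(100, seed=3)
    t["high_adherence"] = 1
    with pytest.raises(ValueError, match="constant"):
        PatternLogit(t, ModelDesign("high_adherence", covariates=["sex"]))


def test_singular_design_names_collinear_terms():
    t = _sim_table(200, seed=4)
    t["dup"] = (t["sex"] == "male").astype(float)
    with pytest.raises(ValueError, match="singular|collinear"):
        PatternLogit(t, ModelDesign("high_adherence", covariates=["sex", "dup"]))


def test_separation_is_flagged():
    t = _sim_table(200, seed=5)
    t["high_adherence"] = (t["sex"] == "male").astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_logistic(ModelDesign("high_adherence", covariates=["sex"]), t)
    assert fit.separation_flag


def test_relevel_flips_log_odds_sign():
    t = _sim_table(5_000, seed=6, or_male=0.6)
    fit = fit_logistic(ModelDesign("high_adherence", covariates=["sex"]), t)
    flipped = t.assign(sex=t["sex"].map({"male": "female", "female": "male"}))
    fit2 = fit_logistic(ModelDesign("high_adherence", covariates=["sex"]), flipped)
    assert fit.params["sex_male"] == pytest.approx(-fit2.params["sex_male"], abs=1e-6)


def test_null_wald_type_one_error():
    """With no true effect, the 5% Wald test rejects ~5% of the time."""
    rng = np.random.default_rng(12)
    rejections = 0
    reps = 500
    for _ in range(reps):
        t = _sim_table(400, seed=rng.integers(2**31), or_male=1.0)
        fit = fit_logistic(ModelDesign("high_adherence", covariates=["sex"]), t)
        rejections += fit.pvalues["sex_male"] < 0.05
    rate = rejections / reps
    # binomial 3.5-sigma band around 0.05 with 500 replicates
    assert 0.016 <= rate <= 0.084, rate


# --------------------------------------------------------------- evaluation

def test_auc_perfect_and_null():
    t = _sim_table(4_000, seed=7, or_male=1.0)
    fit = fit_logistic(ModelDesign("high_adherence", covariates=["sex"]), t)
    m = evaluate(fit, t)
    assert abs(m["auc"] - 0.5) < 0.05  # score independent of outcome
    y = np.array([0, 0, 1, 1])
    assert auc_bruteforce(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0


def test_auc_equals_exhaustive_concordance_small_tables():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(8)
    for _ in range(30):
        n = rng.integers(6, 50)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        p = rng.choice(np.linspace(0, 1, 7), size=n)  # many ties
        assert roc_auc_score(y, p) == pytest.approx(auc_bruteforce(y, p))


def test_sensitivity_specificity_at_cutoff():
    t = pd.DataFrame(
        {"sex": ["male"] * 3 + ["female"] * 3, "high_adherence": [1, 1, 0, 0, 0, 1]}
    )
    fit = fit_logistic(ModelDesign("high_adherence", covariates=["sex"]),
                       _sim_table(2_000, seed=9, or_male=4.0))
    m = evaluate(fit, t, cutoff=0.5)
    p = fit.predict(t)
    pred = p >= 0.5
    y = t["high_adherence"].to_numpy()
    assert m["sensitivity"] == pytest.approx(
        ((pred) & (y == 1)).sum() / (y == 1).sum()
    )
    assert m["specificity"] == pytest.approx(
        ((~pred) & (y == 0)).sum() / (y == 0).sum()
    )


def test_single_class_test_set_auc_missing():
    t = _sim_table(2_000, seed=10, or_male=2.0)
    fit = fit_logistic(ModelDesign("high_adherence", covariates=["sex"]), t)
    sub = t[t["high_adherence"] == 1].head(20)
    assert np.isnan(evaluate(fit, sub)["auc"])


# ---------------------------------------------------------- Hosmer-Lemeshow

def test_hosmer_lemeshow_perfect_calibration():
    # predicted risk identical to the empirical rate in every group
    p = np.repeat([0.2, 0.8], 10)
    y = np.array([1, 1] + [0] * 8 + [1] * 8 + [0, 0])
    stat, pval = hosmer_lemeshow(y, p, g=2)
    assert stat == pytest.approx(0.0)
    assert pval == pytest.approx(1.0)


def test_hosmer_lemeshow_two_group_hand_arithmetic():
    p = np.array([0.1] * 5 + [0.9] * 5)
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 0])
    # group 1: O=1, E=0.5, n=5 -> (0.5)^2/(0.5*(1-0.1)) ; group 2: O=4, E=4.5
    hand = 0.25 / (0.5 * 0.9) + 0.25 / (4.5 * (1 - 0.9))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, _ = hosmer_lemeshow(y, p, g=2)
    assert stat == pytest.approx(hand)


def test_hosmer_lemeshow_sparse_warning():
    rng = np.random.default_rng(11)
    p = rng.random(30)
    y = (rng.random(30) < p).astype(int)
    with pytest.warns(UserWarning, match="sparse"):
        hosmer_lemeshow(y, p, g=10)


# -------------------------------------------------------------------- lasso

def _lasso_table(n, seed, betas):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(betas)))
    y = rng.random(n) < expit(X @ np.asarray(betas))
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(len(betas))])
    df["continuation"] = y.astype(int)
    return df


def test_lasso_limits():
    betas = [1.0, -1.0, 0.5, 0.0, 0.0]
    t = _lasso_table(3_000, 13, betas)
    covs = [f"x{i}" for i in range(5)]
    design = ModelDesign("continuation", covariates=covs)
    sel_all, fit_all = fit_lasso(design, t, lambda_grid=[1e-8], seed=1)
    assert sel_all == covs  # vanishing penalty keeps every term
    unpen = fit_logistic(design, t)
    for c in covs:
        assert fit_all.params[c] == pytest.approx(unpen.params[c], abs=1e-4)
    sel_none, fit_none = fit_lasso(design, t, lambda_grid=[1e8], seed=1)
    assert sel_none == []  # infinite penalty leaves the intercept only
    assert fit_none.columns == ["intercept"]


def test_lasso_selects_true_terms():
    """Three planted effects among 15 features are selected in >=90% of
    replicates."""
    true = {0, 1, 2}
    hits = 0
    reps = 20
    for r in range(reps):
        betas = [0.5, -0.5, 0.4] + [0.0] * 12
        t = _lasso_table(4_000, 100 + r, betas)
        covs = [f"x{i}" for i in range(15)]
        sel, _ = fit_lasso(ModelDesign("continuation", covariates=covs), t,
                           seed=r, cv=5)
        if true <= {int(s[1:]) for s in sel}:
            hits += 1
    assert hits / reps >= 0.9


def test_lasso_selection_seed_stable():
    t = _lasso_table(2_000, 21, [0.8, 0.0, 0.0])
    design = ModelDesign("continuation", covariates=["x0", "x1", "x2"])
    s1, _ = fit_lasso(design, t, seed=5)
    s2, _ = fit_lasso(design, t, seed=5)
    assert s1 == s2


# ------------------------------------------------------------- Kaplan-Meier

def test_km_no_events_flat_at_one():
    df = pd.DataFrame({"duration": [100, 200, 300], "event": [0, 0, 0],
                       "index_class": "simvastatin"})
    curves, _ = km_low_adherence(df)
    assert (curves["survival"] == 1.0).all()


def test_km_all_events_single_day():
    df = pd.DataFrame({"duration": [100] * 4, "event": [1] * 4,
                       "index_class": "simvastatin"})
    curves, _ = km_low_adherence(df)
    assert curves.loc[curves["time"] == 100, "survival"].iloc[0] == 0.0


def test_km_matches_manual_product_limit_five_subjects():
    durations = [50, 100, 100, 150, 200]
    events = [1, 1, 0, 1, 0]
    df = pd.DataFrame({"duration": durations, "event": events,
                       "index_class": "simvastatin"})
    curves, _ = km_low_adherence(df)
    for t, s in manual_km(durations, events):
        got = curves.loc[curves["time"] == t, "survival"].iloc[0]
        assert got == pytest.approx(s)


# --------------------------------------------------------------------- IPW

def _cox_table(n, seed, hr_b=1.0, confounded=False):
    rng = np.random.default_rng(seed)
    cls = np.where(rng.random(n) < 0.5, "simvastatin", "atorvastatin")
    x = rng.integers(0, 2, n)  # binary covariate (e.g. diabetes flag)
    if confounded:
        # covariate shifts both treatment and hazard
        cls = np.where(rng.random(n) < 0.3 + 0.4 * x, "atorvastatin", "simvastatin")
    base = 1 / 500.0
    rate = base * np.exp(np.log(hr_b) * (cls == "atorvastatin") + 0.7 * x)
    times = rng.exponential(1 / rate)
    cens = rng.uniform(200, 1100, n)
    return pd.DataFrame(
        {
            "duration": np.minimum(times, cens),
            "event": (times <= cens).astype(int),
            "index_class": cls,
            "flag_diabetes": x.astype(bool),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        }
    )


def test_ipw_null_weights_near_one():
    df = _cox_table(4_000, 30)
    w, diag = ipw_weights(df, covariates=["sex", "flag_diabetes"])
    assert abs(w.mean() - 1.0) < 0.02
    for cls, grp in df.groupby("index_class"):
        assert w[grp.index].sum() == pytest.approx(len(grp), rel=0.05)


def test_ipw_small_class_warns():
    df = _cox_table(400, 31)
    df.loc[df.index[:5], "index_class"] = "fluvastatin"
    with pytest.warns(UserWarning, match="<25"):
        ipw_weights(df, covariates=["sex", "flag_diabetes"])


def test_ipw_reduces_covariate_imbalance():
    df = _cox_table(6_000, 32, confounded=True)
    w, diag = ipw_weights(df, covariates=["flag_diabetes"])
    assert diag.loc["flag_diabetes", "smd_weighted"] < diag.loc[
        "flag_diabetes", "smd_unweighted"
    ]


# --------------------------------------------------------------------- Cox

def test_cox_null_hr_near_one():
    df = _cox_table(4_000, 33, hr_b=1.0)
    res = fit_cox_ipw(df)
    row = res.hr_table.set_index("term").loc["index_class_atorvastatin"]
    assert row["ci_low"] < 1.0 < row["ci_high"]
    assert abs(np.log(row["HR"])) < 0.15


def test_cox_positive_duration_required():
    df = _cox_table(100, 34)
    df.loc[0, "duration"] = 0.0
    with pytest.raises(ValueError, match="positive"):
        AdherenceTransitionCox(df)


def test_cox_time_dependent_reports_interactions():
    df = _cox_table(1_500, 35, hr_b=0.8)
    res = fit_cox_ipw(df, time_dependent=True)
    terms = set(res.hr_table["term"])
    assert "index_class_atorvastatin" in terms
    assert "index_class_atorvastatin:log_t" in terms


def test_schoenfeld_diagnostic_runs():
    df = _cox_table(1_000, 36)
    model = AdherenceTransitionCox(df)
    tab = model.schoenfeld_test()
    assert "p" in tab.columns


# ----------------------------------------------------- transition table

def test_adherence_transition_table_event_timing():
    cohort = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "index_day": [0, 0, 0],
            "last_record_day": [2000, 2000, 900],
            "index_class": "simvastatin",
            "sex": "female",
            "age_group": "40-69",
            "calendar_period": "2010-2020",
        }
    )
    yearly = pd.DataFrame(
        {
            "patient_id": ["A", "A", "B"],
            "year": [1, 2, 1],
            "adherence": [0.5, 0.9, 0.4],
            "high": [False, True, False],
        }
    )
    persistence = pd.Series({"A": 900, "B": 500, "C": 2000})
    tab = adherence_transition_table(cohort, yearly, persistence)
    tab = tab.set_index("patient_id")
    # A converts to high adherence in year 2 -> event at day 720
    assert tab.loc["A", "event"] == 1 and tab.loc["A", "duration"] == 720
    # B never converts -> censored at persistence end
    assert tab.loc["B", "event"] == 0 and tab.loc["B", "duration"] == 500
    # C's records span < 3 years and persistence > horizon -> excluded
    assert "C" not in tab.index
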