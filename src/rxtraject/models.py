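"""Risk-prediction and survival layer.

Multivariable logistic models for binary adherence and the four
drug-utilisation patterns (with a Lasso variant for feature selection),
Kaplan-Meier estimation of remaining in low adherence, and inverse
probability weighted (IPW) Cox regression of the transition to high
adherence, with and without time-dependent treatment effects.

The modelling surface follows the Model/Results convention: build a model
from a cohort-level DataFrame, call ``fit()``, and read estimates,
intervals and diagnostics off the results object (``summary()`` gives the
full table).  Reference levels are fixed: simvastatin for treatment class,
low adherence, female sex, the 18-39 age band, absent comorbidity flags
and the 1996-2000 calendar period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .cohort import AGE_GROUPS, CALENDAR_PERIODS
from .vocab import COMEDICATION_GROUPS

OUTCOMES = (
    "high_adherence",
    "continuation",
    "discontinuation",
    "switch",
    "add_on",
    "high_adherence_3yr",
)

REFERENCE_LEVELS = {
    "index_class": "simvastatin",
    "adherence": "low",
    "sex": "female",
    "age_group": AGE_GROUPS[0],
    "calendar_period": CALENDAR_PERIODS[0],
}

CATEGORY_ORDERS = {
    "index_class": ["simvastatin", "atorvastatin", "fibrates", "fluvastatin",
                    "pravastatin", "rosuvastatin"],
    "adherence": ["low", "high"],
    "sex": ["female", "male"],
    "age_group": list(AGE_GROUPS),
    "calendar_period": list(CALENDAR_PERIODS),
}

DEFAULT_COVARIATES = (
    ["index_class", "adherence", "sex", "age_group"]
    + [f"flag_{g}" for g in COMEDICATION_GROUPS]
    + ["calendar_period"]
)


@dataclass
class ModelDesign:
    """Outcome + covariate specification with the fixed reference levels."""

    outcome: str
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    split_ratio: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        # adherence never explains itself
        if self.outcome in ("high_adherence", "high_adherence_3yr"):
            self.covariates = [c for c in self.covariates if c != "adherence"]


def build_design_matrix(table: pd.DataFrame, covariates) -> pd.DataFrame:
    """Intercept + dummy columns, reference levels dropped."""
    cols = [pd.Series(1.0, index=table.index, name="intercept")]
    for cov in covariates:
        if cov in CATEGORY_ORDERS:
            cat = pd.Categorical(table[cov], categories=CATEGORY_ORDERS[cov])
            if cat.isna().any():
                bad = sorted(set(table[cov]) - set(CATEGORY_ORDERS[cov]))
                raise ValueError(f"unknown level(s) {bad} in {cov!r}")
            dummies = pd.get_dummies(cat, prefix=cov, drop_first=True, dtype=float)
            dummies.index = table.index
            cols.append(dummies)
        else:
            cols.append(table[cov].astype(float).rename(cov))
    return pd.concat(cols, axis=1)


def split_train_test(table: pd.DataFrame, ratio: float = 0.7, seed: int = 0):
    """Seed-reproducible disjoint, exhaustive split (7:3 by default)."""
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(ratio * n))
    return (
        table.iloc[perm[:n_train]].reset_index(drop=True),
        table.iloc[perm[n_train:]].reset_index(drop=True),
    )


class LogitResults:
    """Fitted logistic model: ORs, Wald 95% CIs, p-values, diagnostics."""

    def __init__(self, design: ModelDesign, sm_results, columns, separation: bool):
        self.design = design
        self._res = sm_results
        self.columns = list(columns)
        self.separation_flag = separation
        self.params = pd.Series(sm_results.params, index=self.columns)
        self.bse = pd.Series(sm_results.bse, index=self.columns)
        self.pvalues = pd.Series(sm_results.pvalues, index=self.columns)
        ci = np.asarray(sm_results.conf_int())
        self.or_table = pd.DataFrame(
            {
                "term": self.columns,
                "OR": np.exp(self.params.values),
                "ci_low": np.exp(ci[:, 0]),
                "ci_high": np.exp(ci[:, 1]),
                "p": self.pvalues.values,
            }
        )
        self.metrics: dict = {}

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = build_design_matrix(table, self.design.covariates)
        X = X.reindex(columns=self.columns, fill_value=0.0)
        return np.asarray(self._res.predict(X))

    def odds_ratio(self, term: str) -> float:
        return float(np.exp(self.params[term]))

    def summary(self) -> pd.DataFrame:
        tab = self.or_table.copy()
        for key, val in self.metrics.items():
            tab.attrs[key] = val
        return tab


class PatternLogit:
    """Maximum-likelihood logistic risk model for one binary outcome."""

    def __init__(self, data: pd.DataFrame, design: ModelDesign):
        self.design = design
        self.data = data
        y = data[design.outcome]
        if y.nunique() < 2:
            raise ValueError(f"outcome {design.outcome!r} is constant in the data")
        self.endog = y.astype(float).to_numpy()
        self.exog = build_design_matrix(data, design.covariates)
        empty = [c for c in self.exog.columns
                 if c != "intercept" and (self.exog[c] == 0).all()]
        if empty:
            warnings.warn(f"dropping unobserved level(s): {empty}", stacklevel=2)
            self.exog = self.exog.drop(columns=empty)
        rank = np.linalg.matrix_rank(self.exog.to_numpy())
        if rank < self.exog.shape[1]:
            # name the collinear terms via the QR diagonal
            _q, r = np.linalg.qr(self.exog.to_numpy())
            bad = [c for c, d in zip(self.exog.columns, np.abs(np.diag(r))) if d < 1e-8]
            raise ValueError(f"singular design matrix; collinear term(s): {bad}")

    def fit(self) -> LogitResults:
        hard_separation = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = sm.Logit(self.endog, self.exog.to_numpy())
            try:
                res = model.fit(disp=0, maxiter=200)
            except np.linalg.LinAlgError:
                # Newton's Hessian is singular under (quasi-)complete
                # separation; BFGS still yields usable (flagged) estimates
                hard_separation = True
                res = model.fit(method="bfgs", disp=0, maxiter=500)
        separation = (
            hard_separation
            or any("separation" in str(w.message).lower() for w in caught)
            or not res.mle_retvals.get("converged", True)
            or bool(np.max(np.abs(res.params)) > 15)
        )
        if separation:
            warnings.warn("possible complete separation; estimates flagged", stacklevel=2)
        return LogitResults(self.design, res, self.exog.columns, separation)


def fit_logistic(design: ModelDesign, train: pd.DataFrame) -> LogitResults:
    """Fit the multivariable logistic model on the training table."""
    return PatternLogit(train, design).fit()


def evaluate(fit: LogitResults, test: pd.DataFrame, cutoff: float = 0.5) -> dict:
    """AUC (pairwise concordance, ties count 1/2) and sensitivity /
    specificity at the probability cutoff; AUC is NaN for a single-class
    test set."""
    y = test[fit.design.outcome].astype(int).to_numpy()
    p = fit.predict(test)
    out: dict = {"n_test": len(y)}
    out["auc"] = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else float("nan")
    pred = p >= cutoff
    tp, fn = int((pred & (y == 1)).sum()), int((~pred & (y == 1)).sum())
    tn, fp = int((~pred & (y == 0)).sum()), int((pred & (y == 0)).sum())
    out["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
    out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    fit.metrics.update(out)
    return out


def hosmer_lemeshow(y, p, g: int = 10):
    """Hosmer-Lemeshow calibration statistic and chi-square p-value.

    Groups are deciles of predicted risk (quantile boundaries, ties kept
    together; ``g`` is reduced with a warning when ties or sparsity leave
    fewer groups).  statistic = sum (O-E)^2 / (E (1 - E/n_g)), df = g-2.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if len(y) < 5 * g:
        warnings.warn(f"sparse groups: n={len(y)} with g={g}", stacklevel=2)
    groups = pd.qcut(p, g, labels=False, duplicates="drop")
    g_eff = int(pd.Series(groups).nunique())
    if g_eff < g:
        warnings.warn(f"tied quantiles reduced groups from {g} to {g_eff}", stacklevel=2)
    if g_eff < 2:
        raise ValueError("fewer than 2 distinct risk groups")
    stat = 0.0
    for k in range(g_eff):
        sel = groups == k
        n_g = int(sel.sum())
        obs = float(y[sel].sum())
        exp = float(p[sel].sum())
        denom = exp * (1.0 - exp / n_g)
        if denom > 0:
            stat += (obs - exp) ** 2 / denom
    df = g_eff - 2
    if df > 0:
        pval = float(stats.chi2.sf(stat, df))
    else:
        # chi-square with 0 df is degenerate at 0
        pval = 1.0 if stat <= 1e-12 else float("nan")
    return float(stat), pval


def fit_lasso(
    design: ModelDesign,
    table: pd.DataFrame,
    lambda_grid=None,
    seed: int = 0,
    cv: int = 10,
):
    """L1-penalised logistic path with cross-validated penalty.

    Features are standardised before penalisation; the penalty is chosen
    by ``cv``-fold cross-validated deviance; the selected terms are then
    refit unpenalised for odds ratios.  Returns ``(selected_terms,
    LogitResults)``; an all-zero selection yields an intercept-only model.
    """
    y = table[design.outcome].astype(int).to_numpy()
    X = build_design_matrix(table, design.covariates).drop(columns="intercept")
    mu, sd = X.mean(), X.std(ddof=0).replace(0, 1.0)
    Z = (X - mu) / sd
    Cs = 1.0 / np.asarray(lambda_grid) if lambda_grid is not None else np.logspace(-3, 3, 20)
    clf = LogisticRegressionCV(
        Cs=Cs,
        cv=KFold(cv, shuffle=True, random_state=seed),
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=2000,
        refit=True,
    )
    clf.fit(Z.to_numpy(), y)
    coef = clf.coef_.ravel()
    selected = [c for c, b in zip(Z.columns, coef) if abs(b) > 1e-8]

    refit_design = ModelDesign(design.outcome, covariates=[], seed=seed)
    exog = pd.concat(
        [pd.Series(1.0, index=table.index, name="intercept"), X[selected]], axis=1
    )
    res = sm.Logit(y.astype(float), exog.to_numpy()).fit(disp=0, maxiter=200)
    out = LogitResults(refit_design, res, exog.columns, separation=False)
    out.metrics["lambda"] = float(1.0 / clf.C_[0])
    return selected, out


def km_low_adherence(
    data: pd.DataFrame,
    duration_col: str = "duration",
    event_col: str = "event",
    group_col: str | None = "index_class",
):
    """Kaplan-Meier curves of remaining in low adherence, per treatment.

    Event = first transition to high adherence; censoring at the end of
    the 3-year window.  Returns ``(curve_table, fitters)`` where the curve
    table has columns ``group, time, survival, at_risk``.
    """
    fitters: dict[str, KaplanMeierFitter] = {}
    frames = []
    groups = [None] if group_col is None else sorted(data[group_col].unique())
    for grp in groups:
        sub = data if grp is None else data[data[group_col] == grp]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col], label=str(grp))
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
        frames.append(
            pd.DataFrame(
                {
                    "group": str(grp),
                    "time": surv.index.to_numpy(dtype=float),
                    "survival": surv.to_numpy(),
                    "at_risk": at_risk.to_numpy(),
                }
            )
        )
        fitters[str(grp)] = kmf
    return pd.concat(frames, ignore_index=True), fitters


def plot_km(curves: pd.DataFrame, ax=None):
    """Step plot of the per-class low-adherence survival curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    for grp, sub in curves.groupby("group"):
        ax.step(sub["time"], sub["survival"], where="post", label=grp)
    ax.set_xlabel("days since index")
    ax.set_ylabel("P(still low adherence)")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    return ax


def standardized_mean_differences(
    data: pd.DataFrame, treatment_col: str, covariates, weights=None
) -> pd.Series:
    """Mean absolute pairwise SMD per covariate column (dummy-expanded)."""
    X = build_design_matrix(data, covariates).drop(columns="intercept")
    w = np.ones(len(data)) if weights is None else np.asarray(weights, dtype=float)
    groups = sorted(data[treatment_col].unique())
    out = {}
    for col in X.columns:
        x = X[col].to_numpy()
        means, variances = [], []
        for grp in groups:
            sel = (data[treatment_col] == grp).to_numpy()
            ww = w[sel]
            m = np.average(x[sel], weights=ww)
            v = np.average((x[sel] - m) ** 2, weights=ww)
            means.append(m)
            variances.append(v)
        smds = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pooled = np.sqrt((variances[i] + variances[j]) / 2)
                smds.append(abs(means[i] - means[j]) / pooled if pooled > 0 else 0.0)
        out[col] = float(np.mean(smds))
    return pd.Series(out)


def ipw_weights(
    data: pd.DataFrame,
    treatment_col: str = "index_class",
    covariates=None,
    truncate: tuple[float, float] = (1.0, 99.0),
):
    """Stabilised inverse-probability-of-treatment weights.

    A multinomial-logistic propensity model over the treatment classes;
    weight = marginal class probability / fitted probability of the
    received class, truncated at the given percentiles.  Returns
    ``(weights, diagnostics)`` where diagnostics carries pre/post-weighting
    standardised mean differences.
    """
    covariates = covariates or [c for c in DEFAULT_COVARIATES
                                if c not in ("index_class", "adherence")]
    counts = data[treatment_col].value_counts()
    small = counts[counts < 25]
    if len(small):
        warnings.warn(
            f"treatment class(es) with <25 subjects: {small.index.tolist()}; "
            "propensities may be unstable",
            stacklevel=2,
        )
    X = build_design_matrix(data, covariates).drop(columns="intercept").to_numpy()
    y = data[treatment_col].to_numpy()
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    clf.fit(X, y)
    prob = clf.predict_proba(X)
    class_idx = {c: i for i, c in enumerate(clf.classes_)}
    p_received = prob[np.arange(len(y)), [class_idx[c] for c in y]]
    marginal = data[treatment_col].map(counts / len(data)).to_numpy()
    w = marginal / p_received
    lo, hi = np.percentile(w, truncate)
    w = np.clip(w, lo, hi)
    weights = pd.Series(w, index=data.index, name="ipw")
    diagnostics = pd.DataFrame(
        {
            "smd_unweighted": standardized_mean_differences(data, treatment_col, covariates),
            "smd_weighted": standardized_mean_differences(
                data, treatment_col, covariates, weights=w
            ),
        }
    )
    return weights, diagnostics


class CoxResults:
    """Hazard ratios with 95% CIs from a (weighted) Cox fit."""

    def __init__(self, summary: pd.DataFrame, fitter, time_dependent: bool):
        self.fitter = fitter
        self.time_dependent = time_dependent
        self.hr_table = pd.DataFrame(
            {
                "term": summary.index,
                "HR": np.exp(summary["coef"].to_numpy()),
                "ci_low": np.exp(summary["coef lower 95%"].to_numpy()),
                "ci_high": np.exp(summary["coef upper 95%"].to_numpy()),
                "p": summary["p"].to_numpy(),
            }
        ).reset_index(drop=True)

    def hazard_ratio(self, term: str) -> float:
        row = self.hr_table[self.hr_table["term"] == term]
        return float(row["HR"].iloc[0])

    def summary(self) -> pd.DataFrame:
        return self.hr_table.copy()


class AdherenceTransitionCox:
    """Cox model of the transition to high adherence across treatments.

    Duration/event columns come from the 3-year transition table; the
    treatment class enters as dummies against simvastatin.  ``fit`` runs
    the weighted partial likelihood with robust (sandwich) variance when
    IPW weights are supplied; the time-dependent variant adds treatment x
    log(time) interactions via yearly episode splitting.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        duration_col: str = "duration",
        event_col: str = "event",
        treatment_col: str = "index_class",
    ):
        if (data[duration_col] <= 0).any():
            raise ValueError("event/censoring times must be positive")
        self.data = data.reset_index(drop=True)
        self.duration_col = duration_col
        self.event_col = event_col
        self.treatment_col = treatment_col
        cat = pd.Categorical(
            self.data[treatment_col],
            categories=[c for c in CATEGORY_ORDERS["index_class"]
                        if c in set(self.data[treatment_col])],
        )
        self.dummies = pd.get_dummies(cat, prefix=treatment_col, drop_first=True, dtype=float)
        no_event = [
            c for c in cat.categories
            if self.data.loc[self.data[treatment_col] == c, event_col].sum() == 0
        ]
        if no_event:
            warnings.warn(
                f"class(es) without events: {no_event}; their HRs are unidentified",
                stacklevel=2,
            )

    def fit(self, weights=None, time_dependent: bool = False) -> CoxResults:
        if time_dependent:
            return self._fit_time_dependent(weights)
        df = pd.concat(
            [self.data[[self.duration_col, self.event_col]], self.dummies], axis=1
        )
        kwargs = {}
        if weights is not None:
            df["ipw"] = np.asarray(weights, dtype=float)
            kwargs = {"weights_col": "ipw", "robust": True}
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=self.duration_col, event_col=self.event_col, **kwargs)
        return CoxResults(cph.summary, cph, time_dependent=False)

    def _fit_time_dependent(self, weights=None, episode_days: int = 360) -> CoxResults:
        # episode splitting at yearly boundaries; interaction uses the
        # log of the episode end time
        rows = []
        w = np.ones(len(self.data)) if weights is None else np.asarray(weights, dtype=float)
        for i, row in self.data.iterrows():
            dur = float(row[self.duration_col])
            ev = int(row[self.event_col])
            start = 0.0
            while start < dur:
                stop = min(start + episode_days, dur)
                rec = {
                    "id": i,
                    "start": start,
                    "stop": stop,
                    "event": ev if stop >= dur else 0,
                    "ipw": w[i],
                }
                for c in self.dummies.columns:
                    rec[c] = row_d = self.dummies.iloc[i][c]
                    rec[f"{c}:log_t"] = row_d * np.log(stop)
                rows.append(rec)
                start = stop
        long = pd.DataFrame(rows)
        ctv = CoxTimeVaryingFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(
                long,
                id_col="id",
                start_col="start",
                stop_col="stop",
                event_col="event",
                weights_col="ipw",
            )
        return CoxResults(ctv.summary, ctv, time_dependent=True)

    def schoenfeld_test(self) -> pd.DataFrame:
        """Proportional-hazards diagnostic (Schoenfeld residual test)."""
        from lifelines.statistics import proportional_hazard_test

        res = self.fit()
        df = pd.concat(
            [self.data[[self.duration_col, self.event_col]], self.dummies], axis=1
        )
        cph = CoxPHFitter().fit(df, self.duration_col, self.event_col)
        test = proportional_hazard_test(cph, df, time_transform="log")
        return test.summary


def fit_cox_ipw(
    data: pd.DataFrame,
    weights=None,
    time_dependent: bool = False,
    duration_col: str = "duration",
    event_col: str = "event",
    treatment_col: str = "index_class",
) -> CoxResults:
    """Convenience wrapper: (IPW-)weighted Cox fit with robust variance."""
    model = AdherenceTransitionCox(data, duration_col, event_col, treatment_col)
    return model.fit(weights=weights, time_dependent=time_dependent)


def adherence_transition_table(
    cohort: pd.DataFrame,
    yearly: pd.DataFrame,
    persistence: pd.Series,
    horizon_years: int = 3,
    year_days: int = 360,
) -> pd.DataFrame:
    """Duration/event table for the 3-year low-to-high adherence analysis.

    Event time = end of the first 360-day year with adherence >= 0.8;
    censoring at the earlier of persistence end and the 3-year mark.
    Population: database records span more than ``horizon_years`` from
    index and time on the original monotherapy is at most that horizon.
    """
    horizon = horizon_years * year_days
    first_high = (
        yearly[yearly["high"] & (yearly["year"] <= horizon_years)]
        .groupby("patient_id")["year"]
        .min()
    )
    rows = []
    for _, ent in cohort.iterrows():
        pid = ent["patient_id"]
        pers = int(persistence.loc[pid])
        span = int(ent["last_record_day"]) - int(ent["index_day"])
        if span <= horizon or pers > horizon:
            continue
        if pid in first_high.index:
            duration, event = int(first_high.loc[pid]) * year_days, 1
        else:
            duration, event = min(pers, horizon), 0
        rows.append({"patient_id": pid, "duration": duration, "event": event})
    out = pd.DataFrame(rows, columns=["patient_id", "duration", "event"])
    keep = [c for c in cohort.columns
            if c in ("patient_id", "index_class", "sex", "age_group", "calendar_period")
            or c.startswith("flag_")]
    return out.merge(cohort[keep], on="patient_id")
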