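# rxtraject

Trajectory reconstruction, adherence metrics, drug-utilisation pattern
classification and risk modelling for **new users of lipid-lowering
monotherapy** (five statin compounds — simvastatin C10AA01, pravastatin
C10AA03, fluvastatin C10AA04, atorvastatin C10AA05, rosuvastatin C10AA07 —
plus fibrates C10AB), built for pharmacoepidemiologists working with
longitudinal community-pharmacy dispensing records.

Real dispensing databases of this kind are typically proprietary, so the
package ships a first-class **synthetic dispensing-data generator** with
planted ground truth (trajectory archetypes, latent adherence classes,
covariate effects), letting every downstream stage be validated against a
known answer.

## What it computes

Starting from two delimited tables — dispensings
(`patient_id,date,atc,strength_mg,units,days_supplied`) and patients
(`patient_id,birth_date,sex`) — the pipeline:

1. **Cohort** — inception (new-user) design: index at the first-ever
   study-class dispensing; require age ≥ 18, ≥ 2 years of database history
   before index, ≥ 1 year of records after, and ≥ 3 index-class dispensings
   in the first year (360 days ≡ 1 year throughout); exclude
   antihypertensive use in the first year and acute-cardiac therapy from
   2 years before to 90 days after index; follow-up ends at the earliest of
   study end, a cardiovascular-event proxy, the final run-out, or a
   treatment change, capped at ~10 years.
2. **Coverage & adherence** — dispensings merge into half-open coverage
   intervals with a 90-day stockpile carryover cap. Yearly adherence is a
   PDC-style ratio: covered days in year *k* / 360, dichotomised at
   **0.8 (inclusive)**; also the prevalence of high adherence per year and
   a 3-year follow-up-window variant.
3. **Patterns** — per patient: *discontinuation* (index-supply gap
   **strictly > 180 days**), *switch* (different class or fixed combination
   **within 180 days** after discontinuation), *add-on* (second class
   dispensed while index supply is active, before any discontinuation),
   *continuation* (none of the above); rate tables by index class.
4. **Equivalent doses** — daily dose = strength × units / days supplied,
   mapped to low/medium/high tiers by expected LDL-reduction band
   (<30%, 30–45%, >45%), with dose-transition labels for switch/add-on
   sensitivity analyses.
5. **Models** — multivariable logistic risk models (Model/Results style:
   `PatternLogit(...).fit()` → OR table, Wald 95% CIs) with a 7:3
   train/test split, AUC, sensitivity/specificity and a Hosmer–Lemeshow
   calibration test; a Lasso variant for feature selection; Kaplan–Meier
   curves of remaining in low adherence; and stabilised-IPW-weighted Cox
   regression of the transition to high adherence, with and without
   treatment × log(time) effects. Reference levels are fixed:
   simvastatin, low adherence, female, age 18–39, flags absent, 1996–2000.

## Worked example

```python
from rxtraject import (GeneratorConfig, generate_population, run_pipeline,
                       ModelDesign, fit_logistic, split_train_test, evaluate)
from rxtraject.patterns import pattern_rate_table
from rxtraject.adherence import prevalence_by_year

patients, dispensing, labels = generate_population(GeneratorConfig(n_patients=2000, seed=42))
res = run_pipeline(dispensing, patients)

print(res.attrition)
#                        rule  n_excluded  n_remaining
#                   new_users           0         2000
# antihypertensive_first_year          32         1968
#              cardiac_window          36         1932

print(pattern_rate_table(res.assessments, res.cohort).iloc[:, :2])
#                 Overall (N=1932) simvastatin (N=1511)
# Continuation         810 (41.9%)          644 (42.6%)
# Discontinuation      877 (45.4%)          678 (44.9%)
# Switch               334 (17.3%)          259 (17.1%)
# Add on               245 (12.7%)          189 (12.5%)

print(prevalence_by_year(res.yearly, 2))
#  year  n_high  n_at_risk  prevalence
#     1    1616       1932    0.836439
#     2    1271       1507    0.843397

design = ModelDesign("high_adherence", covariates=["sex", "age_group", "flag_diabetes"])
train, test = split_train_test(res.model_table, 0.7, seed=0)
fit = fit_logistic(design, train)
print(fit.or_table.round(3))
#            term    OR  ci_low  ci_high     p
#       intercept 2.350   1.663    3.321 0.000
#        sex_male 0.928   0.695    1.239 0.612
# age_group_40-69 2.474   1.725    3.549 0.000
#  age_group_>=70 2.833   1.822    4.405 0.000
#   flag_diabetes 1.147   0.701    1.879 0.585
print(evaluate(fit, test))
# {'n_test': 580, 'auc': 0.518, 'sensitivity': 1.0, 'specificity': 0.0}
```

The attrition table shows the planted exclusion violations being removed;
the year-1 prevalence of high adherence sits at the generator's calibrated
83.6%; the odds ratios recover the planted covariate effects (here age and
diabetes at their defaults, sex near null at this sample size); and the
near-degenerate sensitivity/specificity at the 0.5 cutoff is what weakly
discriminating risk models produce when the outcome is common.

A CLI mirrors the library: `rxtraject simulate`, `rxtraject cohort`,
`rxtraject patterns`, `rxtraject fit --outcome continuation ...`.

## Layout

- `src/rxtraject/simulate.py` — synthetic generator (archetypes + planted effects)
- `src/rxtraject/io.py`, `vocab.py` — CSV schemas, ATC prefix vocabulary
- `src/rxtraject/cohort.py` — inclusion/exclusion, follow-up, covariates
- `src/rxtraject/coverage.py`, `adherence.py` — supply intervals, PDC metrics
- `src/rxtraject/patterns.py` — pattern classification and rate tables
- `src/rxtraject/eqd.py` — equivalent-dose tiers and transitions
- `src/rxtraject/models.py` — logistic/Lasso/KM/IPW-Cox layer
- `docs/methods.md` — modelling assumptions, defaults and limitations
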