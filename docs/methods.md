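# Methods

## Time and intervals

All dates are handled internally as integer day offsets; every window is
half-open `[start, end)`. A "year" is 360 days and a "half year" 180 days,
so the ~10-year follow-up cap is 3780 days. Calendar periods
(1996–2000, 2000–2010, 2010–2020) are half-open bins with boundary years
assigned to the later period.

## Cohort definition

Index date is the first-ever dispensing of a study class. Entry requires:
exactly one study class begun on the index day (same-day dual initiation
is not monotherapy and is excluded), age ≥ 18 at index (the inclusive
reading of "adult"; configurable), first database record ≥ 720 days
before index, a record ≥ 360 days after, and ≥ 3 index-class dispensings
in `[index, index+360)`. "Database history" is operationalised as the
first dispensing on record, since a registration date is not part of the
input schema. Exclusions: any antihypertensive-list dispensing in
`[index, index+360)`; any acute-cardiac-list dispensing in
`[index−720, index+90)`. The cardiac ATC lists (defaults: C01, B01A) are
placeholder reconstructions — the original convention is not public — and
should be overridden for real analyses; the antihypertensive list is
C02/C03/C07/C08/C09 plus fixed lipid combinations C10BX/C10BA.

Follow-up ends at the earliest of: study end (2020-12-31) or the 3780-day
cap (both reported as `study_end`), the first cardiac-proxy dispensing
after index (dispensing data carry no diagnoses, so a drug-list proxy
stands in for a cardiovascular event; it can be disabled), the run-out of
the final index-class dispensing, or the first dispensing of a different
study class / fixed combination. Ties resolve in that order.

## Coverage and adherence

Each dispensing contributes `days_supplied` covered days. A refill before
run-out is carried forward — it starts at the previous run-out — with the
carried surplus capped at a 90-day stockpile (configurable; 0 reproduces
pure truncation). The cap choice is a compromise: truncation undercounts
covered days for early refillers, unbounded carryover lets adherence grow
without limit. Under the default cap a 360-day year holds at most 450
covered days, so yearly adherence ≤ 1.25; values are **not** clipped
before averaging but are dichotomised at 0.8 (inclusive) as printed.

Year *k* adherence is defined only for patients on the original
monotherapy beyond *k* years — no discontinuation, switch or add-on event
before `index + k*360` — so non-persisters leave the denominator rather
than contributing zeros. The same persistence rule defines the prevalence
denominators. The 3-year window outcome uses covered days over the actual
follow-up (capped at 1080 days) divided by follow-up days, in patients
whose records span more than 3 years while persistence is at most 3 years.

## Pattern classification

Discontinuation is a supply gap strictly exceeding 180 days, measured
from a run-out (coverage-interval end) to the next index-class
dispensing, or from the final run-out to the follow-up cap; the
discontinuation date is the run-out opening the gap. Measuring from
run-out rather than the dispensing date matches the "stopped using"
reading; a last-dispensing-date mode is available. Switch requires a
different study class or fixed combination within 180 days (inclusive)
after the discontinuation date; add-on requires one strictly inside an
active coverage interval and before any discontinuation (a looser
any-time-before-discontinuation mode exists for short-gap edge cases).
Continuation is the absence of all three through the follow-up cap. Dose
changes within the same compound never break continuation; dose-level
transitions are the equivalent-dose module's concern. Flags are
non-exclusive apart from the structural implications (switch ⇒
discontinuation; continuation excludes everything), which are asserted on
every run. Events are "any during follow-up", not first-event-only.

## Equivalent doses

Daily dose = strength × units / days supplied; records missing strength
or units are excluded with a count. Tiers follow standard
statin-intensity bands (simvastatin 10 low, 20–40 medium; atorvastatin
10–20 medium, 40–80 high; rosuvastatin 5–10 medium, 20–40 high;
pravastatin 10–20 low, 40–80 medium; fluvastatin 20–40 low, 80 medium),
monotone-extended outside the table (above the top band → high, below the
bottom → low, gaps inherit the band below). The exact published cut-offs
for the LDL-reduction scheme are not reproduced anywhere public, so this
table is an explicit reconstruction and fully overridable; fibrates have
no LDL equivalence and sit in a single tier with a warning.

## Statistical layer

Logistic models are maximum-likelihood fits (statsmodels) with Wald 95%
CIs on the OR scale — Wald rather than profile to match conventional
reporting. Complete separation is detected (singular Hessian, failed
convergence, or |log-OR| > 15) and flagged, with a BFGS fallback so a
flagged fit is still returned. Reference levels are fixed exactly as in
the main analysis: simvastatin / low adherence / female / 18–39 / flags
absent / 1996–2000; adherence is dropped as a covariate when it is the
outcome. Data are split 7:3 by seeded permutation. AUC uses the pairwise
concordance convention (ties count ½); sensitivity/specificity use a 0.5
probability cutoff by default (no cutoff was stated for the original
analysis; with a common outcome this yields near-degenerate pairs such as
1.0/0.0, which is a property of the convention, not a bug).
Hosmer–Lemeshow groups are risk deciles (quantiles, ties kept together,
`g` reduced with a warning), statistic Σ(O−E)²/(E(1−E/n_g)), df = g−2;
with df = 0 the statistic is degenerate and p = 1 iff the statistic is 0.

The Lasso variant standardises all columns (dummies included), picks the
penalty by k-fold (default 10) cross-validated deviance with seeded
folds, and refits the selected terms unpenalised for ORs; an empty
selection returns the intercept-only model.

IPW uses an unpenalised multinomial-logistic propensity over the
treatment classes; weights are stabilised (marginal class probability /
fitted probability) and truncated at the 1st/99th percentiles; classes
under 25 subjects trigger a warning; pre/post standardised mean
differences (mean absolute pairwise SMD across classes) are reported. The
Cox fit is a weighted partial likelihood with robust sandwich variance
(lifelines). Time-dependent effects — named but not constructed in the
source analysis — are operationalised as treatment × log(time)
interactions via yearly episode splitting; a Schoenfeld-residual
diagnostic is also available. The transition-to-high-adherence event time
is the end of the first 360-day year with adherence ≥ 0.8 (the yearly
metric is the finest granularity the adherence definition supports),
censored at the earlier of persistence end and 3 years.

## Synthetic data generator

The generator emulates a 1996–2020 community-pharmacy database of new
statin/fibrate users. Per patient it draws: an index date with a 2-year
lookback inside the study window; a drug class (shares matching the
observed cohort composition, ~79% simvastatin); a trajectory archetype
(continuer .38 / discontinuer .28 / switcher .18 / add-on .13 /
intermittent .03, approximating the observed pattern rates); sex
(Bernoulli 0.5); an age band (15/60/25% over 18–39/40–69/≥70, uniform
within bands); nine independent baseline comorbidity flags realised as
dispensing rows in the first 180 days; and a latent high/low adherence
class from a logistic model with planted odds ratios (defaults: male
0.79, age 40–69 1.68, age ≥70 2.46, diabetes 1.17; intercept 1.2256
solved so marginal prevalence of high adherence is 0.836 under this mix).

Adherence is realised by **thinning refills**, not shortening supplies:
the refill interval is `ceil(days_supplied / target_pdc)` with targets
drawn from [0.85, 0.99] (high) or [0.40, 0.75] (low) and the interval
capped at 120 days so every patient clears the 3-fills-in-year-1 rule.
With supplies of 30/60/90 days this guarantees the realised year-1 PDC
falls on the planted side of the 0.8 threshold, so planted effects pass
through the full pipeline without attenuation — which is what makes
parameter-recovery checks exact rather than approximate. Archetypes are
deterministic schedules: discontinuers stop at a drawn day ≥ 480 leaving
a confirmable >180-day gap; switchers add a different class 30–150 days
after run-out; add-on patients start a second class strictly inside
active coverage around day 380; intermittents carry a 160-day
(sub-threshold) gap in year 2. A configurable fraction (default 3%) of
patients carries a planted exclusion violation. Background analgesic
dispensings mark database presence before and after index. Ground truth
(archetype, expected flags, adherence class, covariates, violator status)
goes to a separate labels table, never into the analysis inputs.

What the generator does **not** emulate: refill-timing noise beyond the
deterministic schedules (no published distribution exists to calibrate
against), correlated comorbidities, dose titration within a compound,
re-initiation after discontinuation, seasonal or secular prescribing
trends, and hospital dispensing (absent from community-pharmacy data).
Passing tests therefore demonstrate correctness of the *definitions and
estimators* under controlled conditions, not fidelity to any particular
real database.

## Problem sizes and numerical choices

Validation runs use: 1,300 patients for archetype-agreement checks
(≥1,000 eligible traces), 300 randomised traces against the day-by-day
brute-force oracle, 50,000 patients for logistic planted-OR recovery
through the full pipeline, 20,000 simulated subjects for Cox HR recovery,
500 replicates of n=400 for the null Wald size check, and 20 replicates
of n=4,000 with 15 features for Lasso selection rates. Quantile ties in
Hosmer–Lemeshow grouping reduce `g` rather than erroring; empty pattern
classes format as a bare count with no percentage.

## Known limitations

The cardiac exclusion lists and the equivalent-dose cut-offs are
reconstructions (flagged above). The cohort cannot distinguish database
registration from first dispensing. The cardiovascular-event proxy is a
drug-list surrogate. Fibrate dose tiers are undefined. The generator's
archetype realisations are deterministic given the draws, which is a
feature for validation but understates real-world heterogeneity.
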