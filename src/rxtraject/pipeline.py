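"""End-to-end convenience layer tying the pipeline stages together."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .adherence import (
    index_class_coverage,
    window_adherence_3yr,
    yearly_adherence_table,
)
from .cohort import CohortRules, build_cohort
from .patterns import PatternOptions, classify_patterns_table
from .vocab import AtcVocabulary


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    attrition: pd.DataFrame
    assessments: pd.DataFrame
    coverages: dict
    persistence: pd.Series
    yearly: pd.DataFrame
    model_table: pd.DataFrame
    adherence_3yr: pd.DataFrame


def analysis_table(cohort, assessments, yearly) -> pd.DataFrame:
    """One row per eligible entrant with covariates and all six outcomes.

    Restricted to patients on the original monotherapy for more than one
    year (so year-1 adherence is defined).  ``adherence`` is the year-1
    binary level as a covariate; the ``high_adherence`` outcome is its
    0/1 version.
    """
    y1 = yearly[yearly["year"] == 1][["patient_id", "adherence", "high"]].rename(
        columns={"adherence": "adherence_value", "high": "high_adherence"}
    )
    flags = [c for c in cohort.columns if c.startswith("flag_")]
    base = cohort[
        ["patient_id", "index_class", "sex", "age_group", "calendar_period"] + flags
    ]
    df = base.merge(y1, on="patient_id", how="inner")
    df = df.merge(
        assessments[
            ["patient_id", "eligible", "continuation", "discontinuation", "switch", "add_on"]
        ],
        on="patient_id",
    )
    df = df[df["eligible"]].drop(columns="eligible").reset_index(drop=True)
    df["adherence"] = df["high_adherence"].map({True: "high", False: "low"})
    df["high_adherence"] = df["high_adherence"].astype(int)
    for c in ("continuation", "discontinuation", "switch", "add_on"):
        df[c] = df[c].astype(int)
    return df


def run_pipeline(
    dispensing: pd.DataFrame,
    patients: pd.DataFrame,
    vocab: AtcVocabulary | None = None,
    rules: CohortRules | None = None,
    opts: PatternOptions | None = None,
    n_years: int = 10,
) -> PipelineResult:
    """Cohort -> coverage -> patterns -> adherence -> analysis table."""
    vocab = vocab or AtcVocabulary()
    rules = rules or CohortRules()
    cohort, attrition = build_cohort(dispensing, patients, vocab, rules)
    assessments = classify_patterns_table(cohort, dispensing, vocab, rules, opts)
    persistence = assessments.set_index("patient_id")["persistence_days"]
    coverages = index_class_coverage(cohort, dispensing, vocab, rules)
    yearly = yearly_adherence_table(cohort, coverages, persistence, n_years=n_years)
    table = analysis_table(cohort, assessments, yearly)
    adh3 = window_adherence_3yr(cohort, coverages, persistence)
    return PipelineResult(
        cohort=cohort,
        attrition=attrition,
        assessments=assessments,
        coverages=coverages,
        persistence=persistence,
        yearly=yearly,
        model_table=table,
        adherence_3yr=adh3,
    )
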