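"""Configuration objects for the synthetic dispensing-data generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

ARCHETYPES = ("continuer", "discontinuer", "switcher", "addon", "intermittent")

#: class shares taken from the observed cohort composition
#: (simvastatin-dominated prescribing in the Netherlands, 1996-2020)
DEFAULT_CLASS_PROBS = {
    "simvastatin": 0.7894,
    "atorvastatin": 0.1153,
    "rosuvastatin": 0.0448,
    "pravastatin": 0.0378,
    "fluvastatin": 0.0055,
    "fibrates": 0.0072,
}

DEFAULT_PATTERN_MIX = {
    "continuer": 0.38,
    "discontinuer": 0.28,
    "switcher": 0.18,
    "addon": 0.13,
    "intermittent": 0.03,
}


@dataclass
class PlantedEffects:
    """Odds ratios of the latent high-adherence model used by the generator.

    P(high adherence) = expit(intercept + log(or_male)*male
    + log(or_age_40_69)*[40-69] + log(or_age_70plus)*[>=70]
    + log(or_diabetes)*diabetes).  Defaults are calibrated to the published
    multivariable estimates for these factors; the intercept is solved so
    that the marginal prevalence of high adherence is 0.836 under the
    default covariate mix.
    """

    intercept_logit: float = 1.2256
    or_male: float = 0.79
    or_age_40_69: float = 1.68
    or_age_70plus: float = 2.46
    or_diabetes: float = 1.17
    #: per-drug-class multiplier on the odds of high adherence (all 1 = null)
    class_or: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("or_male", "or_age_40_69", "or_age_70plus", "or_diabetes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(v <= 0 for v in self.class_or.values()):
            raise ValueError("class odds ratios must be > 0")

    @classmethod
    def null(cls) -> "PlantedEffects":
        """All effects off (OR 1) except the intercept."""
        return cls(or_male=1.0, or_age_40_69=1.0, or_age_70plus=1.0, or_diabetes=1.0)


def _check_probs(probs: dict, what: str) -> None:
    vals = np.array(list(probs.values()), dtype=float)
    if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"{what} must be a probability vector summing to 1, got {probs}")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic pharmacy database.

    Defaults emulate a 1996-2020 community-pharmacy dispensing database of
    new statin/fibrate users: index dates spread over the study window with
    a two-year clean lookback, 30/60/90-day supplies, and trajectory
    archetypes mixed to match observed utilisation-pattern rates.
    """

    n_patients: int = 1000
    date_range: tuple[str, str] = ("1996-01-01", "2020-12-31")
    drug_class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    pattern_mix: dict = field(default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    days_supplied_choices: tuple[int, ...] = (30, 60, 90)
    #: mean refill interval is supply/pdc; this caps the low-adherence
    #: interval so every eligible patient has >=3 first-year fills
    max_refill_interval_days: int = 120
    #: age-band shares at index: 18-39, 40-69, >=70
    age_band_probs: tuple[float, float, float] = (0.15, 0.60, 0.25)
    p_male: float = 0.5
    #: marginal prevalence of each baseline drug-treated comorbidity proxy
    comorbidity_probs: dict = field(
        default_factory=lambda: {
            "diabetes": 0.10,
            "ra": 0.01,
            "asthma_copd": 0.05,
            "antiepileptics": 0.02,
            "antiparkinson": 0.01,
            "psycholeptics": 0.08,
            "psychoanaleptics": 0.06,
            "addictive_disorders": 0.01,
            "antineoplastics": 0.005,
        }
    )
    #: fraction of patients planted with a cohort-exclusion violation
    violator_fraction: float = 0.03
    planted_effects: PlantedEffects = field(default_factory=PlantedEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        _check_probs(self.drug_class_probs, "drug_class_probs")
        _check_probs(self.pattern_mix, "pattern_mix")
        if set(self.pattern_mix) - set(ARCHETYPES):
            raise ValueError(f"unknown archetype(s): {set(self.pattern_mix) - set(ARCHETYPES)}")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        start, end = np.datetime64(self.date_range[0]), np.datetime64(self.date_range[1])
        if not start < end:
            raise ValueError("date_range start must precede end")
        if isinstance(self.planted_effects, dict):
            self.planted_effects = PlantedEffects(**self.planted_effects)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
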