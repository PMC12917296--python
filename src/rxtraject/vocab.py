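"""ATC vocabulary: study drug classes, co-medication proxies, exclusion lists.

The study exposure is lipid-lowering monotherapy: five statin compounds
(C10AA01/03/04/05/07) plus the fibrates class (C10AB).  Drug-treated
comorbidity proxies and cohort exclusion rules are expressed as ATC prefix
lists; the source study names the drug groups but not their codes, so the
mappings here are explicit, overridable configuration with shipped defaults.
The acute-cardiac exclusion list in particular is a placeholder
reconstruction (the original convention is not public) and should be
replaced for any real analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: study drug classes, label -> ATC prefix.  Statin compounds are full
#: 7-character codes; fibrates are matched at the chemical-subgroup level.
DEFAULT_STUDY_CLASSES: dict[str, str] = {
    "simvastatin": "C10AA01",
    "pravastatin": "C10AA03",
    "fluvastatin": "C10AA04",
    "atorvastatin": "C10AA05",
    "rosuvastatin": "C10AA07",
    "fibrates": "C10AB",
}

#: fixed-dose lipid-lowering combinations count as a regimen change
#: (switch/add-on target) but never as an index drug.
DEFAULT_FIXED_COMBO_PREFIXES: list[str] = ["C10BX", "C10BA"]

DEFAULT_COMEDICATION_MAP: dict[str, list[str]] = {
    "diabetes": ["A10"],
    "ra": ["M01C", "L04"],
    "asthma_copd": ["R03"],
    "antiepileptics": ["N03"],
    "antiparkinson": ["N04"],
    "psycholeptics": ["N05"],
    "psychoanaleptics": ["N06"],
    "addictive_disorders": ["N07B"],
    "antineoplastics": ["L01"],
}

DEFAULT_EXCLUSION_MAP: dict[str, list[str]] = {
    # anti-hypertensive monotherapy or fixed antihypertensive/lipid combos
    # in the first year after index
    "antihypertensive_first_year": ["C02", "C03", "C07", "C08", "C09"],
    # acute cardiac / possible chronic cardiac therapy in the two years
    # before or 90 days after index (placeholder reconstruction)
    "cardiac_window": ["C01", "B01A"],
}

COMEDICATION_GROUPS = tuple(DEFAULT_COMEDICATION_MAP)


@dataclass
class AtcVocabulary:
    """Prefix-based drug vocabulary used throughout the pipeline."""

    study_classes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STUDY_CLASSES)
    )
    fixed_combo_prefixes: list[str] = field(
        default_factory=lambda: list(DEFAULT_FIXED_COMBO_PREFIXES)
    )
    comedication_map: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_COMEDICATION_MAP.items()}
    )
    exclusion_map: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_EXCLUSION_MAP.items()}
    )

    def __post_init__(self) -> None:
        prefixes = sorted(self.study_classes.values())
        for a, b in zip(prefixes, prefixes[1:]):
            if b.startswith(a):
                raise ValueError(
                    f"study-class prefixes overlap: {a!r} is a prefix of {b!r}"
                )
        for label, prefix in self.study_classes.items():
            if not prefix or not prefix[0].isalpha():
                raise ValueError(f"invalid ATC prefix {prefix!r} for {label!r}")

    @classmethod
    def from_yaml(cls, path) -> "AtcVocabulary":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def classify(self, atc: str) -> str | None:
        return classify_atc(atc, self)

    def is_fixed_combo(self, atc: str) -> bool:
        return any(atc.startswith(p) for p in self.fixed_combo_prefixes)


def classify_atc(atc: str, vocab: AtcVocabulary) -> str | None:
    """Map an ATC code to a study-class label by longest-prefix match.

    Returns ``None`` for codes outside the study classes (co-medications,
    fixed combinations, anything else).
    """
    best: str | None = None
    best_len = -1
    for label, prefix in vocab.study_classes.items():
        if atc.startswith(prefix) and len(prefix) > best_len:
            best, best_len = label, len(prefix)
    return best
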