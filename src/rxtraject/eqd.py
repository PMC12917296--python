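"""Equivalent-dose (EQD) tiers and dose-transition classification.

Statin daily doses are mapped to three tiers corresponding to expected
LDL-cholesterol reduction bands: low (<30%), medium (30-45%) and high
(>45%).  The shipped default table is a reconstruction following standard
statin-intensity bands and is fully overridable; fibrates have no defined
LDL equivalence and default to a single (low) tier with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

TIERS = ("low", "medium", "high")
_TIER_RANK = {t: i for i, t in enumerate(TIERS)}

#: class -> list of (dose_lo, dose_hi, tier), inclusive mg/day bounds,
#: sorted by dose; doses above the top band map to high, below the bottom
#: band to low, and doses in a gap inherit the band below (monotone).
DEFAULT_EQD_ROWS: dict[str, list[tuple[float, float, str]]] = {
    "simvastatin": [(5, 10, "low"), (20, 40, "medium")],
    "pravastatin": [(10, 20, "low"), (40, 80, "medium")],
    "fluvastatin": [(20, 40, "low"), (80, 80, "medium")],
    "atorvastatin": [(10, 20, "medium"), (40, 80, "high")],
    "rosuvastatin": [(5, 10, "medium"), (20, 40, "high")],
    "fibrates": [(0, float("inf"), "low")],
}


@dataclass
class EqdTable:
    """Dose-range -> tier lookup per study class."""

    rows: dict[str, list[tuple[float, float, str]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_EQD_ROWS.items()}
    )

    def __post_init__(self) -> None:
        for cls, bands in self.rows.items():
            if not bands:
                raise ValueError(f"class {cls!r} has no dose bands")
            bands.sort(key=lambda b: b[0])
            for (lo0, hi0, t0), (lo1, _hi1, t1) in zip(bands, bands[1:]):
                if lo1 <= hi0:
                    raise ValueError(f"overlapping dose bands for {cls!r}")
                if _TIER_RANK[t1] < _TIER_RANK[t0]:
                    raise ValueError(f"tiers not monotone in dose for {cls!r}")
            for lo, hi, tier in bands:
                if tier not in TIERS or lo > hi:
                    raise ValueError(f"invalid band {(lo, hi, tier)} for {cls!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EqdTable":
        rows: dict[str, list[tuple[float, float, str]]] = {}
        for _, r in df.iterrows():
            rows.setdefault(r["class"], []).append(
                (float(r["dose_lo"]), float(r["dose_hi"]), str(r["tier"]))
            )
        return cls(rows)


def daily_dose(strength_mg, units, days_supplied) -> float:
    """mg/day of one dispensing: strength x units / days supplied.

    Returns NaN when strength or units is missing; such records are
    excluded from the EQD analysis (callers count them).
    """
    if pd.isna(strength_mg) or pd.isna(units):
        return float("nan")
    return float(strength_mg) * float(units) / float(days_supplied)


def eqd_level(drug_class: str, dose_mg_day: float, table: EqdTable | None = None) -> str:
    """Tier of a (class, daily dose) pair, monotone-extended beyond the
    defined bands."""
    table = table or EqdTable()
    if drug_class not in table.rows:
        raise KeyError(f"no EQD bands for class {drug_class!r}")
    if drug_class == "fibrates" and len(table.rows["fibrates"]) == 1:
        warnings.warn(
            "fibrates have no LDL-equivalence; using the single default tier",
            stacklevel=2,
        )
    bands = table.rows[drug_class]
    if dose_mg_day < bands[0][0]:
        return "low"
    tier = bands[0][2]
    for lo, hi, t in bands:
        if dose_mg_day >= lo:
            tier = t
    if dose_mg_day > bands[-1][1]:
        return "high"
    return tier


def transition_class(baseline: tuple[str, str], new: tuple[str, str]) -> str:
    """Label a (class, tier) -> (class, tier) dose transition.

    E.g. ('simvastatin','low') -> ('atorvastatin','medium') is a
    'cross-class escalation'.
    """
    (c0, t0), (c1, t1) = baseline, new
    for t in (t0, t1):
        if t not in TIERS:
            raise ValueError(f"unknown tier {t!r}")
    scope = "same-class" if c0 == c1 else "cross-class"
    d = _TIER_RANK[t1] - _TIER_RANK[t0]
    move = "same-tier" if d == 0 else ("escalation" if d > 0 else "de-escalation")
    return f"{scope} {move}"


def eqd_analysis(records: pd.DataFrame, class_col: str = "study_class",
                 table: EqdTable | None = None):
    """Tier every dispensing record; returns (tiered_frame, n_excluded).

    Records lacking strength or units get no tier and are counted as
    excluded; ``mapped + excluded == total``.
    """
    table = table or EqdTable()
    dose = records.apply(
        lambda r: daily_dose(r["strength_mg"], r["units"], r["days_supplied"]), axis=1
    )
    out = records.copy()
    out["dose_mg_day"] = dose
    tiers = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cls, d in zip(out[class_col], dose):
            tiers.append(None if pd.isna(d) else eqd_level(cls, d, table))
    out["eqd_tier"] = tiers
    n_excluded = int(dose.isna().sum())
    return out, n_excluded
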