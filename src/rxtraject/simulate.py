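"""Synthetic community-pharmacy dispensing data with planted ground truth.

The generator emulates a 1996-2020 Dutch-style dispensing database of new
users of lipid-lowering monotherapy.  Each synthetic patient carries

* a trajectory *archetype* (continuer / discontinuer / switcher / add-on /
  intermittent) realised as a deterministic refill schedule whose
  classification by :mod:`rxtraject.patterns` is known by construction, and
* a latent *adherence class* (high/low) drawn from a logistic model with
  configurable planted odds ratios, realised by thinning refills: the
  refill interval is ``ceil(days_supplied / target_pdc)`` so the proportion
  of covered days per 360-day year lands in the high (>=0.85) or low
  (<=0.75) band on either side of the 0.8 threshold.

Ground truth (archetype, expected pattern flags, adherence class, planted
covariates) is written to a separate labels table and never into the
analysis inputs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import ARCHETYPES, GeneratorConfig
from .io import from_day, to_day

#: representative full ATC code and tablet strengths (mg) per study class
CLASS_CODES = {
    "simvastatin": "C10AA01",
    "pravastatin": "C10AA03",
    "fluvastatin": "C10AA04",
    "atorvastatin": "C10AA05",
    "rosuvastatin": "C10AA07",
    "fibrates": "C10AB04",
}
CLASS_STRENGTHS = {
    "simvastatin": (10.0, 20.0, 40.0),
    "pravastatin": (20.0, 40.0),
    "fluvastatin": (40.0, 80.0),
    "atorvastatin": (10.0, 20.0, 40.0),
    "rosuvastatin": (5.0, 10.0, 20.0),
    "fibrates": (600.0,),
}

#: background (non-study, non-excluding) dispensings marking database
#: presence around the index date
BACKGROUND_ATC = "N02BE01"
_BACKGROUND_OFFSETS = (-730, -365, 370, 1100, 2000)

COMORBIDITY_CODES = {
    "diabetes": "A10BA02",
    "ra": "L04AB01",
    "asthma_copd": "R03AC02",
    "antiepileptics": "N03AX09",
    "antiparkinson": "N04BA02",
    "psycholeptics": "N05BA01",
    "psychoanaleptics": "N06AB04",
    "addictive_disorders": "N07BA01",
    "antineoplastics": "L01XA01",
}
VIOLATION_CODES = {"antihypertensive": "C03AA01", "cardiac": "C01DA02"}

#: expected classification of each archetype under the pattern definitions
ARCHETYPE_FLAGS = {
    "continuer": dict(continuation=True, discontinuation=False, switch=False, add_on=False),
    "intermittent": dict(continuation=True, discontinuation=False, switch=False, add_on=False),
    "discontinuer": dict(continuation=False, discontinuation=True, switch=False, add_on=False),
    "switcher": dict(continuation=False, discontinuation=True, switch=True, add_on=False),
    "addon": dict(continuation=False, discontinuation=False, switch=False, add_on=True),
}

FOLLOWUP_CAP_DAYS = 3780  # ~10 years


def refill_interval(days_supplied: int, pdc: float, max_interval: int = 120) -> int:
    """Integer refill interval realising a target proportion of covered days."""
    if not 0 < pdc <= 1:
        raise ValueError("pdc must be in (0, 1]")
    return max(days_supplied, min(math.ceil(days_supplied / pdc), max_interval))


def _trace_arrays(
    archetype: str,
    *,
    atc: str,
    days_supplied: int,
    strength_mg: float,
    pdc: float,
    cap_days: int,
    stop_day: int,
    switch_delay: int,
    second_atc: str,
    second_strength_mg: float,
    addon_anchor_day: int,
    max_interval: int,
):
    """Refill days/codes/strengths of one archetype, days relative to index."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}")
    s = int(days_supplied)
    interval = refill_interval(s, pdc, max_interval)

    if archetype in ("continuer", "intermittent", "addon"):
        fills = np.arange(0, cap_days, interval)
        if archetype == "intermittent" and cap_days > 1000:
            before = fills[fills < 720]
            runout = int(before[-1]) + s
            fills = np.sort(
                np.append(fills[(fills < 720) | (fills >= 840)], runout + 160)
            )
        days = fills
        codes = [atc] * len(fills)
        strengths = [strength_mg] * len(fills)
        if archetype == "addon":
            anchor = fills[fills >= addon_anchor_day]
            if len(anchor) == 0:
                raise ValueError("cap_days too short to place the add-on")
            t0 = int(anchor[0]) + 1  # strictly inside the index coverage interval
            add = [t for t in (t0, t0 + s) if t < cap_days]
            days = np.concatenate([days, add])
            codes += [second_atc] * len(add)
            strengths += [second_strength_mg] * len(add)
    else:  # discontinuer, switcher
        fills = np.arange(0, stop_day, interval)
        days = fills
        codes = [atc] * len(fills)
        strengths = [strength_mg] * len(fills)
        runout = int(fills[-1]) + s
        if runout + 181 > cap_days:
            raise ValueError("cap_days too short to confirm a >180-day gap")
        if archetype == "switcher":
            if not 1 <= switch_delay <= 180:
                raise ValueError("switch_delay must lie in [1, 180] days")
            t0 = runout + switch_delay
            add = [t0 + k * s for k in range(4) if t0 + k * s < cap_days]
            days = np.concatenate([days, add])
            codes += [second_atc] * len(add)
            strengths += [second_strength_mg] * len(add)
    return np.asarray(days, dtype=np.int64), codes, strengths


def generate_archetype_trace(
    archetype: str,
    *,
    index_day: int = 0,
    atc: str = "C10AA01",
    days_supplied: int = 30,
    strength_mg: float = 20.0,
    pdc: float = 0.95,
    cap_days: int = 3600,
    stop_day: int = 500,
    switch_delay: int = 60,
    second_atc: str = "C10AA05",
    second_strength_mg: float = 20.0,
    addon_anchor_day: int = 380,
    max_interval: int = 120,
) -> pd.DataFrame:
    """Deterministic dispensing fragment realising one trajectory archetype.

    Returns a frame with columns ``day, atc, strength_mg, units,
    days_supplied``.  The fragment classifies as its archetype by
    construction: e.g. a switcher refills the index drug, runs out, leaves
    a >180-day gap on the index class, and starts a different class
    ``switch_delay`` (<=180) days after the run-out.
    """
    days, codes, strengths = _trace_arrays(
        archetype,
        atc=atc,
        days_supplied=days_supplied,
        strength_mg=strength_mg,
        pdc=pdc,
        cap_days=cap_days,
        stop_day=stop_day,
        switch_delay=switch_delay,
        second_atc=second_atc,
        second_strength_mg=second_strength_mg,
        addon_anchor_day=addon_anchor_day,
        max_interval=max_interval,
    )
    df = pd.DataFrame(
        {
            "day": days + index_day,
            "atc": codes,
            "strength_mg": strengths,
            "units": float(days_supplied),
            "days_supplied": int(days_supplied),
        }
    )
    return df.sort_values("day", kind="mergesort").reset_index(drop=True)


def _latent_prob_high(cfg: GeneratorConfig, male, age_band, diabetes, drug_class):
    eff = cfg.planted_effects
    lin = (
        eff.intercept_logit
        + np.log(eff.or_male) * male
        + np.log(eff.or_age_40_69) * (age_band == 1)
        + np.log(eff.or_age_70plus) * (age_band == 2)
        + np.log(eff.or_diabetes) * diabetes
    )
    if eff.class_or:
        lin = lin + np.array([np.log(eff.class_or.get(c, 1.0)) for c in drug_class])
    return 1.0 / (1.0 + np.exp(-lin))


def generate_population(config: GeneratorConfig):
    """Generate (patient_table, dispensing_table, labels_table).

    Every patient flagged eligible has >=2 years of database presence
    before the index date and >=1 year after; dispensing rows come back
    sorted by ``(patient_id, date)``; the labels table carries the planted
    ground truth.  Output is byte-identical for a fixed seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    start_day, end_day = to_day(list(cfg.date_range))
    if n > 0 and end_day - start_day < 1600:
        raise ValueError("date_range too short: need at least ~4.5 years")

    if n == 0:
        dispensing = pd.DataFrame(
            columns=["patient_id", "date", "atc", "strength_mg", "units", "days_supplied", "day"]
        )
        patients = pd.DataFrame(columns=["patient_id", "birth_date", "sex", "birth_day"])
        return patients, dispensing, pd.DataFrame()

    classes = list(cfg.drug_class_probs)
    p_class = np.array([cfg.drug_class_probs[c] for c in classes])
    arche_names = list(cfg.pattern_mix)
    p_arche = np.array([cfg.pattern_mix[a] for a in arche_names])
    comorb_names = list(cfg.comorbidity_probs)

    # ---- vectorised per-patient draws (fixed order => reproducible) ----
    index_day = rng.integers(start_day + 730, end_day - 800, size=n, endpoint=True)
    drug_class = np.array(classes)[rng.choice(len(classes), size=n, p=p_class)]
    archetype = np.array(arche_names)[rng.choice(len(arche_names), size=n, p=p_arche)]
    male = rng.random(n) < cfg.p_male
    age_band = rng.choice(3, size=n, p=np.asarray(cfg.age_band_probs))
    age = np.select(
        [age_band == 0, age_band == 1],
        [rng.uniform(18.2, 39.8, n), rng.uniform(40.2, 69.8, n)],
        rng.uniform(70.2, 89.8, n),
    )
    birth_day = index_day - np.round(age * 365.25).astype(np.int64)
    comorb = {g: rng.random(n) < cfg.comorbidity_probs[g] for g in comorb_names}
    comorb_offset = rng.integers(0, 180, size=(n, len(comorb_names)))

    diab = comorb.get("diabetes", np.zeros(n, dtype=bool))
    high = rng.random(n) < _latent_prob_high(cfg, male, age_band, diab, drug_class)
    pdc = np.where(high, rng.uniform(0.85, 0.99, n), rng.uniform(0.40, 0.75, n))
    supply = np.array(cfg.days_supplied_choices)[
        rng.choice(len(cfg.days_supplied_choices), size=n)
    ]
    strength_idx = rng.integers(0, 3, size=n)
    rel_cap = np.minimum(end_day - index_day, FOLLOWUP_CAP_DAYS)
    stop_hi = np.maximum(481, np.minimum(1800, rel_cap - supply - 185))
    stop_day = rng.integers(480, stop_hi, size=n, endpoint=True)
    switch_delay = rng.integers(30, 150, size=n, endpoint=True)
    u_viol = rng.random(n)
    violator = np.where(
        u_viol < cfg.violator_fraction / 2,
        "antihypertensive",
        np.where(u_viol < cfg.violator_fraction, "cardiac", "none"),
    )
    viol_offset_ah = rng.integers(0, 360, size=n)
    viol_offset_cd = rng.integers(-720, 89, size=n, endpoint=True)
    other_idx = rng.choice(len(classes), size=n)

    pid = np.array([f"P{i:06d}" for i in range(n)])

    all_pid: list = []
    all_day: list = []
    all_atc: list = []
    all_strength: list = []
    all_units: list = []
    all_supply: list = []

    def emit(i, day, atc, strength, units, sup):
        all_pid.append(pid[i])
        all_day.append(day)
        all_atc.append(atc)
        all_strength.append(strength)
        all_units.append(units)
        all_supply.append(sup)

    for i in range(n):
        cls = drug_class[i]
        strengths = CLASS_STRENGTHS[cls]
        strength = strengths[strength_idx[i] % len(strengths)]
        second = classes[other_idx[i]]
        if second == cls:
            second = classes[(other_idx[i] + 1) % len(classes)]
        s = int(supply[i])
        days, codes, strs = _trace_arrays(
            archetype[i],
            atc=CLASS_CODES[cls],
            days_supplied=s,
            strength_mg=strength,
            pdc=float(pdc[i]),
            cap_days=int(rel_cap[i]),
            stop_day=int(stop_day[i]),
            switch_delay=int(switch_delay[i]),
            second_atc=CLASS_CODES[second],
            second_strength_mg=CLASS_STRENGTHS[second][0],
            addon_anchor_day=380,
            max_interval=cfg.max_refill_interval_days,
        )
        idx = int(index_day[i])
        for d, a, st in zip(days, codes, strs):
            emit(i, idx + int(d), a, st, float(s), s)
        for off in _BACKGROUND_OFFSETS:
            d = idx + off
            if start_day <= d <= end_day:
                emit(i, d, BACKGROUND_ATC, 500.0, 10.0, 10)
        for j, g in enumerate(comorb_names):
            if comorb[g][i]:
                emit(i, idx + int(comorb_offset[i, j]), COMORBIDITY_CODES[g], 10.0, 30.0, 30)
        if violator[i] == "antihypertensive":
            emit(i, idx + int(viol_offset_ah[i]), VIOLATION_CODES["antihypertensive"], 12.5, 30.0, 30)
        elif violator[i] == "cardiac":
            emit(i, idx + int(viol_offset_cd[i]), VIOLATION_CODES["cardiac"], 5.0, 30.0, 30)

    dispensing = pd.DataFrame(
        {
            "patient_id": all_pid,
            "day": np.asarray(all_day, dtype=np.int64),
            "atc": all_atc,
            "strength_mg": np.asarray(all_strength, dtype=float),
            "units": np.asarray(all_units, dtype=float),
            "days_supplied": np.asarray(all_supply, dtype=np.int64),
        }
    )
    dispensing = dispensing.sort_values(["patient_id", "day"], kind="mergesort").reset_index(
        drop=True
    )
    dispensing["date"] = from_day(dispensing["day"]).values
    dispensing = dispensing[
        ["patient_id", "date", "atc", "strength_mg", "units", "days_supplied", "day"]
    ]

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "birth_date": from_day(birth_day).values,
            "sex": np.where(male, "male", "female"),
            "birth_day": birth_day,
        }
    )

    labels = pd.DataFrame(
        {
            "patient_id": pid,
            "archetype": archetype,
            "index_class": drug_class,
            "index_day": index_day,
            "adherence_class": np.where(high, "high", "low"),
            "target_pdc": pdc,
            "sex": np.where(male, "male", "female"),
            "age_band": np.array(["18-39", "40-69", ">=70"])[age_band],
            "violator": violator,
        }
    )
    for flag in ("continuation", "discontinuation", "switch", "add_on"):
        labels[f"true_{flag}"] = [ARCHETYPE_FLAGS[a][flag] for a in archetype]
    for g in comorb_names:
        labels[f"comorb_{g}"] = comorb[g]
    return patients, dispensing, labels


def write_simulation(config: GeneratorConfig, outdir) -> None:
    """Run the generator and write patients/dispensing/labels CSVs."""
    from pathlib import Path

    from .io import write_dispensing_table, write_patient_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    patients, dispensing, labels = generate_population(config)
    write_patient_table(patients, out / "patients.csv")
    write_dispensing_table(dispensing, out / "dispensing.csv")
    labels.to_csv(out / "labels.csv", index=False)
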