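"""Independent brute-force oracles and table builders shared by the tests.

Everything here works day by day or pair by pair, deliberately ignoring the
interval arithmetic used by the package, so agreement is informative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rxtraject.io import from_day, normalise_dispensing, normalise_patients

DAY0 = 12788  # 2005-01-06 on the epoch day grid


def disp_table(rows) -> pd.DataFrame:
    """rows: (patient_id, day, atc, days_supplied[, strength_mg, units])."""
    recs = []
    for r in rows:
        pid, day, atc, sup = r[:4]
        strength = r[4] if len(r) > 4 else 20.0
        units = r[5] if len(r) > 5 else float(sup)
        recs.append(
            {
                "patient_id": pid,
                "date": from_day([day])[0],
                "atc": atc,
                "strength_mg": strength,
                "units": units,
                "days_supplied": sup,
            }
        )
    return normalise_dispensing(pd.DataFrame(recs))


def patient_table(entries) -> pd.DataFrame:
    """entries: (patient_id, birth_day[, sex])."""
    recs = [
        {
            "patient_id": e[0],
            "birth_date": from_day([e[1]])[0],
            "sex": e[2] if len(e) > 2 else "female",
        }
        for e in entries
    ]
    return normalise_patients(pd.DataFrame(recs))


def standard_records(pid, fills, extra=(), first_day=None):
    """Study fills plus background rows giving 2y lookback / 1y follow-on."""
    anchor = first_day if first_day is not None else min(f[0] for f in fills)
    rows = [(pid, anchor - 730, "N02BE01", 10), (pid, anchor + 370, "N02BE01", 10)]
    rows += [(pid, d, atc, sup) for d, atc, sup in fills]
    rows += list(extra)
    return rows


def brute_covered_days(fill_days, supplies, cap_day, stockpile_cap=90):
    """Day-by-day pill-supply simulation; returns the set of covered days."""
    fills = sorted(zip(fill_days, supplies))
    if not fills:
        return set()
    covered = set()
    stock = 0
    day = fills[0][0]
    i = 0
    horizon = cap_day
    while day < horizon:
        while i < len(fills) and fills[i][0] == day:
            stock = min(stock, stockpile_cap) + fills[i][1]
            i += 1
        if stock > 0:
            covered.add(day)
            stock -= 1
        elif i >= len(fills):
            break
        day += 1
    return covered


def brute_patterns(index_day, fill_days, supplies, other_events, cap_day,
                   stockpile_cap=90):
    """Day-level scan for discontinuation / switch / add-on.

    ``other_events``: sorted list of (day, class) for non-index study
    dispensings before the cap.  Returns dict of flags and dates.
    """
    covered = brute_covered_days(fill_days, supplies, cap_day, stockpile_cap)
    fillset = sorted(set(fill_days))
    disc_day = None
    if covered:
        day = min(covered)
        while day < cap_day:
            if day in covered:
                day += 1
                continue
            # run of uncovered days starting at `day`
            nxt_fills = [f for f in fillset if f >= day]
            gap_end = nxt_fills[0] if nxt_fills else cap_day
            if gap_end - day > 180:
                disc_day = day
                break
            day = gap_end
    switch = (False, None, None)
    if disc_day is not None:
        for d, c in other_events:
            if disc_day < d <= disc_day + 180:
                switch = (True, d, c)
                break
    addon = (False, None, None)
    for d, c in other_events:
        if (disc_day is None or d < disc_day) and d in covered:
            addon = (True, d, c)
            break
    cont = disc_day is None and not switch[0] and not addon[0]
    return {
        "continuation": cont,
        "discontinuation": disc_day is not None,
        "disc_day": disc_day,
        "switch": switch[0],
        "add_on": addon[0],
    }


def auc_bruteforce(y, p):
    """Exhaustive pairwise concordance; ties count 1/2."""
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    pos = p[y == 1]
    neg = p[y == 0]
    total = conc = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                conc += 0.5
    return conc / total


def manual_km(durations, events):
    """Hand product-limit estimate: [(time, survival)] at event times."""
    pts = sorted(set(t for t, e in zip(durations, events) if e))
    surv = 1.0
    out = []
    for t in pts:
        at_risk = sum(1 for d in durations if d >= t)
        d_t = sum(1 for d, e in zip(durations, events) if e and d == t)
        surv *= 1 - d_t / at_risk
        out.append((t, surv))
    return out
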