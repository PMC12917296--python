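"""Reconstruction of drug-supply coverage from dispensing dates.

Each dispensing contributes ``days_supplied`` covered days.  A refill
collected before the previous supply runs out is carried forward: it starts
at the previous run-out, with the total carried surplus capped at a
configurable stockpile limit (default 90 days).  Coverage is represented as
ordered disjoint half-open day intervals ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_STOCKPILE_CAP = 90


def build_coverage(
    fill_days,
    days_supplied,
    cap_day: int | None = None,
    stockpile_cap: int = DEFAULT_STOCKPILE_CAP,
) -> list[tuple[int, int]]:
    """Merge one patient's dispensings into disjoint coverage intervals.

    ``fill_days`` must be sorted ascending.  ``cap_day`` (exclusive) clips
    the result, e.g. at the follow-up cap.  ``stockpile_cap=0`` disables
    carryover (each refill truncates the remaining supply).
    """
    intervals: list[tuple[int, int]] = []
    cur_start = cur_end = None
    for t, s in zip(fill_days, days_supplied):
        t, s = int(t), int(s)
        if cur_end is None:
            cur_start, cur_end = t, t + s
        elif t >= cur_end:
            intervals.append((cur_start, cur_end))
            cur_start, cur_end = t, t + s
        else:
            carry = min(cur_end - t, stockpile_cap)
            cur_end = t + carry + s
    if cur_end is not None:
        intervals.append((cur_start, cur_end))
    if cap_day is not None:
        intervals = [(a, min(b, cap_day)) for a, b in intervals if a < cap_day]
    return intervals


@dataclass
class CoverageSet:
    """Ordered disjoint half-open coverage intervals for one patient."""

    patient_id: str
    intervals: list[tuple[int, int]]

    def covered_days(self, start: int | None = None, end: int | None = None) -> int:
        total = 0
        for a, b in self.intervals:
            if start is not None:
                a = max(a, start)
            if end is not None:
                b = min(b, end)
            if b > a:
                total += b - a
        return total

    def contains(self, day: int) -> bool:
        return any(a <= day < b for a, b in self.intervals)

    @property
    def last_end(self) -> int | None:
        return self.intervals[-1][1] if self.intervals else None


def coverage_table(
    fills: pd.DataFrame,
    caps: pd.Series | None = None,
    stockpile_cap: int = DEFAULT_STOCKPILE_CAP,
) -> pd.DataFrame:
    """Coverage intervals for many patients at once.

    ``fills`` needs columns ``patient_id, day, days_supplied`` sorted by
    ``(patient_id, day)``; ``caps`` maps patient_id to an exclusive cap day.
    Returns a frame with columns ``patient_id, start, end``.
    """
    out_pid: list = []
    out_start: list[int] = []
    out_end: list[int] = []
    for pid, grp in fills.groupby("patient_id", sort=False):
        cap = None if caps is None else int(caps.loc[pid])
        ivals = build_coverage(
            grp["day"].to_numpy(), grp["days_supplied"].to_numpy(), cap, stockpile_cap
        )
        out_pid.extend([pid] * len(ivals))
        out_start.extend(a for a, _ in ivals)
        out_end.extend(b for _, b in ivals)
    return pd.DataFrame(
        {
            "patient_id": out_pid,
            "start": np.asarray(out_start, dtype=np.int64),
            "end": np.asarray(out_end, dtype=np.int64),
        }
    )
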