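"""Compile 24-h recall diaries into closed daily compositions.

A recall diary lists every activity over a day at >= 5-minute resolution,
each with an energy cost in METs.  Sleep is a distinct diary entry (so quiet
wakeful rest stays sedentary); waking activities are binned by MET value:
< 1.5 sedentary, 1.5-2.99 LPA, >= 3 MVPA (the MVPA edge is inclusive).
Because a diary tiles the full day, the compiled composition sums to exactly
1440 min without any closure step.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accel import BEHAVIOURS, MINUTES_PER_DAY

SED_MET_UPPER = 1.5
MVPA_MET_LOWER = 3.0


@dataclass
class RecallDiaryDay:
    """One recalled day: ordered (start_min, end_min, activity, met) segments.

    Segments are half-open minute intervals that tile [0, 1440) exactly;
    every duration is >= 5 min and a multiple of 5; METs are positive.
    """

    participant_id: str
    date: _dt.date
    segments: list[tuple[int, int, str, float]]

    def __post_init__(self) -> None:
        problems = []
        pos = 0
        for start, end, activity, met in self.segments:
            if start != pos:
                problems.append(f"[{start}, {end}) {activity!r}: expected start {pos}")
            d = end - start
            if d < 5 or d % 5:
                problems.append(
                    f"[{start}, {end}) {activity!r}: duration {d} not a multiple "
                    "of 5 >= 5")
            if not met > 0:
                problems.append(f"[{start}, {end}) {activity!r}: MET {met} not positive")
            pos = end
        if pos != MINUTES_PER_DAY:
            problems.append(f"day covers {pos} minutes, expected {MINUTES_PER_DAY}")
        if problems:
            raise ValueError("invalid recall diary: " + "; ".join(problems))


def classify_met(met: float) -> str:
    """MET band for a waking activity (sed / lpa / mvpa)."""
    if met < SED_MET_UPPER:
        return "sed"
    if met < MVPA_MET_LOWER:
        return "lpa"
    return "mvpa"


def compile_recall_day(day: RecallDiaryDay) -> np.ndarray:
    """Daily minutes of sleep/SED/LPA/MVPA; always sums to exactly 1440.

    Sleep is identified by the activity label, not by its MET value.
    """
    totals = dict.fromkeys(BEHAVIOURS, 0)
    for start, end, activity, met in day.segments:
        key = "sleep" if activity == "sleep" else classify_met(met)
        totals[key] += end - start
    return np.array([totals[b] for b in BEHAVIOURS], dtype=float)


def compile_diaries(diaries: list[RecallDiaryDay]) -> pd.DataFrame:
    """Per-day self-reported composition table."""
    rows = []
    for d in diaries:
        comp = compile_recall_day(d)
        rows.append({"participant": d.participant_id, "date": d.date.isoformat(),
                     "sleep_min": comp[0], "sed_min": comp[1],
                     "lpa_min": comp[2], "mvpa_min": comp[3]})
    return pd.DataFrame(rows)


def exclude_low_sleep(
    days: pd.DataFrame, *, min_sleep_min: float = 300.0
) -> tuple[pd.DataFrame, dict]:
    """Drop recall days with implausibly low sleep (< 300 min/d, strict).

    Returns the retained table and a small report of what was removed.
    """
    if days.empty:
        return days.copy(), {"n_input": 0, "n_excluded": 0, "excluded": []}
    keep = days["sleep_min"] >= min_sleep_min
    excluded = days.loc[~keep, ["participant", "date"]].to_records(index=False).tolist()
    return days.loc[keep].reset_index(drop=True), {
        "n_input": int(len(days)),
        "n_excluded": int((~keep).sum()),
        "excluded": [tuple(map(str, e)) for e in excluded],
    }


# ---------------------------------------------------------------------------
# CSV interface: date,start_min,end_min,activity,met (plus participant)
# ---------------------------------------------------------------------------

def write_diaries_csv(diaries: list[RecallDiaryDay], path) -> None:
    rows = []
    for d in diaries:
        for start, end, activity, met in d.segments:
            rows.append({"participant": d.participant_id, "date": d.date.isoformat(),
                         "start_min": start, "end_min": end,
                         "activity": activity, "met": met})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_diaries_csv(path) -> list[RecallDiaryDay]:
    df = pd.read_csv(path)
    out = []
    for (pid, date), grp in df.groupby(["participant", "date"], sort=True):
        grp = grp.sort_values("start_min")
        segments = [(int(r.start_min), int(r.end_min), str(r.activity), float(r.met))
                    for r in grp.itertuples(index=False)]
        out.append(RecallDiaryDay(participant_id=str(pid),
                                  date=_dt.date.fromisoformat(str(date)),
                                  segments=segments))
    return out
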