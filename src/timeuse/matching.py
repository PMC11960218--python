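"""Pair recall days with valid accelerometer days and average per child.

A recall day enters the analysis only if the same participant has a *valid*
accelerometer day on the same calendar date.  Matched days are then averaged
within participant and method, producing one "average device day" and one
"average self-report day" per child — participants enter the models with
equal weight regardless of how many matched days they contributed (the day
count is carried along for sensitivity weighting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accel import BEHAVIOURS, MINUTES_PER_DAY

#: characteristics expected on every analysis record; ``academic`` may be
#: missing (its model simply uses the reduced sample).
CHARACTERISTICS = ("sex", "age", "puberty", "parental_education",
                   "zbmi", "vo2max", "academic")
_COMP_COLS = [f"{b}_min" for b in BEHAVIOURS]


@dataclass
class ParticipantRecord:
    """One child's characteristics plus averaged per-method compositions."""

    participant_id: str
    school_id: str
    wave: int
    sex: str
    age: float
    puberty: str
    parental_education: str
    zbmi: float
    vo2max: float
    academic: float
    device_comp: np.ndarray  # 4 parts, min/day, sums to 1440
    self_comp: np.ndarray
    n_matched_days: int

    def __post_init__(self) -> None:
        self.device_comp = np.asarray(self.device_comp, dtype=float)
        self.self_comp = np.asarray(self.self_comp, dtype=float)
        for comp in (self.device_comp, self.self_comp):
            if comp.shape != (4,) or abs(comp.sum() - MINUTES_PER_DAY) > 1e-6:
                raise ValueError("compositions must be 4 parts summing to 1440")
        if self.n_matched_days < 1:
            raise ValueError("a record needs at least one matched day")


def _check_unique(df: pd.DataFrame, side: str) -> None:
    dup = df.duplicated(["participant", "date"])
    if dup.any():
        pairs = df.loc[dup, ["participant", "date"]].head().to_dict("records")
        raise ValueError(f"duplicate (participant, date) on the {side} side: {pairs}")


def match_days(accel_days: pd.DataFrame, recall_days: pd.DataFrame) -> pd.DataFrame:
    """Inner-join accelerometer and recall days on (participant, date).

    ``accel_days`` must carry a ``valid`` flag (only valid days can match)
    and both sides the four ``*_min`` columns.  Device compositions are
    closed to 1440 here — the non-wear adjustment precedes averaging.
    Returns one row per matched day with ``device_*`` and ``self_*`` columns.
    """
    _check_unique(accel_days, "accelerometer")
    _check_unique(recall_days, "recall")
    valid = accel_days[accel_days["valid"]] if "valid" in accel_days else accel_days
    merged = valid.merge(recall_days, on=["participant", "date"],
                         suffixes=("_device", "_self"), how="inner")
    out = merged[["participant", "date"]].copy()
    device = merged[[f"{c}_device" for c in _COMP_COLS]].to_numpy(dtype=float)
    device *= MINUTES_PER_DAY / device.sum(axis=1, keepdims=True)
    for j, b in enumerate(BEHAVIOURS):
        out[f"device_{b}"] = device[:, j]
        out[f"self_{b}"] = merged[f"{b}_min_self"].to_numpy(dtype=float)
    return out


def average_per_participant(
    matched: pd.DataFrame,
    participants: pd.DataFrame,
    *,
    require_complete: tuple[str, ...] = tuple(c for c in CHARACTERISTICS
                                             if c != "academic"),
) -> tuple[pd.DataFrame, dict]:
    """Average matched days within participant and attach characteristics.

    Participants with missing values in ``require_complete`` columns are
    dropped and reported.  The returned table has one row per participant
    with ``device_*`` / ``self_*`` behaviour columns (each set summing to
    1440) and ``n_matched_days``.
    """
    value_cols = [f"{m}_{b}" for m in ("device", "self") for b in BEHAVIOURS]
    means = (matched.groupby("participant", as_index=False)[value_cols].mean())
    counts = matched.groupby("participant").size().rename("n_matched_days")
    means = means.merge(counts, on="participant")

    table = means.merge(participants.rename(columns={"participant_id": "participant"}),
                        on="participant", how="inner")
    missing_chars = table[list(require_complete)].isna().any(axis=1)
    unmatched = set(means["participant"]) - set(table["participant"])
    report = {
        "n_matched_participants": int(len(means)),
        "n_dropped_missing_characteristics": int(missing_chars.sum()),
        "dropped": sorted(table.loc[missing_chars, "participant"].tolist()
                          + list(unmatched)),
    }
    return table.loc[~missing_chars].reset_index(drop=True), report


def to_records(table: pd.DataFrame) -> list[ParticipantRecord]:
    """Typed view of the analysis table (validates closure row by row)."""
    records = []
    for r in table.itertuples(index=False):
        records.append(ParticipantRecord(
            participant_id=r.participant, school_id=r.school_id, wave=int(r.wave),
            sex=r.sex, age=float(r.age), puberty=r.puberty,
            parental_education=r.parental_education, zbmi=float(r.zbmi),
            vo2max=float(r.vo2max), academic=float(r.academic),
            device_comp=np.array([getattr(r, f"device_{b}") for b in BEHAVIOURS]),
            self_comp=np.array([getattr(r, f"self_{b}") for b in BEHAVIOURS]),
            n_matched_days=int(r.n_matched_days),
        ))
    return records


def records_from_study(study) -> pd.DataFrame:
    """Analysis table straight from a simulated study, truth as the device.

    Shortcut for model-focused work: the device composition is the closed
    ground truth (bypassing signal synthesis and classification, which are
    exercised separately) and the self-report side is the compiled diary.
    Every day matches by construction.
    """
    from .accel import normalize_to_1440
    from .recall import compile_diaries

    truth = study.truth_frame()
    device = truth.copy()
    closed = normalize_to_1440(device[_COMP_COLS].to_numpy(dtype=float))
    device[_COMP_COLS] = closed
    device["valid"] = True
    selfr = compile_diaries(study.diaries)
    matched = match_days(device, selfr)
    table, _ = average_per_participant(matched, study.participants_frame())
    return table


def write_analysis_table_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_analysis_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
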