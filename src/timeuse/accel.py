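"""Wrist accelerometry processing: raw signal to a closed 24-hour composition.

The processing chain mirrors the standard epoch-based workflow for wrist-worn
triaxial devices in paediatric field studies:

1. per-sample signal vector magnitude, ``SVM = |sqrt(ax^2+ay^2+az^2) - 1 g|``;
2. aggregation into 1-minute epochs (mean per-sample SVM scaled to g·min, so
   epoch values are invariant to the device sampling rate);
3. per-minute labelling: self-logged sleep window first, logged removals and
   missing-signal minutes as non-wear second, remaining waking-wear minutes
   classified by cut-points into sedentary / LPA / MVPA;
4. replacement of "sports" removals with a 40% MVPA / 40% LPA / 20% sedentary
   mix (children removing the device for organised sport);
5. valid-day and valid-participant screening;
6. linear closure of the four behaviours to 1440 min/day.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
#: Canonical behaviour order used for every 4-part composition in the package.
BEHAVIOURS = ("sleep", "sed", "lpa", "mvpa")

# integer label codes for per-minute day vectors
SLEEP, NONWEAR, SED, LPA, MVPA = 0, 1, 2, 3, 4
LABEL_NAMES = {SLEEP: "sleep", NONWEAR: "nonwear", SED: "sed", LPA: "lpa", MVPA: "mvpa"}

#: Fractions used to reallocate a "sports" removal interval.
SPORT_MIX = {"mvpa": 0.4, "lpa": 0.4, "sed": 0.2}


@dataclass(frozen=True)
class CutPoints:
    """Epoch intensity thresholds in g·min per 60-s epoch.

    Defaults derive from published wrist calibration thresholds for children
    (7 and 19 g·s per 1-s epoch), converted to this package's rate-invariant
    epoch convention (mean per-sample SVM x 60 s): 7/80*60 = 5.25 and
    19/80*60 = 14.25 g·min.  The thresholds correspond to the MET bands
    <1.5 / 1.5-2.99 / >=3 used to define sedentary time, LPA and MVPA.
    The upper band is inclusive: an epoch exactly at ``lpa_mvpa_threshold``
    is MVPA (">= 3 METs").
    """

    sed_lpa_threshold: float = 5.25
    lpa_mvpa_threshold: float = 14.25

    def __post_init__(self) -> None:
        if not (0 < self.sed_lpa_threshold < self.lpa_mvpa_threshold):
            raise ValueError(
                "cut-points must satisfy 0 < sed_lpa_threshold < lpa_mvpa_threshold, "
                f"got {self.sed_lpa_threshold}, {self.lpa_mvpa_threshold}"
            )


@dataclass
class TriaxialRecording:
    """One participant-day of raw triaxial wrist acceleration in g units.

    ``time_s`` holds seconds since midnight; non-wear appears as absent
    samples (gaps in ``time_s``), not as zeros.
    """

    participant_id: str
    date: _dt.date
    sampling_rate_hz: float
    time_s: np.ndarray
    acc: np.ndarray  # (n, 3) in g

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must be an (n, 3) array")
        if self.time_s.shape[0] != self.acc.shape[0]:
            raise ValueError("time_s and acc must have the same length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("sample times must be strictly increasing")


@dataclass
class WearLog:
    """Self-logged bed/get-up times and device-removal intervals for one day.

    Times are minutes-of-day.  ``bed_time > getup_time`` encodes the usual
    sleep window crossing midnight: the window for this date is
    ``[0, getup_time) ∪ [bed_time, 1440)``.  Removals are half-open minute
    intervals with an optional free-text reason.
    """

    participant_id: str
    date: _dt.date
    bed_time: int
    getup_time: int
    removals: list[tuple[int, int, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted((int(s), int(e)) for s, e, _ in self.removals)
        for (s, e) in ivs:
            if not (0 <= s < e <= MINUTES_PER_DAY):
                raise ValueError(f"removal interval [{s}, {e}) outside [0, 1440)")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("removal intervals overlap")

    def sleep_window_mask(self) -> np.ndarray:
        """Boolean 1440-vector marking the sleep window on this date."""
        mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
        if self.bed_time > self.getup_time:  # crosses midnight
            mask[: self.getup_time] = True
            mask[self.bed_time:] = True
        else:  # whole window inside the day (e.g. a full-day sleep log)
            mask[self.bed_time: self.getup_time] = True
        return mask


@dataclass
class EpochSeries:
    """Per-minute epoch SVM values (g·min) for one day.

    ``values`` has one slot per minute of the day; minutes with no samples are
    NaN (candidate non-wear).
    """

    date: _dt.date
    values: np.ndarray
    epoch_length_s: int = 60

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (MINUTES_PER_DAY,):
            raise ValueError("EpochSeries must cover 1440 minutes")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("epoch values must be non-negative")


@dataclass
class LabelledDay:
    """Per-minute behaviour labels for one day (integer codes)."""

    date: _dt.date
    labels: np.ndarray
    weekend: bool

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (MINUTES_PER_DAY,):
            raise ValueError("LabelledDay must have exactly 1440 labels")


@dataclass
class DayComposition:
    """Minutes in each behaviour plus non-wear for one participant-day.

    The five parts sum to 1440 before closure; ``valid`` reflects the wear
    screening rule.
    """

    participant_id: str
    date: _dt.date
    weekend: bool
    sleep_min: float
    sed_min: float
    lpa_min: float
    mvpa_min: float
    nonwear_min: float
    valid: bool = True

    def waking_wear_min(self) -> float:
        return self.sed_min + self.lpa_min + self.mvpa_min

    def parts(self) -> np.ndarray:
        """The 4-part behaviour vector in canonical order."""
        return np.array([self.sleep_min, self.sed_min, self.lpa_min, self.mvpa_min])

    def total(self) -> float:
        return float(self.parts().sum() + self.nonwear_min)


def compute_svm(recording: TriaxialRecording) -> np.ndarray:
    """Per-sample signal vector magnitude |‖a‖ − 1 g| in g.

    Raises on non-finite samples, naming the first offending time.
    """
    bad = ~np.isfinite(recording.acc).all(axis=1)
    if bad.any():
        t = recording.time_s[np.argmax(bad)]
        raise ValueError(f"non-finite acceleration sample at t={t:.3f} s")
    norm = np.linalg.norm(recording.acc, axis=1)
    return np.abs(norm - 1.0)


def aggregate_epochs(svm: np.ndarray, recording: TriaxialRecording) -> EpochSeries:
    """Aggregate per-sample SVM into 1-minute epoch values.

    Epoch value = mean per-sample SVM within the minute x 60, in g·min; this
    makes epoch values invariant to the sampling rate, so the same cut-points
    apply at any configured Hz.  Minutes with no samples are NaN.
    """
    svm = np.asarray(svm, dtype=float)
    if svm.shape != recording.time_s.shape:
        raise ValueError("svm series must align with the recording samples")
    minute = np.floor(recording.time_s / 60.0).astype(np.int64)
    if minute.size and (minute[0] < 0 or minute[-1] >= MINUTES_PER_DAY):
        raise ValueError("sample times fall outside the 24-h day")
    sums = np.bincount(minute, weights=svm, minlength=MINUTES_PER_DAY)
    counts = np.bincount(minute, minlength=MINUTES_PER_DAY)
    values = np.full(MINUTES_PER_DAY, np.nan)
    covered = counts > 0
    values[covered] = sums[covered] / counts[covered] * 60.0
    return EpochSeries(date=recording.date, values=values)


def label_day(
    epochs: EpochSeries,
    log: WearLog,
    cuts: CutPoints,
    *,
    strict_nonwear: bool = False,
) -> LabelledDay:
    """Label each minute sleep / non-wear / SED / LPA / MVPA.

    Order of precedence follows the study protocol: the logged sleep window is
    applied first (it wins over removals that fall inside it), logged removals
    second, then missing-signal minutes outside the logs become non-wear
    (unless ``strict_nonwear``, which trusts the log only and raises on
    unexplained signal gaps), and the remaining waking-wear minutes are
    classified by the cut-points with an inclusive MVPA threshold.
    """
    if log.date != epochs.date:
        raise ValueError("wear log does not cover the epoch series date")
    labels = np.empty(MINUTES_PER_DAY, dtype=np.int8)
    labels.fill(SED)
    values = epochs.values

    waking = ~log.sleep_window_mask()

    removal = np.zeros(MINUTES_PER_DAY, dtype=bool)
    for s, e, _ in log.removals:
        removal[s:e] = True
    removal &= waking  # sleep wins inside the window

    missing = np.isnan(values) & waking & ~removal
    if strict_nonwear and missing.any():
        raise ValueError(
            f"{int(missing.sum())} waking minutes have no signal and no logged removal"
        )

    wear = waking & ~removal & ~missing
    v = values[wear]
    klass = np.where(v >= cuts.lpa_mvpa_threshold, MVPA,
                     np.where(v >= cuts.sed_lpa_threshold, LPA, SED))
    labels[wear] = klass
    labels[~waking] = SLEEP
    labels[removal | missing] = NONWEAR
    weekend = epochs.date.weekday() >= 5
    return LabelledDay(date=epochs.date, labels=labels, weekend=weekend)


def replace_sport_nonwear(
    day: LabelledDay, log: WearLog, participant_id: str | None = None
) -> DayComposition:
    """Count labelled minutes and reallocate "sports" removals.

    Each removal logged with reason ``"sports"`` (d minutes, counted within
    the waking day) is moved out of non-wear and split 40% MVPA / 40% LPA /
    20% sedentary.  Fractional minutes are carried in the daily totals; other
    non-wear is left untouched.  The 1440-minute total is conserved.
    """
    counts = np.bincount(day.labels, minlength=5).astype(float)
    sleep, nonwear, sed, lpa, mvpa = counts[:5]

    waking = ~log.sleep_window_mask()
    for s, e, reason in log.removals:
        if reason != "sports":
            continue
        d = float(np.count_nonzero(waking[s:e]))
        nonwear -= d
        mvpa += SPORT_MIX["mvpa"] * d
        lpa += SPORT_MIX["lpa"] * d
        sed += SPORT_MIX["sed"] * d

    pid = participant_id if participant_id is not None else log.participant_id
    return DayComposition(
        participant_id=pid, date=day.date, weekend=day.weekend,
        sleep_min=sleep, sed_min=sed, lpa_min=lpa, mvpa_min=mvpa,
        nonwear_min=nonwear,
    )


def day_is_valid(
    comp: DayComposition,
    *,
    max_nonwear_min: float = 360.0,
    min_waking_wear_min: float = 600.0,
) -> bool:
    """Wear screening: at most 6 h non-wear and at least 10 h waking wear.

    Both boundaries are inclusive.
    """
    return (comp.nonwear_min <= max_nonwear_min
            and comp.waking_wear_min() >= min_waking_wear_min)


def participant_is_valid(
    days: list[DayComposition], *, min_valid_days: int = 4
) -> bool:
    """A participant needs >= 4 valid days including >= 1 valid weekend day."""
    valid = [d for d in days if d.valid]
    return len(valid) >= min_valid_days and any(d.weekend for d in valid)


def normalize_to_1440(comp: DayComposition | np.ndarray) -> np.ndarray:
    """Linearly rescale the four behaviours to sum to 1440 min.

    This is the non-wear adjustment: non-wear minutes are redistributed
    proportionally across sleep/SED/LPA/MVPA.
    """
    parts = comp.parts() if isinstance(comp, DayComposition) else np.asarray(comp, dtype=float)
    if parts.shape[-1] != 4:
        raise ValueError("expected a 4-part behaviour vector")
    total = parts.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("cannot close a day with zero total wear")
    return parts * (MINUTES_PER_DAY / total)


def screen_days(days: list[DayComposition]) -> list[DayComposition]:
    """Return the days with their ``valid`` flags set by the wear rule."""
    return [replace(d, valid=day_is_valid(d)) for d in days]


def process_recording(
    recording: TriaxialRecording, log: WearLog, cuts: CutPoints | None = None
) -> DayComposition:
    """Raw signal + wear log -> validity-flagged daily composition."""
    cuts = cuts or CutPoints()
    svm = compute_svm(recording)
    epochs = aggregate_epochs(svm, recording)
    day = label_day(epochs, log, cuts)
    comp = replace_sport_nonwear(day, log, participant_id=recording.participant_id)
    comp.valid = day_is_valid(comp)
    return comp


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_raw_csv(path, participant_id: str, date: _dt.date,
                 sampling_rate_hz: float) -> TriaxialRecording:
    df = pd.read_csv(path)
    return TriaxialRecording(
        participant_id=participant_id, date=date,
        sampling_rate_hz=sampling_rate_hz,
        time_s=df["time_s"].to_numpy(),
        acc=df[["ax_g", "ay_g", "az_g"]].to_numpy(),
    )


def write_raw_csv(recording: TriaxialRecording, path) -> None:
    pd.DataFrame({
        "time_s": recording.time_s,
        "ax_g": recording.acc[:, 0],
        "ay_g": recording.acc[:, 1],
        "az_g": recording.acc[:, 2],
    }).to_csv(path, index=False)


def _fmt_hm(minute: int) -> str:
    return f"{minute // 60:02d}:{minute % 60:02d}"


def _parse_hm(text: str) -> int:
    h, m = text.split(":")
    return int(h) * 60 + int(m)


def write_wear_logs_csv(logs: list[WearLog], path) -> None:
    rows = []
    for log in logs:
        removals = log.removals or [(None, None, None)]
        for s, e, reason in removals:
            rows.append({
                "participant": log.participant_id,
                "date": log.date.isoformat(),
                "bed_time": _fmt_hm(log.bed_time),
                "getup_time": _fmt_hm(log.getup_time),
                "removal_start": _fmt_hm(s) if s is not None else "",
                "removal_end": _fmt_hm(e) if e is not None else "",
                "reason": reason or "",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_wear_logs_csv(path) -> list[WearLog]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    logs: dict[tuple[str, str], WearLog] = {}
    for row in df.itertuples(index=False):
        key = (row.participant, row.date)
        if key not in logs:
            logs[key] = WearLog(
                participant_id=row.participant,
                date=_dt.date.fromisoformat(row.date),
                bed_time=_parse_hm(row.bed_time),
                getup_time=_parse_hm(row.getup_time),
            )
        if row.removal_start:
            logs[key].removals.append(
                (_parse_hm(row.removal_start), _parse_hm(row.removal_end),
                 row.reason or None)
            )
    return list(logs.values())


def compositions_to_frame(days: list[DayComposition]) -> pd.DataFrame:
    """Per-day composition table in the package's CSV dialect."""
    return pd.DataFrame([{
        "participant": d.participant_id,
        "date": d.date.isoformat(),
        "weekend": int(d.weekend),
        "sleep_min": d.sleep_min,
        "sed_min": d.sed_min,
        "lpa_min": d.lpa_min,
        "mvpa_min": d.mvpa_min,
        "nonwear_min": d.nonwear_min,
        "valid": int(d.valid),
    } for d in days])


def write_compositions_csv(days: list[DayComposition], path) -> None:
    compositions_to_frame(days).to_csv(path, index=False)


def read_compositions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["weekend"] = df["weekend"].astype(bool)
    df["valid"] = df["valid"].astype(bool)
    return df
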