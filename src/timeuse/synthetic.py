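"""Synthetic cohort generator with known ground-truth behaviour schedules.

Emulates the measurement setting of a primary-school accelerometry cohort:
children wear a wrist device for a week at a time while keeping a paper wear
log, and separately complete interviewer-administered 24-h recalls at 5-min
resolution.  Every downstream stage (signal processing, recall compilation,
matching, agreement, compositional modelling) can therefore be tested against
a known daily truth without any external data.

The generator is organised around three objects:

* :class:`BehaviourSchedule` — the ground truth: a minute-resolution tiling of
  one day into sleep / sedentary / LPA / MVPA / non-wear segments;
* :func:`generate_raw_day` — a stylised triaxial signal whose per-minute epoch
  SVM lands inside configured intensity bands (the classifier only ever sees
  epoch SVM, so band placement is the only feature that matters);
* :func:`generate_recall_day` — a recall diary derived from the truth with
  configurable reporting biases: block-of-time rounding (epoch effect), a
  social-desirability shift of MVPA at the expense of LPA, homogenisation of
  interrupted quiet time (SED gains from LPA), absorption of night awakenings
  into sleep, and recall of the sleep window as bed-to-get-up rather than
  actual sleep.

All randomness flows from one seed through ``numpy.random.SeedSequence``
substreams per participant-day, so any single day can be regenerated in
isolation.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .accel import (
    BEHAVIOURS,
    MINUTES_PER_DAY,
    CutPoints,
    TriaxialRecording,
    WearLog,
)

logger = logging.getLogger(__name__)

PUBERTY_LEVELS = ("pre", "early", "mid", "late", "post")
EDUCATION_LEVELS = ("low", "mid", "high")

#: MET values attached to diary activities, one per behaviour; each sits
#: strictly inside its classification band (<1.5 / 1.5-2.99 / >=3).
DEFAULT_METS = {"sleep": 0.9, "sed": 1.3, "lpa": 2.3, "mvpa": 4.5}


# ---------------------------------------------------------------------------
# Ground-truth schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    behaviour: str  # sleep / sed / lpa / mvpa / nonwear
    start: int
    duration: int
    reason: str | None = None  # only for nonwear


@dataclass
class BehaviourSchedule:
    """Ground-truth tiling of one participant-day into behaviour segments.

    Segments tile [0, 1440) exactly with no gap or overlap.  ``bed_time`` and
    ``getup_time`` record the (logged) sleep window; awake segments may occur
    inside the window (night awakenings), which is exactly what a log-based
    sleep classifier cannot see.
    """

    participant_id: str
    date: _dt.date
    segments: list[Segment]
    bed_time: int = MINUTES_PER_DAY
    getup_time: int = 0

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError(
                    f"segments must tile the day: expected start {pos}, got {seg.start}"
                )
            if seg.duration < 1:
                raise ValueError("segment durations must be >= 1 minute")
            if seg.behaviour not in BEHAVIOURS + ("nonwear",):
                raise ValueError(f"unknown behaviour {seg.behaviour!r}")
            pos += seg.duration
        if pos != MINUTES_PER_DAY:
            raise ValueError(f"segments cover {pos} minutes, expected {MINUTES_PER_DAY}")

    def minutes(self) -> np.ndarray:
        """Per-minute behaviour names (object array of length 1440)."""
        out = np.empty(MINUTES_PER_DAY, dtype=object)
        for seg in self.segments:
            out[seg.start: seg.start + seg.duration] = seg.behaviour
        return out

    def composition(self) -> dict[str, int]:
        """True minutes per behaviour (plus non-wear)."""
        totals = {b: 0 for b in BEHAVIOURS + ("nonwear",)}
        for seg in self.segments:
            totals[seg.behaviour] += seg.duration
        return totals

    def weekend(self) -> bool:
        return self.date.weekday() >= 5


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeviceParams:
    """Signal model for the simulated wrist device.

    ``svm_bands`` gives, per behaviour, the (low, high) band in which each
    minute's target epoch SVM (g·min) is drawn uniformly.  Bands must lie
    strictly inside the classifier's cut-point bands, otherwise ground truth
    would be ambiguous at a boundary.  ``nonwear_mode`` chooses whether
    non-wear appears as absent samples (default) or as a flat 1-g gravity
    signal (to exercise log-only non-wear handling).
    """

    sampling_rate_hz: float = 50.0
    svm_bands: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "sleep": (0.0, 0.4),
        "sed": (0.8, 4.6),
        "lpa": (6.2, 13.2),
        "mvpa": (15.6, 32.0),
    })
    nonwear_mode: str = "absent"  # "absent" | "gravity"

    def validate_against(self, cuts: CutPoints) -> None:
        limits = {
            "sleep": (0.0, cuts.sed_lpa_threshold),
            "sed": (0.0, cuts.sed_lpa_threshold),
            "lpa": (cuts.sed_lpa_threshold, cuts.lpa_mvpa_threshold),
            "mvpa": (cuts.lpa_mvpa_threshold, math.inf),
        }
        for b, (lo, hi) in self.svm_bands.items():
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid SVM band for {b}: ({lo}, {hi})")
            klo, khi = limits[b]
            # the lower classifier edge is inclusive, the upper exclusive
            if lo < klo or hi >= khi:
                raise ValueError(
                    f"SVM band for {b} ({lo}, {hi}) overlaps a cut-point "
                    f"boundary of [{klo}, {khi}); ground truth would be ambiguous"
                )
        if self.nonwear_mode not in ("absent", "gravity"):
            raise ValueError("nonwear_mode must be 'absent' or 'gravity'")


@dataclass(frozen=True)
class BiasParams:
    """Recall-reporting bias model.

    * ``block_min`` — recall granularity: diary segment boundaries are
      rounded to the nearest multiple of this block (epoch effect).  Must be
      a positive multiple of 5.
    * ``mvpa_shift_min`` — minutes of LPA reported as MVPA (social
      desirability; sport remembered as entirely vigorous).
    * ``sed_to_lpa_shift_min`` — minutes of LPA reported as sedentary time
      (interruptions of quiet blocks forgotten); negative values shift the
      other way.
    * ``sleep_extension_min`` — the sleep window is recalled as bed time to
      get-up time and stretched by this many minutes at the expense of
      adjacent sedentary time (sleep onset latency and lie-ins forgotten).
    * ``absorb_awakenings`` — whether awake intervals inside the sleep window
      are reported as sleep.

    Defaults reproduce, in expectation, self-minus-device mean differences of
    +37 sleep, +12 sedentary, −83 LPA and +34 MVPA min/day — the magnitude of
    reporting bias observed in primary-school cohorts using this pairing of
    instruments.
    """

    block_min: int = 15
    mvpa_shift_min: float = 34.0
    sed_to_lpa_shift_min: float = 49.0
    sleep_extension_min: float = 37.0
    absorb_awakenings: bool = True
    mets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_METS))

    def __post_init__(self) -> None:
        if self.block_min <= 0 or self.block_min % 5:
            raise ValueError("block_min must be a positive multiple of 5")
        for name in ("mvpa_shift_min", "sed_to_lpa_shift_min", "sleep_extension_min"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def zero_bias() -> BiasParams:
    """Bias parameters that make the diary a faithful report of the truth."""
    return BiasParams(block_min=5, mvpa_shift_min=0.0,
                      sed_to_lpa_shift_min=0.0, sleep_extension_min=0.0,
                      absorb_awakenings=False)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level study conditions.

    Characteristic distribution centres default to the marginals of the
    emulated cohort: n=120 children aged ~10 (67% girls), zBMI 0.17 (1.20),
    VO2max 40.1 (6.6) mL/kg/min, academic score 126 (9) with ~14% missing.
    The base true composition is the device-measured cohort mean
    (588/488/279/85 min of sleep/SED/LPA/MVPA, which sums to 1440), with
    sex-specific level means from the same source.

    Day-to-day and between-child compositional variation is a symmetric
    Dirichlet perturbation around the level mean; ``person_dispersion`` and
    ``day_dispersion`` are the approximate relative standard deviations
    (sd of a part ≈ dispersion × sqrt(p(1−p)) of its share); 0 means exact.
    """

    n_participants: int = 120
    n_schools: int = 12
    n_waves: int = 2
    days_per_participant: int = 7
    weekend_fraction: float = 2 / 7
    sex_female_prop: float = 0.67
    age_mean: float = 10.0
    age_sd: float = 0.3
    puberty_probs: tuple[float, ...] = (0.65, 0.20, 0.15, 0.0, 0.0)
    parental_ed_probs: tuple[float, ...] = (0.07, 0.36, 0.57)
    zbmi_mean: float = 0.17
    zbmi_sd: float = 1.20
    vo2max_mean: float = 40.1
    vo2max_sd: float = 6.6
    academic_mean: float = 126.0
    academic_sd: float = 9.0
    academic_missing_prob: float = 0.14
    mean_composition: tuple[float, ...] = (588.0, 488.0, 279.0, 85.0)
    sex_compositions: dict[str, tuple[float, ...]] | None = field(
        default_factory=lambda: {
            "male": (595.0, 459.0, 280.0, 106.0),
            "female": (585.0, 502.0, 278.0, 75.0),
        })
    person_dispersion: float = 0.07
    day_dispersion: float = 0.05
    nonwear_mean_min: float = 24.0
    nonwear_sd_min: float = 45.0
    sports_nonwear_prob: float = 0.3
    night_awakening_min: int = 0
    #: minute grid for ground-truth segments (1 = free; 5 aligns the truth
    #: with the recall instrument's resolution, making zero-bias diaries exact)
    schedule_grid_min: int = 1
    bias: BiasParams = field(default_factory=BiasParams)
    bias_by_sex: dict[str, BiasParams] | None = None
    device: DeviceParams = field(default_factory=DeviceParams)
    cuts: CutPoints = field(default_factory=CutPoints)
    seed: int = 0

    def __post_init__(self) -> None:
        for probs, name in ((self.puberty_probs, "puberty_probs"),
                            (self.parental_ed_probs, "parental_ed_probs")):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        comps = [self.mean_composition] + list((self.sex_compositions or {}).values())
        for comp in comps:
            comp = np.asarray(comp, dtype=float)
            if comp.shape != (4,) or np.any(comp <= 0):
                raise ValueError("true compositions must be 4 strictly positive parts")
            if abs(comp.sum() - MINUTES_PER_DAY) > 1e-6:
                raise ValueError("true compositions must sum to 1440 min")
        if not (0 <= self.sex_female_prop <= 1 and 0 <= self.weekend_fraction <= 1):
            raise ValueError("proportions must lie in [0, 1]")
        self.device.validate_against(self.cuts)


@dataclass
class Participant:
    """Characteristics skeleton for one simulated child."""

    participant_id: str
    school_id: str
    wave: int
    sex: str
    age: float
    puberty: str
    parental_education: str
    zbmi: float
    vo2max: float
    academic: float  # NaN if missing


# ---------------------------------------------------------------------------
# Small numeric helpers
# ---------------------------------------------------------------------------

def _round_preserving_sum(x: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of non-negative reals to ints summing to total."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    if x.sum() <= 0:
        raise ValueError("cannot apportion a zero vector")
    scaled = x * (total / x.sum())
    floors = np.floor(scaled).astype(int)
    short = total - int(floors.sum())
    order = np.argsort(-(scaled - floors), kind="stable")
    floors[order[:short]] += 1
    return floors


def dirichlet_perturb(rng: np.random.Generator, mean: np.ndarray,
                      dispersion: float) -> np.ndarray:
    """Dirichlet draw around ``mean`` (a probability vector).

    ``dispersion`` is the approximate relative sd of each part's share:
    concentration c = 1/dispersion^2 − 1, so dispersion 0 returns the mean
    exactly.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return mean.copy()
    c = 1.0 / dispersion**2 - 1.0
    return rng.dirichlet(mean * c)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_WAVE_START = {1: _dt.date(2019, 2, 4), 2: _dt.date(2020, 2, 3)}  # Mondays


def _draw_dates(rng: np.random.Generator, wave: int, n_days: int,
                weekend_fraction: float) -> list[_dt.date]:
    """Distinct measurement dates scattered over the wave's school year."""
    start = _WAVE_START.get(wave, _WAVE_START[1])
    dates: set[_dt.date] = set()
    while len(dates) < n_days:
        week = int(rng.integers(0, 44))
        if rng.random() < weekend_fraction:
            dow = int(rng.integers(5, 7))
        else:
            dow = int(rng.integers(0, 5))
        dates.add(start + _dt.timedelta(days=7 * week + dow))
    return sorted(dates)


def _participant_mean_composition(config: CohortConfig, sex: str) -> np.ndarray:
    if config.sex_compositions and sex in config.sex_compositions:
        comp = np.asarray(config.sex_compositions[sex], dtype=float)
    else:
        comp = np.asarray(config.mean_composition, dtype=float)
    return comp / comp.sum()


def build_day_schedule(
    participant_id: str,
    date: _dt.date,
    parts_min: np.ndarray,
    rng: np.random.Generator,
    *,
    nonwear_min: int = 0,
    sports: bool = False,
    night_awakening_min: int = 0,
    grid_min: int = 1,
) -> BehaviourSchedule:
    """Convert integer behaviour minutes into a concrete segment tiling.

    Sleep is split across midnight (morning block from 0 to get-up, evening
    block from bed time); waking behaviours are shuffled into blocks of at
    most an hour.  A sports non-wear interval is carved from MVPA/LPA/SED in
    the canonical 40/40/20 mix (so the downstream reallocation is exact);
    other non-wear is carved proportionally from the waking behaviours.
    """
    g = max(int(grid_min), 1)
    if g > 1:
        parts_min = _round_preserving_sum(
            np.asarray(parts_min, dtype=float) / g, MINUTES_PER_DAY // g) * g
    sleep, sed, lpa, mvpa = (int(v) for v in parts_min)
    reason = None
    if nonwear_min > 0:
        nonwear_min = min(nonwear_min, sed + lpa + mvpa - 60)
        nonwear_min = max(5 * (nonwear_min // 5), 0)
    if nonwear_min > 0 and sports:
        take_m, take_l, take_s = (int(round(f * nonwear_min))
                                  for f in (0.4, 0.4, 0.2))
        if take_m <= mvpa and take_l <= lpa and take_s <= sed:
            mvpa, lpa, sed = mvpa - take_m, lpa - take_l, sed - take_s
            reason = "sports"
        else:
            sports = False
    if nonwear_min > 0 and not sports:
        takes = _round_preserving_sum(np.array([sed, lpa, mvpa]), nonwear_min)
        if np.all(takes <= np.array([sed, lpa, mvpa])):
            sed, lpa, mvpa = sed - takes[0], lpa - takes[1], mvpa - takes[2]
        else:
            nonwear_min = 0

    awak = 0
    if night_awakening_min > 0:
        awak = min(5 * (night_awakening_min // 5), max(sleep - 240, 0))
        sleep -= awak

    # anchor the window so the child wakes around 06:30-07:30: the evening
    # block (bed time to midnight) absorbs the rest of the night
    total_night = sleep + awak
    if total_night >= 130:
        evening = int(np.clip(total_night - 420, 120, 240))
    else:
        evening = total_night // 2
    evening = g * (evening // g)
    getup = total_night - evening
    bed = MINUTES_PER_DAY - evening

    # waking blocks: chunk each behaviour into <= 60-minute pieces, shuffle
    blocks: list[tuple[str, int]] = []
    for name, total in (("sed", sed), ("lpa", lpa), ("mvpa", mvpa)):
        remaining = total
        while remaining > 0:
            d = min(60, remaining)
            blocks.append((name, d))
            remaining -= d
    rng.shuffle(blocks)
    if nonwear_min > 0:
        pos = int(rng.integers(0, len(blocks) + 1))
        blocks.insert(pos, ("nonwear", nonwear_min))

    segments: list[Segment] = []
    cursor = 0

    def emit(behaviour: str, duration: int, why: str | None = None) -> None:
        nonlocal cursor
        if duration > 0:
            segments.append(Segment(behaviour, cursor, duration, why))
            cursor += duration

    if awak > 0:
        half = g * (getup // (2 * g))
        emit("sleep", half)
        emit("sed", awak)
        emit("sleep", getup - half - awak)
    else:
        emit("sleep", getup)
    for name, d in blocks:
        emit(name, d, reason if name == "nonwear" else None)
    emit("sleep", MINUTES_PER_DAY - bed)

    return BehaviourSchedule(
        participant_id=participant_id, date=date, segments=segments,
        bed_time=bed, getup_time=getup,
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[Participant], list[BehaviourSchedule]]:
    """Draw participants and their ground-truth daily schedules.

    Characteristics come from the configured distributions; each child is
    assigned a school (and through it a study wave), a participant-level mean
    composition perturbed around their sex-level mean, and per-day
    compositions perturbed around the participant mean.
    """
    root = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    day_seeds = root.spawn(config.n_participants)

    schools = [f"S{k + 1:02d}" for k in range(config.n_schools)]
    school_wave = {s: 1 + (k * config.n_waves) // config.n_schools
                   for k, s in enumerate(schools)}

    participants: list[Participant] = []
    schedules: list[BehaviourSchedule] = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        school = schools[int(cohort_rng.integers(0, config.n_schools))]
        sex = "female" if cohort_rng.random() < config.sex_female_prop else "male"
        academic = float(cohort_rng.normal(config.academic_mean, config.academic_sd))
        if cohort_rng.random() < config.academic_missing_prob:
            academic = float("nan")
        participants.append(Participant(
            participant_id=pid, school_id=school, wave=school_wave[school],
            sex=sex,
            age=float(cohort_rng.normal(config.age_mean, config.age_sd)),
            puberty=str(cohort_rng.choice(PUBERTY_LEVELS, p=config.puberty_probs)),
            parental_education=str(
                cohort_rng.choice(EDUCATION_LEVELS, p=config.parental_ed_probs)),
            zbmi=float(cohort_rng.normal(config.zbmi_mean, config.zbmi_sd)),
            vo2max=float(cohort_rng.normal(config.vo2max_mean, config.vo2max_sd)),
            academic=academic,
        ))

        prng = np.random.default_rng(day_seeds[i])
        level_mean = _participant_mean_composition(config, sex)
        person_mean = dirichlet_perturb(prng, level_mean, config.person_dispersion)
        dates = _draw_dates(prng, school_wave[school],
                            config.days_per_participant, config.weekend_fraction)
        for date in dates:
            day_prop = dirichlet_perturb(prng, person_mean, config.day_dispersion)
            parts = _round_preserving_sum(day_prop, MINUTES_PER_DAY)
            nonwear = 0
            if config.nonwear_sd_min > 0 or config.nonwear_mean_min > 0:
                draw = prng.normal(config.nonwear_mean_min, config.nonwear_sd_min)
                nonwear = int(np.clip(draw, 0, 300))
            sports = bool(prng.random() < config.sports_nonwear_prob)
            schedules.append(build_day_schedule(
                pid, date, parts, prng,
                nonwear_min=nonwear, sports=sports,
                night_awakening_min=config.night_awakening_min,
                grid_min=config.schedule_grid_min,
            ))
    return participants, schedules


# ---------------------------------------------------------------------------
# Raw signal synthesis
# ---------------------------------------------------------------------------

def generate_raw_day(
    schedule: BehaviourSchedule,
    device: DeviceParams,
    seed: int | np.random.SeedSequence | np.random.Generator,
    cuts: CutPoints | None = None,
) -> tuple[TriaxialRecording, WearLog]:
    """Emit a stylised triaxial recording plus the matching wear log.

    Each wear minute draws a target epoch SVM uniformly inside its
    behaviour's configured band, realised as white noise rescaled so the
    minute's mean per-sample SVM hits the target exactly; the magnitude is
    carried on the vertical axis around 1 g with random sign.  Non-wear
    minutes are absent from the sample stream (or a flat 1-g gravity signal
    when ``device.nonwear_mode == "gravity"``).
    """
    device.validate_against(cuts or CutPoints())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    minute_behaviour = schedule.minutes()
    per_min = int(round(device.sampling_rate_hz * 60))
    if per_min < 1:
        raise ValueError("sampling rate must give at least one sample per minute")

    keep = np.ones(MINUTES_PER_DAY, dtype=bool)
    if device.nonwear_mode == "absent":
        keep = minute_behaviour != "nonwear"

    targets = np.zeros(MINUTES_PER_DAY)
    for b, (lo, hi) in device.svm_bands.items():
        m = minute_behaviour == b
        targets[m] = rng.uniform(lo, hi, size=int(m.sum()))

    kept_minutes = np.flatnonzero(keep)
    n = kept_minutes.size * per_min
    time_s = (np.repeat(kept_minutes * 60.0, per_min)
              + np.tile((np.arange(per_min) + 0.5) / device.sampling_rate_hz,
                        kept_minutes.size))
    # white noise, renormalised per minute so the minute mean SVM is exact
    w = np.abs(rng.standard_normal(n)).reshape(kept_minutes.size, per_min)
    w /= w.mean(axis=1, keepdims=True)
    svm = w * (targets[kept_minutes, None] / 60.0)
    signs = rng.choice([-1.0, 1.0], size=svm.shape)
    az = 1.0 + signs * svm
    acc = np.zeros((n, 3))
    acc[:, 2] = az.ravel()

    recording = TriaxialRecording(
        participant_id=schedule.participant_id, date=schedule.date,
        sampling_rate_hz=device.sampling_rate_hz, time_s=time_s, acc=acc,
    )
    removals = [(seg.start, seg.start + seg.duration, seg.reason)
                for seg in schedule.segments if seg.behaviour == "nonwear"]
    log = WearLog(
        participant_id=schedule.participant_id, date=schedule.date,
        bed_time=schedule.bed_time, getup_time=schedule.getup_time,
        removals=removals,
    )
    return recording, log


def wear_log_for(schedule: BehaviourSchedule) -> WearLog:
    """The wear log implied by a schedule, without synthesising any signal."""
    removals = [(seg.start, seg.start + seg.duration, seg.reason)
                for seg in schedule.segments if seg.behaviour == "nonwear"]
    return WearLog(participant_id=schedule.participant_id, date=schedule.date,
                   bed_time=schedule.bed_time, getup_time=schedule.getup_time,
                   removals=removals)


# ---------------------------------------------------------------------------
# Recall diary synthesis
# ---------------------------------------------------------------------------

def _in_sleep_window(schedule: BehaviourSchedule, seg: Segment) -> bool:
    end = seg.start + seg.duration
    return end <= schedule.getup_time or seg.start >= schedule.bed_time


def generate_recall_day(
    schedule: BehaviourSchedule,
    bias: BiasParams,
    seed: int | np.random.SeedSequence | np.random.Generator,
):
    """Derive a recall diary from the true schedule under the bias model.

    Steps, in order:

    1. non-wear is reported as what the child was doing: sports removals as
       the canonical 40/40/20 MVPA/LPA/SED mix, other removals as sedentary;
    2. awake intervals inside the sleep window are absorbed into sleep when
       ``absorb_awakenings`` is set;
    3. segment boundaries are snapped to the recall block grid (epoch
       effect);
    4. behaviour totals receive the configured desirability /
       homogenisation / sleep-extension shifts, clamped at a 5-minute floor
       (with a logged warning) if a shift would exhaust a behaviour;
    5. the diary is re-tiled to exactly 1440 min on a 5-minute grid, with
       sleep split across midnight in the same proportions as the truth.
    """
    from .recall import RecallDiaryDay  # local import to avoid a cycle

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    runs: list[tuple[str, float]] = []
    for seg in schedule.segments:
        if seg.behaviour == "nonwear":
            if seg.reason == "sports":
                runs += [("mvpa", 0.4 * seg.duration),
                         ("lpa", 0.4 * seg.duration),
                         ("sed", 0.2 * seg.duration)]
            else:
                runs.append(("sed", float(seg.duration)))
        elif (bias.absorb_awakenings and seg.behaviour != "sleep"
              and _in_sleep_window(schedule, seg)):
            runs.append(("sleep", float(seg.duration)))
        else:
            runs.append((seg.behaviour, float(seg.duration)))

    # epoch effect: snap cumulative boundaries to the recall block grid
    block = bias.block_min
    bounds = np.cumsum([d for _, d in runs])
    snapped = np.round(bounds / block) * block
    totals = dict.fromkeys(BEHAVIOURS, 0.0)
    prev = 0.0
    for (behaviour, _), b in zip(runs, snapped):
        totals[behaviour] += max(b - prev, 0.0)
        prev = max(b, prev)

    def shift(src: str, dst: str, amount: float) -> None:
        if amount == 0:
            return
        if amount < 0:
            src, dst, amount = dst, src, -amount
        available = totals[src] - 5.0
        if amount > available:
            logger.warning(
                "recall bias clamped: shifting %.0f min from %s would leave "
                "less than the 5-min floor on %s for %s; shifted %.0f",
                amount, src, src, schedule.date, max(available, 0.0))
            amount = max(available, 0.0)
        totals[src] -= amount
        totals[dst] += amount

    shift("lpa", "mvpa", bias.mvpa_shift_min)
    shift("lpa", "sed", bias.sed_to_lpa_shift_min)
    shift("sed", "sleep", bias.sleep_extension_min)

    grid = _round_preserving_sum(
        np.array([totals[b] for b in BEHAVIOURS]) / 5.0, MINUTES_PER_DAY // 5) * 5
    totals = dict(zip(BEHAVIOURS, (int(v) for v in grid)))

    # re-tile: morning sleep, waking blocks, evening sleep
    sleep = totals["sleep"]
    true_sleep = max(schedule.composition()["sleep"], 1)
    morning = 5 * int(round(sleep * (schedule.getup_time / true_sleep) / 5))
    morning = int(np.clip(morning, 0, sleep))
    evening = sleep - morning

    blocks: list[tuple[str, int]] = []
    for name in ("sed", "lpa", "mvpa"):
        remaining = totals[name]
        while remaining > 0:
            d = min(90, remaining)
            if remaining - d == 5:  # avoid leaving an orphan < block chunk
                d -= 5
            blocks.append((name, d))
            remaining -= d
    rng.shuffle(blocks)

    segments: list[tuple[int, int, str, float]] = []
    cursor = 0
    for name, d in ([("sleep", morning)] + blocks + [("sleep", evening)]):
        if d > 0:
            segments.append((cursor, cursor + d, name, bias.mets[name]))
            cursor += d
    return RecallDiaryDay(participant_id=schedule.participant_id,
                          date=schedule.date, segments=segments)


# ---------------------------------------------------------------------------
# Whole-study convenience bundle and CSV interfaces
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: CohortConfig
    participants: list[Participant]
    schedules: list[BehaviourSchedule]
    wear_logs: list[WearLog]
    diaries: list  # RecallDiaryDay

    def participants_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.participants])

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.schedules:
            comp = s.composition()
            rows.append({
                "participant": s.participant_id, "date": s.date.isoformat(),
                "sleep_min": comp["sleep"], "sed_min": comp["sed"],
                "lpa_min": comp["lpa"], "mvpa_min": comp["mvpa"],
                "nonwear_min": comp["nonwear"],
            })
        return pd.DataFrame(rows)


def generate_study(config: CohortConfig) -> SimulatedStudy:
    """Generate participants, truth schedules, wear logs and recall diaries.

    Raw signal is intentionally not materialised here (a week of 50-Hz data
    per child is large); regenerate any day's signal reproducibly with
    :func:`raw_day_seed` and :func:`generate_raw_day`.
    """
    participants, schedules = generate_cohort(config)
    bias_by_sex = config.bias_by_sex or {}
    sex_of = {p.participant_id: p.sex for p in participants}
    logs, diaries = [], []
    for sched in schedules:
        logs.append(wear_log_for(sched))
        bias = bias_by_sex.get(sex_of[sched.participant_id], config.bias)
        diaries.append(generate_recall_day(
            sched, bias, raw_day_seed(config.seed, sched) + 1))
    return SimulatedStudy(config=config, participants=participants,
                          schedules=schedules, wear_logs=logs, diaries=diaries)


def raw_day_seed(seed: int, schedule: BehaviourSchedule) -> int:
    """Deterministic per-participant-day substream seed (< 2**31)."""
    h = np.random.SeedSequence(
        [seed, abs(hash((schedule.participant_id, schedule.date.toordinal()))) % (2**31)]
    )
    return int(h.generate_state(1)[0] % (2**31))


def write_schedules_csv(schedules: list[BehaviourSchedule], path) -> None:
    rows = []
    for s in schedules:
        for seg in s.segments:
            rows.append({
                "participant": s.participant_id, "date": s.date.isoformat(),
                "start_min": seg.start, "duration_min": seg.duration,
                "behaviour": seg.behaviour, "reason": seg.reason or "",
                "bed_time": s.bed_time, "getup_time": s.getup_time,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_schedules_csv(path) -> list[BehaviourSchedule]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for (pid, date), grp in df.groupby(["participant", "date"], sort=True):
        grp = grp.sort_values("start_min")
        segments = [
            Segment(r.behaviour, int(r.start_min), int(r.duration_min),
                    r.reason or None)
            for r in grp.itertuples(index=False)
        ]
        out.append(BehaviourSchedule(
            participant_id=str(pid), date=_dt.date.fromisoformat(str(date)),
            segments=segments, bed_time=int(grp["bed_time"].iloc[0]),
            getup_time=int(grp["getup_time"].iloc[0]),
        ))
    return out


def write_truth_csv(study: SimulatedStudy, path) -> None:
    study.truth_frame().to_csv(path, index=False)


def write_participants_csv(study: SimulatedStudy, path) -> None:
    study.participants_frame().to_csv(path, index=False)


def read_participants_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
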