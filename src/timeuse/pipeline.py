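"""End-to-end pipeline: simulate → accel → recall → match → agree → model.

Each stage reads and writes plain CSV in the package's dialects, so stages
can be run individually (e.g. to swap in real data at any point) or as one
shot.  Every output file carries the configuration hash in a leading comment
line; two runs with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import accel, agreement, coda, matching, recall, synthetic

logger = logging.getLogger(__name__)

STAGES = ("simulate", "accel", "recall", "match", "agree", "model")


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    min_sleep_min: float = 300.0       # recall-day exclusion threshold
    alpha: float = 0.05
    pattern_tolerance_min: float = 5.0
    characteristics: tuple[str, ...] = coda.ALL_CHARACTERISTICS
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_sleep_min <= 0 or self.pattern_tolerance_min <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def seed(self) -> int:
        return self.cohort.seed


def _to_dict(obj) -> object:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file plus keyword overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    cohort_raw = raw.pop("cohort", {})
    for key, cls in (("bias", synthetic.BiasParams),
                     ("device", synthetic.DeviceParams),
                     ("cuts", accel.CutPoints)):
        if key in cohort_raw and isinstance(cohort_raw[key], dict):
            cohort_raw[key] = cls(**cohort_raw[key])
    for name in ("puberty_probs", "parental_ed_probs", "mean_composition"):
        if name in cohort_raw:
            cohort_raw[name] = tuple(cohort_raw[name])
    if "characteristics" in raw:
        raw["characteristics"] = tuple(raw["characteristics"])
    return RunConfig(cohort=synthetic.CohortConfig(**cohort_raw), **raw)


def _write_csv(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={chash}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


class PipelineRun:
    """Stage runner bound to one configuration and output directory."""

    def __init__(self, config: RunConfig, outdir) -> None:
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.hash = config_hash(config)

    def path(self, name: str) -> Path:
        return self.outdir / name

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        study = synthetic.generate_study(self.config.cohort)
        _write_csv(study.participants_frame(), self.path("participants.csv"), self.hash)
        _write_csv(study.truth_frame(), self.path("truth.csv"), self.hash)

        sched_rows, log_rows, diary_rows = [], [], []
        for s in study.schedules:
            for seg in s.segments:
                sched_rows.append({
                    "participant": s.participant_id, "date": s.date.isoformat(),
                    "start_min": seg.start, "duration_min": seg.duration,
                    "behaviour": seg.behaviour, "reason": seg.reason or "",
                    "bed_time": s.bed_time, "getup_time": s.getup_time})
        for d in study.diaries:
            for start, end, activity, met in d.segments:
                diary_rows.append({
                    "participant": d.participant_id, "date": d.date.isoformat(),
                    "start_min": start, "end_min": end,
                    "activity": activity, "met": met})
        _write_csv(pd.DataFrame(sched_rows), self.path("schedules.csv"), self.hash)
        _write_csv(pd.DataFrame(diary_rows), self.path("diaries.csv"), self.hash)

    def accel(self) -> None:
        """Synthesize each day's raw signal and process it to a composition.

        Raw signal is regenerated per participant-day from the seeded
        substream rather than stored (a week of high-rate triaxial data per
        child is far too large to keep around).
        """
        cohort = self.config.cohort
        schedules = self._read_schedules()
        days: list[accel.DayComposition] = []
        for sched in schedules:
            rec, log = synthetic.generate_raw_day(
                sched, cohort.device,
                synthetic.raw_day_seed(cohort.seed, sched), cohort.cuts)
            days.append(accel.process_recording(rec, log, cohort.cuts))
        by_pid: dict[str, list[accel.DayComposition]] = {}
        for d in days:
            by_pid.setdefault(d.participant_id, []).append(d)
        pvalid = {pid: accel.participant_is_valid(ds) for pid, ds in by_pid.items()}
        frame = accel.compositions_to_frame(days)
        frame["participant_valid"] = frame["participant"].map(pvalid).astype(int)
        _write_csv(frame, self.path("device_days.csv"), self.hash)

    def recall(self) -> None:
        diaries = self._read_diaries()
        compiled = recall.compile_diaries(diaries)
        kept, report = recall.exclude_low_sleep(
            compiled, min_sleep_min=self.config.min_sleep_min)
        _write_csv(kept, self.path("self_days.csv"), self.hash)
        self._write_json("recall_exclusions.json", report)

    def match(self) -> None:
        device = _read_csv(self.path("device_days.csv"))
        device["valid"] = device["valid"].astype(bool) & device[
            "participant_valid"].astype(bool)
        selfr = _read_csv(self.path("self_days.csv"))
        participants = _read_csv(self.path("participants.csv"))
        matched = matching.match_days(device, selfr)
        table, report = matching.average_per_participant(matched, participants)
        _write_csv(table, self.path("analysis_table.csv"), self.hash)
        self._write_json("match_report.json",
                         {**report, "n_matched_days": int(len(matched))})

    def agree(self) -> None:
        table = _read_csv(self.path("analysis_table.csv"))
        summaries = agreement.summarize_agreement(table)
        _write_csv(agreement.agreement_table(summaries),
                   self.path("agreement.csv"), self.hash)
        if self.config.make_plots:
            for b, s in summaries.items():
                agreement.bland_altman_plot(s, self.path(f"bland_altman_{b}.png"))

    def model(self) -> None:
        table = _read_csv(self.path("analysis_table.csv"))
        results, skipped = [], {}
        for char in self.config.characteristics:
            try:
                results.append(coda.run_characteristic_analysis(
                    table, char, tolerance=self.config.pattern_tolerance_min))
            except ValueError as err:
                skipped[char] = str(err)
                logger.warning("skipping %s: %s", char, err)
        report = coda.interaction_report(results)
        report["significant"] = (report["p"] < self.config.alpha).astype(int)
        _write_csv(report, self.path("interactions.csv"), self.hash)
        patterns = pd.DataFrame([
            {"characteristic": r.characteristic, **r.patterns} for r in results])
        _write_csv(patterns, self.path("patterns.csv"), self.hash)
        if skipped:
            self._write_json("model_skipped.json", skipped)
        if self.config.make_plots and results:
            coda.plot_estimates(results, self.path("estimates.png"))

    # -- helpers -----------------------------------------------------------

    def _read_schedules(self):
        df = _read_csv(self.path("schedules.csv"), keep_default_na=False)
        import datetime as _dt
        out = []
        for (pid, date), grp in df.groupby(["participant", "date"], sort=True):
            grp = grp.sort_values("start_min")
            segments = [synthetic.Segment(r.behaviour, int(r.start_min),
                                          int(r.duration_min), r.reason or None)
                        for r in grp.itertuples(index=False)]
            out.append(synthetic.BehaviourSchedule(
                participant_id=str(pid), date=_dt.date.fromisoformat(str(date)),
                segments=segments, bed_time=int(grp["bed_time"].iloc[0]),
                getup_time=int(grp["getup_time"].iloc[0])))
        return out

    def _read_diaries(self):
        import datetime as _dt
        df = _read_csv(self.path("diaries.csv"))
        out = []
        for (pid, date), grp in df.groupby(["participant", "date"], sort=True):
            grp = grp.sort_values("start_min")
            segments = [(int(r.start_min), int(r.end_min), str(r.activity),
                         float(r.met)) for r in grp.itertuples(index=False)]
            out.append(recall.RecallDiaryDay(
                participant_id=str(pid), date=_dt.date.fromisoformat(str(date)),
                segments=segments))
        return out

    def _write_json(self, name: str, payload: dict) -> None:
        data = {"config": self.hash, **payload}
        self.path(name).write_text(json.dumps(data, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage in order and write a machine-readable summary.

    Any stage failure aborts with the stage name attached.  Returns the
    summary dictionary (also written to ``summary.json``).
    """
    run = PipelineRun(config, outdir)
    for stage in STAGES:
        try:
            getattr(run, stage)()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    agree_df = _read_csv(run.path("agreement.csv"))
    inter_df = _read_csv(run.path("interactions.csv"))
    summary = {
        "config_hash": run.hash,
        "seed": config.seed,
        "versions": {
            "timeuse": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "agreement": {
            row["behaviour"]: {
                "icc": round(float(row["icc"]), 4),
                "bias_min": round(float(row["bias_min"]), 2),
                "mape_pct": round(float(row["mape_pct"]), 2),
            } for _, row in agree_df.iterrows()},
        "interactions": {
            char: {"chi2": round(float(grp["chi2"].iloc[0]), 2),
                   "df": int(grp["df"].iloc[0]),
                   "p": round(float(grp["p"].iloc[0]), 4)}
            for char, grp in inter_df.groupby("characteristic")},
    }
    run._write_json("summary.json", summary)
    return summary
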