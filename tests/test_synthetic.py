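"""Cohort generator: tiling invariants, determinism, signal and diary biases."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

from timeuse import accel
from timeuse.accel import CutPoints
from timeuse.recall import compile_recall_day
from timeuse.synthetic import (
    BehaviourSchedule,
    BiasParams,
    CohortConfig,
    DeviceParams,
    Segment,
    build_day_schedule,
    generate_cohort,
    generate_raw_day,
    generate_recall_day,
    generate_study,
    raw_day_seed,
    zero_bias,
)

DATE = dt.date(2019, 3, 11)


def _simple_schedule(nonwear=0, reason=None, awake=0):
    rng = np.random.default_rng(0)
    return build_day_schedule(
        "P1", DATE, np.array([580, 490, 280, 90]), rng,
        nonwear_min=nonwear, sports=reason == "sports",
        night_awakening_min=awake, grid_min=5)


class TestSchedules:
    def test_tiling_is_validated(self):
        with pytest.raises(ValueError, match="tile"):
            BehaviourSchedule("P1", DATE, [Segment("sleep", 0, 100),
                                           Segment("sed", 110, 1330)])
        with pytest.raises(ValueError, match="1440"):
            BehaviourSchedule("P1", DATE, [Segment("sleep", 0, 1000)])

    def test_generated_schedules_tile_and_sum(self):
        cfg = CohortConfig(n_participants=5, days_per_participant=4, seed=3)
        _, schedules = generate_cohort(cfg)
        for s in schedules:
            comp = s.composition()
            assert sum(comp.values()) == 1440  # tiling is enforced on build
            assert 0 <= s.getup_time < s.bed_time <= 1440

    def test_zero_dispersion_reproduces_level_mean(self):
        cfg = CohortConfig(n_participants=4, days_per_participant=3, seed=1,
                           person_dispersion=0.0, day_dispersion=0.0,
                           sex_compositions=None,
                           nonwear_mean_min=0, nonwear_sd_min=0)
        _, schedules = generate_cohort(cfg)
        for s in schedules:
            comp = s.composition()
            parts = [comp[b] for b in ("sleep", "sed", "lpa", "mvpa")]
            assert parts == [588, 488, 279, 85]

    def test_determinism(self):
        cfg = CohortConfig(n_participants=6, days_per_participant=3, seed=42)
        a = generate_study(cfg)
        b = generate_study(cfg)
        assert a.participants_frame().equals(b.participants_frame())
        assert a.truth_frame().equals(b.truth_frame())
        assert [d.segments for d in a.diaries] == [d.segments for d in b.diaries]

    def test_sex_counts_near_configured_proportion(self):
        cfg = CohortConfig(n_participants=120, days_per_participant=1, seed=2)
        participants, _ = generate_cohort(cfg)
        n_female = sum(p.sex == "female" for p in participants)
        # binomial(120, 0.67): mean 80.4, sd 5.1 — stay within 3 sd
        assert abs(n_female - 80.4) < 3 * 5.2

    def test_rejects_invalid_mean_composition(self):
        with pytest.raises(ValueError, match="positive"):
            CohortConfig(mean_composition=(1440.0, 0.0, 0.0, 0.0),
                         sex_compositions=None)

    def test_characteristic_means_converge(self):
        cfg = CohortConfig(n_participants=2000, days_per_participant=1, seed=9)
        participants, _ = generate_cohort(cfg)
        age = np.array([p.age for p in participants])
        vo2 = np.array([p.vo2max for p in participants])
        assert abs(age.mean() - 10.0) < 3 * 0.3 / np.sqrt(2000)
        assert abs(vo2.mean() - 40.1) < 3 * 6.6 / np.sqrt(2000)
        n_f = sum(p.sex == "female" for p in participants)
        assert abs(n_f / 2000 - 0.67) < 3 * np.sqrt(0.67 * 0.33 / 2000)


class TestRawSignal:
    def test_stationary_sleep_only_day(self):
        sched = BehaviourSchedule("P1", DATE, [Segment("sleep", 0, 1440)],
                                  bed_time=1440, getup_time=0)
        device = DeviceParams(sampling_rate_hz=2.0,
                              svm_bands={"sleep": (0.0, 0.0), "sed": (1.0, 4.0),
                                         "lpa": (6.0, 13.0), "mvpa": (15.0, 30.0)})
        rec, _ = generate_raw_day(sched, device, seed=0)
        norms = np.linalg.norm(rec.acc, axis=1)
        assert np.allclose(norms, 1.0)

    def test_classifier_recovers_schedule_labels(self):
        sched = _simple_schedule()
        device = DeviceParams(sampling_rate_hz=2.0)
        rec, log = generate_raw_day(sched, device, seed=7)
        epochs = accel.aggregate_epochs(accel.compute_svm(rec), rec)
        day = accel.label_day(epochs, log, CutPoints())
        names = np.array([accel.LABEL_NAMES[l] for l in day.labels])
        truth = sched.minutes()
        waking = (truth != "sleep") & (truth != "nonwear")
        assert np.array_equal(names[waking], truth[waking])

    def test_removal_reason_copied_to_log(self):
        sched = _simple_schedule(nonwear=60, reason="sports")
        _, log = generate_raw_day(sched, DeviceParams(sampling_rate_hz=1.0), seed=1)
        assert any(r[2] == "sports" for r in log.removals)
        nw = [s for s in sched.segments if s.behaviour == "nonwear"]
        assert log.removals == [(s.start, s.start + s.duration, s.reason) for s in nw]

    def test_band_overlapping_cutpoint_rejected(self):
        device = DeviceParams(svm_bands={"sleep": (0.0, 0.4), "sed": (1.0, 5.3),
                                         "lpa": (6.0, 13.0), "mvpa": (15.0, 30.0)})
        with pytest.raises(ValueError, match="cut-point"):
            device.validate_against(CutPoints())

    def test_gravity_nonwear_mode_fills_day(self):
        sched = _simple_schedule(nonwear=60)
        device = DeviceParams(sampling_rate_hz=1.0, nonwear_mode="gravity")
        rec, _ = generate_raw_day(sched, device, seed=3)
        assert len(rec.time_s) == 1440 * 60

    def test_day_seed_fits_32bit(self, small_study):
        for sched in small_study.schedules[:10]:
            assert 0 <= raw_day_seed(11, sched) < 2**31


class TestRecallBias:
    def test_zero_bias_identity_on_grid(self):
        sched = _simple_schedule()
        diary = generate_recall_day(sched, zero_bias(), seed=0)
        comp = compile_recall_day(diary)
        truth = sched.composition()
        assert comp.tolist() == [truth["sleep"], truth["sed"],
                                 truth["lpa"], truth["mvpa"]]

    def test_mvpa_shift_moves_exactly_from_lpa(self):
        sched = _simple_schedule()
        bias = dataclasses.replace(zero_bias(), mvpa_shift_min=30.0)
        comp = compile_recall_day(generate_recall_day(sched, bias, seed=0))
        truth = sched.composition()
        assert comp.tolist() == [truth["sleep"], truth["sed"],
                                 truth["lpa"] - 30, truth["mvpa"] + 30]

    def test_awakening_absorbed_into_sleep(self):
        sched = _simple_schedule(awake=20)
        truth = sched.composition()
        on = dataclasses.replace(zero_bias(), absorb_awakenings=True)
        comp = compile_recall_day(generate_recall_day(sched, on, seed=0))
        assert comp[0] == truth["sleep"] + 20
        off = zero_bias()
        comp_off = compile_recall_day(generate_recall_day(sched, off, seed=0))
        assert comp_off[0] == truth["sleep"]

    def test_oversized_shift_clamped_with_warning(self, caplog):
        sched = _simple_schedule()
        bias = dataclasses.replace(zero_bias(), mvpa_shift_min=2000.0)
        with caplog.at_level("WARNING"):
            comp = compile_recall_day(generate_recall_day(sched, bias, seed=0))
        assert "clamped" in caplog.text
        assert comp[2] == 5.0  # LPA floored, not negative
        assert comp.sum() == 1440.0

    def test_block_rounding_keeps_tiling(self):
        rng = np.random.default_rng(5)
        sched = build_day_schedule("P1", DATE, np.array([583, 487, 281, 89]),
                                   rng, grid_min=1)
        diary = generate_recall_day(sched, BiasParams(block_min=15), seed=2)
        comp = compile_recall_day(diary)
        assert comp.sum() == 1440.0
        assert all((e - s) % 5 == 0 for s, e, _, _ in diary.segments)

    def test_block_must_be_multiple_of_five(self):
        with pytest.raises(ValueError, match="multiple of 5"):
            BiasParams(block_min=7)


def test_full_zero_noise_round_trip():
    """Raw → composition and diary → composition both recover the truth."""
    cfg = CohortConfig(
        n_participants=3, days_per_participant=2, seed=13,
        bias=zero_bias(), nonwear_mean_min=0, nonwear_sd_min=0,
        device=DeviceParams(sampling_rate_hz=1.0), schedule_grid_min=5,
        academic_missing_prob=0.0)
    study = generate_study(cfg)
    for sched, diary in zip(study.schedules, study.diaries):
        truth = sched.composition()
        parts = np.array([truth[b] for b in ("sleep", "sed", "lpa", "mvpa")])
        rec, log = generate_raw_day(sched, cfg.device,
                                    raw_day_seed(cfg.seed, sched), cfg.cuts)
        device_comp = accel.process_recording(rec, log, cfg.cuts)
        assert np.abs(device_comp.parts() - parts).max() <= 1.0
        assert np.abs(compile_recall_day(diary) - parts).max() <= 1.0
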