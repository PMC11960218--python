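"""Signal processing: SVM, epochs, labelling, sport replacement, validity."""

import datetime as dt

import numpy as np
import pytest

from timeuse import accel
from timeuse.accel import (
    CutPoints,
    DayComposition,
    EpochSeries,
    TriaxialRecording,
    WearLog,
    aggregate_epochs,
    compute_svm,
    day_is_valid,
    label_day,
    normalize_to_1440,
    participant_is_valid,
    replace_sport_nonwear,
)

DATE = dt.date(2019, 3, 11)  # a Monday
SAT = dt.date(2019, 3, 16)


def _recording(acc, rate=50.0):
    acc = np.asarray(acc, dtype=float)
    t = (np.arange(len(acc)) + 0.5) / rate
    return TriaxialRecording("P1", DATE, rate, t, acc)


class TestComputeSvm:
    @pytest.mark.parametrize("sample,expected", [
        ((0, 0, 1), 0.0),        # device at rest: pure gravity
        ((0.6, 0.8, 0), 0.0),    # any unit-norm orientation
        ((3, 4, 0), 4.0),        # 3-4-5 triple: norm 5 minus 1 g
        ((0, 0, 0.5), 0.5),      # below-gravity norm, absolute value
    ])
    def test_examples(self, sample, expected):
        svm = compute_svm(_recording([sample]))
        assert svm[0] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_axis_permutation_and_sign(self, rng):
        acc = rng.normal(0, 0.6, (200, 3))
        base = compute_svm(_recording(acc))
        for perm in ([1, 2, 0], [2, 0, 1]):
            assert np.allclose(compute_svm(_recording(acc[:, perm])), base)
        assert np.allclose(compute_svm(_recording(-acc)), base)
        assert np.all(base >= 0)

    def test_non_finite_sample_names_time(self):
        acc = np.array([[0, 0, 1.0], [0, np.nan, 1.0]])
        with pytest.raises(ValueError, match="t=0.03"):
            compute_svm(_recording(acc))


class TestAggregateEpochs:
    def test_constant_signal(self):
        # constant per-sample SVM of 0.1 g -> 6.0 g·min whatever the rate
        for rate in (50.0, 10.0):
            n = int(rate * 120)
            acc = np.zeros((n, 3))
            acc[:, 2] = 1.1
            rec = _recording(acc, rate)
            epochs = aggregate_epochs(compute_svm(rec), rec)
            assert epochs.values[0] == pytest.approx(6.0)
            assert epochs.values[1] == pytest.approx(6.0)

    def test_all_zero_signal(self):
        acc = np.tile([0.0, 0.0, 1.0], (3000, 1))
        rec = _recording(acc)
        assert np.nansum(aggregate_epochs(compute_svm(rec), rec).values) == 0.0

    def test_matches_brute_force(self, rng):
        rate = 7.0
        n = int(rate * 60 * 5)
        acc = rng.normal(0, 0.5, (n, 3))
        rec = _recording(acc, rate)
        svm = compute_svm(rec)
        epochs = aggregate_epochs(svm, rec)
        minute = np.floor(rec.time_s / 60).astype(int)
        for m in range(5):
            sel = svm[minute == m]
            assert epochs.values[m] == pytest.approx(sel.mean() * 60.0, rel=1e-12)

    def test_uncovered_minutes_are_nan(self):
        acc = np.tile([0.0, 0.0, 1.2], (50 * 60, 1))
        t = 7200.0 + (np.arange(len(acc)) + 0.5) / 50.0  # only minute 120
        rec = TriaxialRecording("P1", DATE, 50.0, t, acc)
        values = aggregate_epochs(compute_svm(rec), rec).values
        assert np.isfinite(values[120])
        assert np.isnan(values[119]) and np.isnan(values[121])


def _flat_epochs(value, date=DATE):
    return EpochSeries(date=date, values=np.full(1440, float(value)))


class TestLabelDay:
    def test_threshold_boundaries(self):
        cuts = CutPoints(5.25, 14.25)
        log = WearLog("P1", DATE, bed_time=1440, getup_time=0)
        for value, expected in [(14.25, accel.MVPA), (14.2499, accel.LPA),
                                (5.25, accel.LPA), (5.2499, accel.SED)]:
            day = label_day(_flat_epochs(value), log, cuts)
            assert np.all(day.labels == expected), value

    def test_whole_day_sleep_window(self):
        log = WearLog("P1", DATE, bed_time=0, getup_time=1440)
        day = label_day(_flat_epochs(10.0), log, CutPoints())
        assert np.all(day.labels == accel.SLEEP)

    def test_sleep_wins_over_removal_inside_window(self):
        log = WearLog("P1", DATE, bed_time=1320, getup_time=420,
                      removals=[(1330, 1400, None), (600, 660, "bath")])
        day = label_day(_flat_epochs(1.0), log, CutPoints())
        assert np.all(day.labels[1330:1400] == accel.SLEEP)
        assert np.all(day.labels[600:660] == accel.NONWEAR)

    def test_missing_minutes_outside_log_become_nonwear(self):
        values = np.full(1440, 1.0)
        values[700:750] = np.nan
        log = WearLog("P1", DATE, bed_time=1320, getup_time=420)
        day = label_day(EpochSeries(DATE, values), log, CutPoints())
        assert np.all(day.labels[700:750] == accel.NONWEAR)
        with pytest.raises(ValueError, match="no logged removal"):
            label_day(EpochSeries(DATE, values), log, CutPoints(),
                      strict_nonwear=True)

    def test_weekend_flag_follows_date(self):
        log = WearLog("P1", SAT, bed_time=1320, getup_time=420)
        day = label_day(_flat_epochs(1.0, SAT), log, CutPoints())
        assert day.weekend


class TestSportReplacement:
    def _day_with_removal(self, start, dur, reason):
        labels = np.full(1440, accel.SED, dtype=np.int8)
        labels[:420] = accel.SLEEP
        labels[1320:] = accel.SLEEP
        labels[start:start + dur] = accel.NONWEAR
        day = accel.LabelledDay(DATE, labels, weekend=False)
        log = WearLog("P1", DATE, bed_time=1320, getup_time=420,
                      removals=[(start, start + dur, reason)] if dur else [])
        return day, log

    @pytest.mark.parametrize("dur,add", [(60, (24.0, 24.0, 12.0)),
                                         (25, (10.0, 10.0, 5.0)),
                                         (0, (0.0, 0.0, 0.0))])
    def test_sport_mix(self, dur, add):
        day, log = self._day_with_removal(600, dur, "sports")
        comp = replace_sport_nonwear(day, log)
        assert comp.mvpa_min == add[0]
        assert comp.lpa_min == add[1]
        assert comp.sed_min == 900 - dur + add[2]
        assert comp.nonwear_min == 0.0
        assert comp.total() == pytest.approx(1440.0)

    def test_other_reasons_left_as_nonwear(self):
        day, log = self._day_with_removal(600, 45, "bath")
        comp = replace_sport_nonwear(day, log)
        assert comp.nonwear_min == 45.0
        assert comp.total() == pytest.approx(1440.0)


def _comp(sleep, sed, lpa, mvpa, nonwear=0.0, weekend=False):
    return DayComposition("P1", SAT if weekend else DATE, weekend,
                          sleep, sed, lpa, mvpa, nonwear)


class TestValidity:
    @pytest.mark.parametrize("nonwear,waking,expected", [
        (360, 600, True),    # both boundaries inclusive
        (361, 600, False),
        (360, 599, False),
        (0, 1000, True),
    ])
    def test_day_rule(self, nonwear, waking, expected):
        comp = _comp(1440 - nonwear - waking, waking, 0, 0, nonwear)
        assert day_is_valid(comp) is expected

    def test_day_rule_monotone_in_nonwear(self):
        # converting wear to non-wear can never rescue an invalid day
        for nw in range(0, 841, 60):
            comp = _comp(500, 940 - nw, 0, 0, nw)
            if not day_is_valid(comp):
                worse = _comp(500, 940 - nw - 60, 0, 0, nw + 60)
                assert not day_is_valid(worse)

    def test_participant_rule(self):
        valid_weekday = _comp(600, 500, 250, 90)
        valid_weekend = _comp(600, 500, 250, 90, weekend=True)
        assert not participant_is_valid([valid_weekday] * 4)
        assert participant_is_valid([valid_weekday] * 3 + [valid_weekend])
        assert not participant_is_valid([])
        invalid = _comp(500, 400, 100, 40, 400)
        invalid.valid = False
        assert not participant_is_valid([valid_weekday] * 3 + [invalid])


class TestNormalize:
    def test_identity_when_closed(self):
        out = normalize_to_1440(np.array([600.0, 500.0, 250.0, 90.0]))
        assert np.allclose(out, [600, 500, 250, 90])

    def test_nonwear_day_scales_linearly(self):
        out = normalize_to_1440(np.array([580.0, 480.0, 270.0, 86.0]))
        assert np.round(out, 2).tolist() == [589.83, 488.14, 274.58, 87.46]
        assert out.sum() == pytest.approx(1440.0, abs=1e-9)

    def test_closure_property(self, rng):
        for _ in range(25):
            parts = rng.uniform(10, 700, 4)
            assert normalize_to_1440(parts).sum() == pytest.approx(1440.0, abs=1e-9)

    def test_zero_wear_rejected(self):
        with pytest.raises(ValueError, match="zero total wear"):
            normalize_to_1440(np.zeros(4))


def test_label_counts_conserve_minutes(rng):
    values = np.abs(rng.normal(4, 4, 1440))
    log = WearLog("P1", DATE, bed_time=1330, getup_time=410,
                  removals=[(500, 560, "sports"), (900, 930, None)])
    day = label_day(EpochSeries(DATE, values), log, CutPoints())
    assert np.bincount(day.labels, minlength=5).sum() == 1440
    comp = replace_sport_nonwear(day, log)
    assert comp.total() == pytest.approx(1440.0)
    assert comp.nonwear_min == 30.0  # only the unexplained removal remains
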