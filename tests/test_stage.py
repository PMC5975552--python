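"""Activity metric, threshold staging and time-in-phase summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wss.features import window_stage_truth
from wss.simulate import (
    NoiseModel,
    ProtocolSpec,
    SensorStream,
    LabeledRecording,
    generate_sleep_protocol,
)
from wss.stage import (
    StageThresholds,
    activity_series,
    derive_thresholds,
    stage_accuracy,
    stage_from_activity,
    time_in_phase,
)


def _constant_recording(n=200, rate=50.0):
    """Three sensors at rest with gravity on the z axis."""
    t = np.arange(n) / rate
    streams = {}
    for loc in ("trunk", "left_forearm", "right_forearm"):
        accel = np.tile([0.0, 0.0, 1.0], (n, 1))
        streams[loc] = SensorStream(loc, rate, t, accel, np.zeros((n, 3)), np.zeros((n, 3)))
    return LabeledRecording(streams=streams, rate=rate, posture_truth=np.ones(n, dtype=int))


def test_constant_streams_have_zero_activity():
    act = activity_series(_constant_recording())
    assert len(act) == 5
    assert np.allclose(act.values, 0.0)


def test_single_noisy_axis_closed_form():
    """One axis alternating +/-0.1 g about a 1 g rest signal: exactly one of
    nine axis CoVs is 0.1/(1 + eps), so the combined value is that ninth."""
    rec = _constant_recording(n=100)
    trunk = rec.streams["trunk"].accel
    trunk[:, 0] = np.where(np.arange(100) % 2 == 0, 0.1, -0.1)
    act = activity_series(rec, window=2.0, step=0.5, eps=0.01)
    expected = 0.1 / (np.sqrt(1.0 + 0.0) + 0.01) / 9  # mean vector is (0,0,1)
    assert np.allclose(act.values, expected, atol=1e-12)
    assert expected == pytest.approx(0.0110, abs=1e-4)


def test_activity_sum_combination_is_nine_times_mean():
    rec = generate_sleep_protocol(ProtocolSpec(), NoiseModel(seed=3), rate=50.0)
    mean = activity_series(rec, combine="mean")
    total = activity_series(rec, combine="sum")
    assert np.allclose(total.values, 9 * mean.values)


def test_activity_rejects_short_windows():
    with pytest.raises(ValueError, match="2 samples"):
        activity_series(_constant_recording(), window=0.01)


@pytest.mark.parametrize(
    "value,expected",
    [
        (0.20, 3),  # awake branch
        (0.10, 2),  # sleep branch
        (0.03, 1),  # REM branch
        (0.14, 2),  # exactly at high -> lower stage
        (0.1400001, 3),
        (0.058, 1),  # exactly at low -> lower stage
        (0.0580001, 2),
        (0.0, 1),
    ],
)
def test_nested_threshold_rule(value, expected):
    assert stage_from_activity(value) == expected


def test_stage_rule_rejects_negative_activity():
    with pytest.raises(ValueError, match="non-negative"):
        stage_from_activity(-0.1)


@given(st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=50))
def test_stage_rule_is_monotone_step_function(values):
    v = np.sort(np.array(values))
    stages = stage_from_activity(v)
    assert set(np.unique(stages)) <= {1, 2, 3}
    assert (np.diff(stages) >= 0).all()


def test_threshold_validation():
    with pytest.raises(ValueError, match="low < high"):
        StageThresholds(high=0.05, low=0.06)


def test_derived_thresholds_are_midpoints():
    values = np.concatenate([np.full(10, 0.02), np.full(10, 0.09), np.full(10, 0.20)])
    truth = np.repeat([1, 2, 3], 10)
    thr = derive_thresholds(values, truth)
    assert thr.low == pytest.approx(0.055)
    assert thr.high == pytest.approx(0.145)


def test_derived_thresholds_recover_printed_values():
    """Stage levels placed symmetrically around the published thresholds
    (0.016/0.100 and 0.100/0.180) derive back to low=0.058, high=0.140."""
    values = np.concatenate([np.full(5, 0.016), np.full(5, 0.100), np.full(5, 0.180)])
    truth = np.repeat([1, 2, 3], 5)
    thr = derive_thresholds(values, truth)
    assert thr.low == pytest.approx(0.058)
    assert thr.high == pytest.approx(0.140)


def test_derive_thresholds_rejects_wrong_ordering():
    values = np.concatenate([np.full(5, 0.2), np.full(5, 0.1), np.full(5, 0.3)])
    truth = np.repeat([1, 2, 3], 5)
    with pytest.raises(ValueError, match="not separable"):
        derive_thresholds(values, truth)
    with pytest.raises(ValueError, match="no windows labelled stage 3"):
        derive_thresholds(values[:10], truth[:10])


def test_threshold_midpoint_recovery_on_synthetic_protocol():
    """On a default protocol, derived thresholds land within Monte-Carlo error
    of the midpoints of the per-stage activity levels implied by the tremor
    SDs (0.015, 0.07, 0.16 g)."""
    rec = generate_sleep_protocol(ProtocolSpec(), NoiseModel(seed=23), rate=50.0)
    act = activity_series(rec)
    truth = window_stage_truth(rec)
    thr = derive_thresholds(act.values, truth)
    assert thr.low == pytest.approx((0.015 + 0.07) / 2 / 1.01, abs=0.004)
    assert thr.high == pytest.approx((0.07 + 0.16) / 2 / 1.01, abs=0.006)


def test_stage_mean_activity_ordering_follows_tremor():
    rec = generate_sleep_protocol(ProtocolSpec(), NoiseModel(seed=31), rate=50.0)
    act = activity_series(rec)
    truth = window_stage_truth(rec)
    means = [act.values[truth == c].mean() for c in (1, 2, 3)]
    assert means[0] < means[1] < means[2]


def test_time_in_phase_all_awake():
    summary = time_in_phase(np.full(40, 3))
    assert summary.percent_awake == 100.0
    assert summary.percent_sleep == summary.percent_rem == 0.0


def test_time_in_phase_on_protocol_truth_matches_design():
    rec = generate_sleep_protocol(ProtocolSpec(), NoiseModel(seed=1), rate=50.0)
    summary = time_in_phase(rec.stage_truth)
    assert round(summary.percent_awake, 1) == 28.6
    assert round(summary.percent_sleep, 1) == 42.9
    assert round(summary.percent_rem, 1) == 28.6


@given(st.lists(st.integers(1, 3), min_size=1, max_size=300))
def test_phase_percentages_sum_to_100(stages):
    summary = time_in_phase(np.array(stages))
    assert sum(summary.percent.values()) == pytest.approx(100.0, abs=0.1)
    assert sum(summary.counts.values()) == summary.total


def test_stage_accuracy_arithmetic():
    truth = np.full(40, 2)
    pred = truth.copy()
    assert stage_accuracy(pred, truth) == 100.0
    pred[0] = 3
    assert stage_accuracy(pred, truth) == pytest.approx(97.5)
    with pytest.raises(ValueError, match="align"):
        stage_accuracy(pred[:-1], truth)
    with pytest.raises(ValueError, match="empty"):
        time_in_phase(np.array([], dtype=int))


def test_reduced_separation_degrades_agreement():
    """Shrinking the tremor separation between stages lowers the per-window
    agreement obtained with derived thresholds."""

    def agreement(tremor):
        noise = NoiseModel(seed=41, stage_tremor_sd=tremor)
        rec = generate_sleep_protocol(ProtocolSpec(), noise, rate=50.0)
        act = activity_series(rec)
        truth = window_stage_truth(rec)
        thr = derive_thresholds(act.values, truth)
        return stage_accuracy(stage_from_activity(act.values, thr), truth)

    wide = agreement({"rem": 0.015, "sleep": 0.07, "awake": 0.16})
    narrow = agreement({"rem": 0.055, "sleep": 0.07, "awake": 0.09})
    assert narrow < wide
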