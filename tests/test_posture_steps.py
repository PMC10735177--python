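import numpy as np
import pytest

from mobilitykit.accel import (AccelStream, PostureParams, classify_posture,
                               count_steps, trim_task_window)
from mobilitykit.study import posture_accuracy
from mobilitykit.synth import ScenarioConfig, ScheduleEntry, generate_accel_stream


def _static_stream(axis, minutes=10, rate=30.0, noise=0.05, placement="thigh",
                   seed=0):
    r = np.random.default_rng(seed)
    n = int(minutes * 60 * rate)
    data = r.normal(0, noise, (n, 3))
    data[:, axis] += 1.0
    return AccelStream(rate, data, placement)


def test_standing_signal_classified_standing():
    labels = classify_posture(_static_stream(axis=0))
    assert np.mean(labels == "standing") >= 0.95


def test_lying_signal_classified_sitting_lying():
    labels = classify_posture(_static_stream(axis=2))
    assert np.mean(labels == "sitting_lying") >= 0.95


def test_wrist_placement_refused():
    with pytest.raises(ValueError, match="thigh"):
        classify_posture(_static_stream(axis=0, placement="wrist"))


def test_task_trimming_five_minutes_leaves_three_and_a_half():
    t0, t1 = trim_task_window(0.0, 300.0)
    assert t1 - t0 == pytest.approx(3.5 * 60.0)
    with pytest.raises(ValueError):
        trim_task_window(0.0, 80.0)


def test_posture_accuracy_counting():
    pred = np.array(["standing"] * 9 + ["sitting_lying"])
    truth = np.array(["standing"] * 10)
    acc = posture_accuracy(pred, truth)
    assert acc["standing"] == pytest.approx(90.0)
    assert acc["overall"] == pytest.approx(90.0)


# --------------------------------------------------------------------- steps
def _walk_stream(steps=80, cadence=2.0, rate=25.0, noise=0.0, amp=0.35, seed=0,
                 pad_s=5.0):
    r = np.random.default_rng(seed)
    dur = steps / cadence
    n_pad = int(pad_s * rate)
    t = np.arange(int(dur * rate)) / rate
    osc = amp * (np.sin(2 * np.pi * cadence * t)
                 + 0.25 * np.sin(4 * np.pi * cadence * t))
    sig = np.concatenate([np.zeros(n_pad), osc, np.zeros(n_pad)])
    data = np.zeros((len(sig), 3))
    data[:, 2] = 1.0 + sig
    if noise:
        data += r.normal(0, noise, data.shape)
    return AccelStream(rate, data, "wrist")


def test_static_signal_zero_steps():
    s = AccelStream(25.0, np.tile([0.0, 0.0, 1.0], (25 * 60, 1)), "wrist")
    assert count_steps(s) == 0


@pytest.mark.parametrize("noise", [0.0, 0.05])
def test_eighty_step_walk_recovered(noise):
    s = _walk_stream(steps=80, noise=noise)
    assert abs(count_steps(s) - 80) <= 2


def test_amplitude_doubling_leaves_count_unchanged():
    s1 = _walk_stream(steps=60, amp=0.35)
    s2 = _walk_stream(steps=60, amp=0.70)
    assert count_steps(s1) == count_steps(s2)


def test_empty_window_counts_zero():
    s = _walk_stream()
    assert count_steps(s, 1e9, 1e9 + 10) == 0


def test_generated_walk_task_peaks_match_planted_steps():
    """End to end through the generator: a planted 100-step walk at 2 Hz
    lasts 50 s and yields 100 detectable peaks."""
    cfg = ScenarioConfig(seed=3)
    day = 0
    tw0 = cfg.wear_start_h * 3600.0
    schedule = [ScheduleEntry(tw0, tw0 + 600.0, "sit"),
                ScheduleEntry(tw0 + 600.0, tw0 + 650.0, "walk", 2.0, 100),
                ScheduleEntry(tw0 + 650.0, tw0 + 1250.0, "sit")]
    stream, truth = generate_accel_stream(cfg, 0, day, "ticwatch_s2", "wrist",
                                          schedule)
    (t0, t1, steps, cad) = truth.walk_tasks[0]
    assert t1 - t0 == pytest.approx(50.0)
    assert steps == 100
    assert abs(count_steps(stream, t0, t1) - 100) <= 2
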