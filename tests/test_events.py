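"""Start/stop modulation index and speed-coding score."""
import numpy as np
import pytest

from spikegait import events as ev
from spikegait import synth
from spikegait.bouts import MotionBout, detect_motion_bouts
from spikegait.events import modulation_index, speed_coding, start_stop_test
from spikegait.kinematics import body_speed
from spikegait.types import SpikeTrain

FR = 80.0


def _train(times, end=200.0):
    return SpikeTrain("u", np.asarray(times, dtype=float), session_end=end)


def _regular(rate, start, stop):
    return np.arange(start, stop, 1.0 / rate)


# ------------------------------------------------------------------ MI formula
def test_modulation_index_flat_rate_is_zero():
    # one spike in every 20 ms bin everywhere (placed at bin centers):
    # normalized PETH is exactly 1
    spikes = _train(_regular(50.0, 0.01, 100.0))
    bouts = [MotionBout(20.0, 30.0, 100.0), MotionBout(50.0, 60.0, 100.0)]
    assert modulation_index(spikes, bouts, "start") == pytest.approx(0.0, abs=1e-9)


def test_modulation_index_peak_three_gives_two():
    # flat 50 Hz baseline; two extra spikes in one event bin -> 150 Hz = 3x
    times = list(_regular(50.0, 0.01, 100.0))
    for e in (20.0, 50.0):
        times += [e + 0.101, e + 0.112]  # land in the same 20 ms bin as one base spike
    spikes = _train(sorted(times))
    bouts = [MotionBout(20.0, 30.0, 100.0), MotionBout(50.0, 60.0, 100.0)]
    assert modulation_index(spikes, bouts, "start") == pytest.approx(2.0, abs=0.01)


def test_modulation_index_uniform_suppression():
    # event window firing at half the baseline rate in every bin -> index 0.5
    times = []
    for a, b in [(0.0, 19.5), (20.5, 49.5), (50.5, 100.0)]:
        times += list(_regular(50.0, a, b))
    # 25 Hz trains interleaved across the two events so the event-aligned
    # average is 25 Hz (= half baseline) in every 20 ms bin
    times += list(_regular(25.0, 20.0 - 0.5 + 0.005, 20.0 + 0.5))
    times += list(_regular(25.0, 50.0 - 0.5 + 0.025, 50.0 + 0.5))
    spikes = _train(sorted(times))
    bouts = [MotionBout(20.0, 30.0, 100.0), MotionBout(50.0, 60.0, 100.0)]
    mi = modulation_index(spikes, bouts, "start")
    assert mi == pytest.approx(0.5, abs=0.02)


def test_modulation_index_rescaling_invariance():
    """Uniformly rescaling the firing rate leaves the index unchanged."""
    rng = np.random.default_rng(2)
    bouts = [MotionBout(20.0 + 40 * i, 40.0 + 40 * i, 100.0) for i in range(4)]
    base = np.sort(rng.uniform(0, 200.0, 2000))
    mi1 = modulation_index(_train(base), bouts, "start")
    # triple the rate by overlaying three shifted copies
    tripled = np.sort(np.concatenate([base, base + 1e-4, base + 2e-4]))
    mi3 = modulation_index(_train(tripled), bouts, "start")
    assert mi3 == pytest.approx(mi1, abs=0.15)


def test_modulation_index_zero_baseline_undefined():
    spikes = _train(_regular(50.0, 30.0, 31.0))
    bouts = [MotionBout(20.0, 25.0, 100.0), MotionBout(50.0, 55.0, 100.0)]
    assert np.isnan(modulation_index(spikes, bouts, "start"))


# ------------------------------------------------------------ start/stop test
def test_identical_windows_not_significant():
    spikes = _train(_regular(20.0, 0.0, 200.0))
    bouts = [MotionBout(20.0 + 30 * i, 35.0 + 30 * i, 100.0) for i in range(5)]
    res = start_stop_test(spikes, bouts, "start")
    assert res.p_value > 0.9 and not res.significant


def test_start_transient_detected_stop_only_constructed():
    sched = [(20.0 + 40 * i, 40.0 + 40 * i, 150.0) for i in range(6)]
    track = synth.generate_pose_track(
        synth.GaitGenParams(bout_schedule=sched, session_duration=280.0, seed=3)
    )
    bouts = detect_motion_bouts(body_speed(track), FR)
    start_unit = synth.generate_phase_locked_spikes(
        track, None, synth.SpikeGenParams(base_rate=5.0, start_transient_amp=3.0, seed=4)
    )
    res = start_stop_test(start_unit, bouts, "start")
    assert res.significant and res.event_rate > res.baseline_rate
    stop_unit = synth.generate_phase_locked_spikes(
        track, None, synth.SpikeGenParams(base_rate=5.0, stop_transient_amp=3.0, seed=5)
    )
    assert not start_stop_test(stop_unit, bouts, "start").significant
    assert start_stop_test(stop_unit, bouts, "stop").significant


def test_too_few_events_flagged():
    spikes = _train(_regular(20.0, 0.0, 200.0))
    res = start_stop_test(spikes, [MotionBout(20.0, 25.0, 100.0)], "start")
    assert res.n_events < 2 and not res.significant and np.isnan(res.p_value)


# ------------------------------------------------------------- speed coding
def _linear_rate_spikes_and_speed():
    """Speed spends 2 s at each bin center; spike rate = 2 + 0.5*speed."""
    frames_per_level = 160  # 2 s
    levels = np.array([5.0, 15.0, 25.0, 35.0, 45.0, 55.0])
    speed = np.repeat(levels, frames_per_level)
    times = []
    for i, v in enumerate(levels):
        t0, t1 = i * 2.0, (i + 1) * 2.0
        times += list(np.arange(t0, t1, 1.0 / (2.0 + 0.5 * v)))
    return _train(sorted(times), end=len(speed) / FR), speed


def test_exact_linear_tuning_scores_one():
    spikes, speed = _linear_rate_spikes_and_speed()
    res = speed_coding(spikes, speed, FR, seed=0)
    assert res.score == pytest.approx(1.0, abs=0.01)
    assert res.significant


def test_decreasing_tuning_scores_like_increasing():
    spikes, speed = _linear_rate_spikes_and_speed()
    up = speed_coding(spikes, speed, FR, seed=0)
    down = speed_coding(spikes, speed[::-1].copy(), FR, seed=0)
    assert down.score == pytest.approx(up.score, abs=0.02)


def test_low_occupancy_bins_excluded():
    spikes, speed = _linear_rate_spikes_and_speed()
    # a lone frame at very high speed must not enter the correlation
    speed2 = speed.copy()
    speed2[0] = 500.0
    res = speed_coding(spikes, speed2, FR, seed=0)
    assert res.score == pytest.approx(1.0, abs=0.02)


def test_few_occupied_bins_undefined():
    spikes = _train(_regular(5.0, 0.0, 10.0), end=10.0)
    res = speed_coding(spikes, np.full(800, 5.0), FR, seed=0)
    assert np.isnan(res.score) and not res.significant


def test_coding_categories_consistency():
    assert ev.coding_categories(True, False, True, False) == {"phase", "startstop"}
    assert ev.coding_categories(False, False, False, False) == set()
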