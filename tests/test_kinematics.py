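"""Stride segmentation, projection geometry, filtering, and gait metrics."""
import numpy as np
import pytest

from spikegait import kinematics as kin
from spikegait import synth
from spikegait.types import KEYPOINTS, LIMBS, PoseTrack, WalkingBout


def _make_track(coords, fr=80.0):
    n = len(next(iter(coords.values())))
    return PoseTrack(np.arange(n) / fr, coords, frame_rate=fr)


def _rigid_transform(track, angle_deg, shift):
    th = np.deg2rad(angle_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    coords = {k: track.coords[k] @ R.T + np.asarray(shift) for k in KEYPOINTS}
    return PoseTrack(track.frame_times, coords, track.frame_rate, track.pixel_scale)


# ---------------------------------------------------------------- smoothing
def test_savgol_reproduces_cubic_and_constant():
    t = np.linspace(0, 1, 200)
    cubic = 3 * t**3 - 2 * t**2 + t - 5
    coords = {k: np.column_stack([cubic, np.full_like(t, 7.0)]) for k in KEYPOINTS}
    track = _make_track(coords)
    out = kin.smooth_track(track, window_frames=11)
    for k in KEYPOINTS:
        np.testing.assert_allclose(out.coords[k][:, 0], cubic, atol=1e-8)
        np.testing.assert_allclose(out.coords[k][:, 1], 7.0, atol=1e-10)


def test_savgol_reduces_noise_on_sinusoid():
    rng = np.random.default_rng(0)
    t = np.arange(800) / 80.0
    clean = 10 * np.sin(2 * np.pi * 2.5 * t)
    noisy = clean + rng.normal(0, 1.0, t.size)
    coords = {k: np.column_stack([noisy, noisy]) for k in KEYPOINTS}
    out = kin.smooth_track(_make_track(coords), window_frames=7)
    resid = out.coords["LF"][:, 0] - clean
    assert np.std(resid) < np.std(noisy - clean)


def test_savgol_window_validation():
    track = _make_track({k: np.zeros((20, 2)) for k in KEYPOINTS})
    with pytest.raises(ValueError):
        kin.smooth_track(track, window_frames=6)
    with pytest.raises(ValueError):
        kin.smooth_track(track, window_frames=21)


# --------------------------------------------------------------- projection
def test_projection_geometry_and_rotation_invariance():
    n = 10
    coords = {k: np.zeros((n, 2)) for k in KEYPOINTS}
    coords["nose"] = np.tile([50.0, 0.0], (n, 1))
    coords["tail"] = np.zeros((n, 2))
    coords["LF"] = np.tile([50.0, 0.0], (n, 1))  # at the nose
    coords["LR"] = np.zeros((n, 2))  # at the tail
    coords["RF"] = np.tile([25.0, 12.0], (n, 1))
    track = _make_track(coords)
    p = kin.project_limb(track, "LF")
    np.testing.assert_allclose(p, 50.0)
    np.testing.assert_allclose(kin.project_limb(track, "LR"), 0.0)
    rotated = _rigid_transform(track, 90.0, (30.0, -12.0))
    for limb in ("LF", "LR", "RF"):
        np.testing.assert_allclose(
            kin.project_limb(rotated, limb), kin.project_limb(track, limb), atol=1e-9
        )


# ----------------------------------------------------------------- bandpass
@pytest.mark.parametrize(
    "freq,expect",
    [(0.0, "dc"), (2.5, "pass"), (20.0, "stop")],
)
def test_bandpass_gain(freq, expect):
    fr = 80.0
    t = np.arange(4000) / fr
    x = np.ones_like(t) * 5.0 if freq == 0 else np.sin(2 * np.pi * freq * t)
    y = kin.bandpass_gait(x, fr)
    core = slice(500, -500)  # ignore filter edges
    amp = np.max(np.abs(y[core]))
    if expect == "dc":
        assert amp < 1e-6
    elif expect == "pass":
        assert amp == pytest.approx(1.0, rel=0.05)
    else:
        assert amp < 0.10


# ------------------------------------------------------------------ strides
def test_noiseless_stride_segmentation_exact(noiseless_track, single_bout):
    strides = kin.detect_strides(noiseless_track, single_bout)
    lf = strides[strides["limb"] == "LF"]
    assert len(lf) == 24
    fr = noiseless_track.frame_rate
    assert np.all(np.abs(lf["duration"] - 0.4) <= 1.0 / fr + 1e-9)
    # partition: stance + swing = stride duration exactly
    stance = strides["swing_onset"] - strides["stance_onset"]
    swing = strides["next_stance_onset"] - strides["swing_onset"]
    np.testing.assert_allclose(stance + swing, strides["duration"], atol=1e-12)
    # stride length = body displacement per cycle = 150 mm/s / 2.5 Hz
    np.testing.assert_allclose(strides["length"], 60.0, rtol=0.05)


def test_short_bout_yields_no_strides(noiseless_track):
    strides = kin.detect_strides(
        noiseless_track, [WalkingBout(5.0, 5.3, bout_id=0)]
    )
    assert len(strides) == 0


def test_consecutive_same_type_extrema_keep_deeper():
    # two troughs whose intervening bump is below the prominence criterion:
    # the cleaner must keep only the deeper trough
    x = np.zeros(100)
    x[20] = -5.0
    x[21:60] = -4.95
    x[40] = -4.9  # sub-prominence bump, rejected by find_peaks
    x[60] = -8.0
    x[80] = 6.0
    cfg = kin.KinematicsConfig(prominence_frac=0.2)
    troughs, peaks = kin._alternating_extrema(x, 80.0, cfg)
    assert list(troughs) == [60]  # the deeper trough survives
    assert 80 in list(peaks)


def test_stride_detection_rigid_invariance(noiseless_track, single_bout):
    a = kin.detect_strides(noiseless_track, single_bout)
    b = kin.detect_strides(
        _rigid_transform(noiseless_track, 137.0, (500.0, -250.0)), single_bout
    )
    np.testing.assert_allclose(
        a[["stance_onset", "duration", "length"]].to_numpy(),
        b[["stance_onset", "duration", "length"]].to_numpy(),
        atol=1e-6,
    )


# -------------------------------------------------------------------- phase
def test_phase_linear_zero_at_stance(noiseless_track, single_bout):
    strides = kin.detect_strides(noiseless_track, single_bout)
    phase = kin.assign_phase(strides, noiseless_track)
    fr = noiseless_track.frame_rate
    row = strides[strides["limb"] == "LF"].iloc[3]
    i0 = int(round(row.stance_onset * fr))
    i1 = int(round(row.next_stance_onset * fr))
    assert phase["LF"][i0] == 0.0
    mid = (i0 + i1) // 2
    assert phase["LF"][mid] == pytest.approx(360.0 * (mid - i0) / (i1 - i0))
    diffs = np.diff(phase["LF"][i0:i1])
    assert np.allclose(diffs, diffs[0])
    assert phase["LF"][i1 - 1] < 360.0


# -------------------------------------------------------------------- speed
def test_body_speed_uniform_translation():
    n = 400
    t = np.arange(n) / 80.0
    base = np.column_stack([100.0 * t, np.zeros(n)])
    coords = {k: base + i * 10.0 for i, k in enumerate(KEYPOINTS)}
    speed = kin.body_speed(_make_track(coords))
    np.testing.assert_allclose(speed, 100.0, atol=1.0)


def test_body_speed_stationary(noiseless_track):
    speed = kin.body_speed(noiseless_track)
    rest = np.concatenate([speed[: 4 * 80], speed[16 * 80 :]])
    assert np.max(rest) < 1.0


# -------------------------------------------------------------------- bouts
def test_walking_bout_accepted_and_override(noiseless_track):
    bouts = kin.find_walking_bouts(noiseless_track)
    assert len(bouts) == 1 and bouts[0].accepted
    assert bouts[0].rhythmicity_score > 0.5
    cfg = kin.KinematicsConfig(overrides={0: False})
    assert not kin.find_walking_bouts(noiseless_track, cfg)[0].accepted


def test_fast_but_arrhythmic_bout_rejected():
    """High body speed with broadband random limb jitter is not walking."""
    rng = np.random.default_rng(5)
    n = 800
    t = np.arange(n) / 80.0
    base = np.column_stack([150.0 * t, np.zeros(n)])
    coords = {k: base + rng.normal(0, 8.0, (n, 2)) for k in KEYPOINTS}
    coords["nose"] = base + [35.0, 0.0]
    coords["tail"] = base + [-35.0, 0.0]
    bouts = kin.find_walking_bouts(_make_track(coords))
    assert all(not b.accepted for b in bouts)


# ---------------------------------------------------------- relative phase
def test_relative_phase_recovers_lateral_sequence(walking_strides):
    rel = kin.relative_limb_phase(walking_strides, reference="LR")
    assert rel[("LR", "LR")] == pytest.approx(0.0, abs=1e-6)
    # diagonal partner near 0, same-side front-rear near 180
    d_diag = abs((rel[("RF", "LR")] + 180) % 360 - 180)
    assert d_diag <= 15.0
    d_fr = abs((rel[("LF", "LR")] - 180 + 180) % 360 - 180)
    assert d_fr <= 15.0


def test_swing_time_offsets_order(walking_strides):
    off = kin.swing_time_offsets(walking_strides, reference="LR")
    assert off["LR"] == pytest.approx(0.0, abs=1e-9)
    for limb in LIMBS:
        assert np.isfinite(off[limb])


# ------------------------------------------------------------------ summary
def test_gait_summary_recovers_generator(walking_strides, walking_track):
    summary = kin.gait_summary(walking_strides, walking_track)
    for limb in LIMBS:
        m = summary["per_limb"][limb]
        assert m["length_mean"] == pytest.approx(60.0, rel=0.05)
        assert m["duration_mean"] == pytest.approx(0.4, rel=0.05)
        assert m["speed_mean"] == pytest.approx(150.0, rel=0.05)
    assert abs(summary["mean_heading_change_deg"]) <= 5.0


def test_gait_summary_zero_cv_for_identical_strides(noiseless_track, single_bout):
    strides = kin.detect_strides(noiseless_track, single_bout)
    phase = kin.assign_phase(strides, noiseless_track)
    from spikegait.types import StrideTable

    table = StrideTable(strides, phase, bouts=[], frame_rate=80.0)
    summary = kin.gait_summary(table, noiseless_track)
    assert summary["per_limb"]["LF"]["duration_cv"] == pytest.approx(0.0, abs=1e-9)
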