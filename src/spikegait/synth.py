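"""Synthetic sessions with known ground truth.

Generates pose tracks that emulate a lateral-sequence quadruped walk
(bouts of walking separated by rest), and spike trains with von Mises
gait-phase coupling, linear speed tuning, movement-start transients, and
laser-evoked tagged responses.  Every generator is deterministic given its
seed, and returns the ground-truth parameters needed for recovery tests.

The limb model: each limb's projected position along the nose-tail axis is
``anchor - (amplitude/2)·cos(phase)`` with phase advancing at the stride
frequency during walking bouts.  Phase 0 therefore sits at the trough of
the projection, which is the stance-onset convention used by the stride
segmentation stage.  Default phase offsets encode left-right alternation
within each girdle and near-synchronous diagonals, giving the stance-onset
footfall order LR -> LF -> RR -> RF of a lateral-sequence walk.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import i0

from .types import KEYPOINTS, LIMBS, LaserProtocol, PoseTrack, SpikeTrain, StrideTable

__all__ = [
    "GaitGenParams",
    "SpikeGenParams",
    "TagGenParams",
    "generate_pose_track",
    "generate_phase_locked_spikes",
    "generate_tagged_unit",
    "default_waveform_template",
]

#: stance-onset phase offsets (degrees) producing the lateral-sequence
#: footfall order LR->LF->RR->RF with diagonal pairs within 10 degrees
DEFAULT_PHASE_OFFSETS = {"LR": 0.0, "LF": 185.0, "RR": 175.0, "RF": 10.0}

# body-frame keypoint anchors, mm (x forward toward nose, y leftward)
_ANCHORS = {
    "nose": (35.0, 0.0),
    "tail": (-35.0, 0.0),
    "LF": (15.0, 10.0),
    "RF": (15.0, -10.0),
    "LR": (-15.0, 10.0),
    "RR": (-15.0, -10.0),
}


@dataclass
class GaitGenParams:
    """Parameters of the synthetic gait generator.

    ``bout_schedule`` lists (start_s, stop_s, body_speed_mm_s) walking bouts;
    they must be ordered and non-overlapping.  ``timing_jitter_sd`` perturbs
    each stride's stance time; ``position_noise_sd`` is per-frame Gaussian
    keypoint noise in mm (default one pixel).  ``turn_rate`` (deg/s, positive
    = leftward/counter-clockwise) gives a constant-curvature walking path.
    """

    frame_rate: float = 80.0
    pixel_scale: float = 0.3
    stride_frequency: float = 2.5
    limb_phase_offsets: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_OFFSETS))
    stride_amplitude: float = 30.0
    bout_schedule: Sequence[tuple] = field(
        default_factory=lambda: [(5.0, 25.0, 150.0), (35.0, 55.0, 150.0)]
    )
    timing_jitter_sd: float = 0.01
    position_noise_sd: float = 0.3
    session_duration: Optional[float] = None
    turn_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (0.5 <= self.stride_frequency <= 8.0):
            raise ValueError("stride_frequency must lie in the 0.5-8 Hz gait band")
        prev_stop = -np.inf
        for start, stop, speed in self.bout_schedule:
            if not start < stop:
                raise ValueError("bout start must precede stop")
            if start < prev_stop:
                raise ValueError("bouts must be ordered and non-overlapping")
            if speed < 0:
                raise ValueError("bout speed must be nonnegative")
            prev_stop = stop


@dataclass
class SpikeGenParams:
    """Ground-truth coding parameters of one synthetic unit.

    Firing rate model (rectified at zero):

        r(t) = max(0, (base_rate + speed_gain * v(t)) * g_phase(t) * g_start(t))

    where ``g_phase = exp(kappa*cos(phase - mu)) / I0(kappa)`` whenever the
    coupled limb's phase is defined (mean 1 over a uniform phase cycle, so
    kappa does not change the average rate), and ``g_start`` adds Gaussian
    transients of fractional amplitude ``start_transient_amp`` at bout starts
    (and ``stop_transient_amp`` at bout stops).
    """

    base_rate: float = 5.0
    phase_kappa: float = 0.0
    preferred_phase: float = 0.0
    coupled_limb: Optional[str] = None
    speed_gain: float = 0.0
    start_transient_amp: float = 0.0
    start_transient_width: float = 0.25
    stop_transient_amp: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be nonnegative")
        if self.phase_kappa < 0:
            raise ValueError("phase_kappa must be nonnegative")
        if self.coupled_limb is not None and self.coupled_limb not in LIMBS:
            raise ValueError(f"unknown limb {self.coupled_limb!r}")


@dataclass
class TagGenParams:
    """Laser-tagging protocol and evoked-response ground truth."""

    n_pulses: int = 200
    pulse_period: float = 3.0
    pulse_duration: float = 0.010
    evoked_latency: float = 0.002
    evoked_prob: float = 0.9
    waveform_template: Optional[np.ndarray] = None
    evoked_scale: float = 1.0
    latency_jitter_sd: float = 0.0003
    waveform_noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.evoked_latency < 0:
            raise ValueError("evoked_latency must be nonnegative")
        if not 0.0 <= self.evoked_prob <= 1.0:
            raise ValueError("evoked_prob must be a probability")
        if self.n_pulses < 1:
            raise ValueError("need at least one pulse")


def generate_pose_track(params: GaitGenParams) -> PoseTrack:
    """Simulate a tracked session of walking bouts and rest.

    During each scheduled bout the body translates at the scheduled speed
    (optionally turning at ``params.turn_rate``) while each limb oscillates
    along the instantaneous nose-tail axis at the stride frequency with its
    assigned phase offset; between bouts all keypoints are stationary apart
    from tracking noise.

    Returns a :class:`PoseTrack` whose ``ground_truth`` attribute records the
    per-limb phase series (deg, NaN at rest), per-frame body speed, heading,
    and the generator parameters.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fr = params.frame_rate
    last_stop = max((b[1] for b in params.bout_schedule), default=10.0)
    duration = params.session_duration or last_stop + 5.0
    n = int(round(duration * fr))
    t = np.arange(n) / fr

    # scheduled per-frame body speed and bout membership
    speed = np.zeros(n)
    in_bout = np.zeros(n, dtype=bool)
    for start, stop, v in params.bout_schedule:
        m = (t >= start) & (t < stop)
        speed[m] = v
        in_bout[m] = True

    # heading and centroid path (constant curvature inside bouts)
    dt = 1.0 / fr
    heading = np.cumsum(np.where(in_bout, np.deg2rad(params.turn_rate) * dt, 0.0))
    heading = np.concatenate([[0.0], heading[:-1]])
    dir_xy = np.stack([np.cos(heading), np.sin(heading)], axis=1)
    centroid = np.cumsum(speed[:, None] * dir_xy * dt, axis=0)

    # per-limb oscillator phase with per-stride timing jitter
    f = params.stride_frequency
    gt_phase = {}
    for limb in LIMBS:
        phase = np.full(n, np.nan)
        for start, stop, v in params.bout_schedule:
            m = (t >= start) & (t < stop)
            tb = t[m] - start
            if params.timing_jitter_sd > 0:
                n_strides = int(np.ceil((stop - start) * f)) + 2
                knots = np.arange(n_strides) / f
                eps = rng.normal(0.0, params.timing_jitter_sd, n_strides)
                warp = np.interp(tb, knots, eps)
            else:
                warp = 0.0
            phase[m] = (
                360.0 * f * (tb + warp) + params.limb_phase_offsets[limb]
            ) % 360.0
        gt_phase[limb] = phase

    # keypoint positions: rigid anchors plus the limb oscillation along the
    # body axis; noise everywhere
    perp = np.stack([-np.sin(heading), np.cos(heading)], axis=1)
    coords = {}
    for kp in KEYPOINTS:
        ax, ay = _ANCHORS[kp]
        pos = centroid + ax * dir_xy + ay * perp
        if kp in LIMBS:
            osc = np.where(
                np.isnan(gt_phase[kp]),
                0.0,
                -(params.stride_amplitude / 2.0)
                * np.cos(np.deg2rad(np.nan_to_num(gt_phase[kp]))),
            )
            pos = pos + osc[:, None] * dir_xy
        pos = pos + rng.normal(0.0, params.position_noise_sd, (n, 2))
        coords[kp] = pos

    track = PoseTrack(t, coords, frame_rate=fr, pixel_scale=params.pixel_scale)
    track.ground_truth = {
        "phase": gt_phase,
        "speed": speed,
        "heading_deg": np.rad2deg(heading),
        "in_bout": in_bout,
        "params": params,
        # stride length ground truth: body displacement per gait cycle
        "step_length": {
            (start, stop): v / f for start, stop, v in params.bout_schedule
        },
    }
    return track


def _phase_series(
    track: PoseTrack, strides: Optional[StrideTable], limb: str
) -> np.ndarray:
    if strides is not None:
        if limb not in strides.phase:
            raise ValueError(f"limb {limb!r} missing from stride table")
        return strides.phase[limb]
    gt = getattr(track, "ground_truth", None)
    if gt is None or limb not in gt["phase"]:
        raise ValueError(f"limb {limb!r} missing from ground truth")
    return gt["phase"][limb]


def _frame_rate_profile(
    track: PoseTrack, strides: Optional[StrideTable], params: SpikeGenParams
) -> np.ndarray:
    """Per-frame firing rate (spikes/s) implied by the coding parameters."""
    n = track.n_frames
    t = track.frame_times
    gt = getattr(track, "ground_truth", {})
    speed = gt.get("speed")
    if speed is None:
        from .kinematics import body_speed

        speed = body_speed(track)
    rate = params.base_rate + params.speed_gain * speed

    g = np.ones(n)
    if params.coupled_limb is not None and params.phase_kappa > 0:
        phase = _phase_series(track, strides, params.coupled_limb)
        defined = ~np.isnan(phase)
        theta = np.deg2rad(phase[defined] - params.preferred_phase)
        g[defined] = np.exp(params.phase_kappa * np.cos(theta)) / i0(params.phase_kappa)
    rate = rate * g

    if params.start_transient_amp or params.stop_transient_amp:
        bouts = gt.get("params").bout_schedule if gt else []
        w = params.start_transient_width
        mod = np.ones(n)
        for start, stop, _v in bouts:
            if params.start_transient_amp:
                mod += params.start_transient_amp * np.exp(
                    -((t - start) ** 2) / (2 * w**2)
                )
            if params.stop_transient_amp:
                mod += params.stop_transient_amp * np.exp(
                    -((t - stop) ** 2) / (2 * w**2)
                )
        rate = rate * mod
    return np.maximum(rate, 0.0)


def generate_phase_locked_spikes(
    track: PoseTrack,
    strides: Optional[StrideTable],
    params: SpikeGenParams,
    unit_id: str = "synthetic",
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes from the unit's rate model.

    The rate is piecewise constant over video frames (the resolution at which
    phase and speed are known), so spike counts per frame are exactly Poisson
    with mean rate*dt and times uniform within the frame.  Pass
    ``strides=None`` to couple to the generator's ground-truth phase.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rate = _frame_rate_profile(track, strides, params)
    dt = 1.0 / track.frame_rate
    counts = rng.poisson(rate * dt)
    idx = np.repeat(np.arange(track.n_frames), counts)
    times = track.frame_times[idx] + rng.uniform(0.0, dt, idx.size)
    st = SpikeTrain(
        unit_id=unit_id,
        spike_times=times,
        session_end=track.duration,
        ground_truth={"params": params, "rate_profile_hz": rate},
    )
    return st


def default_waveform_template(n_samples: int = 32) -> np.ndarray:
    """Canonical biphasic extracellular spike shape (uV), trough ~ -100."""
    s = np.arange(n_samples, dtype=float)
    return -100.0 * np.exp(-((s - 10.0) ** 2) / 8.0) + 30.0 * np.exp(
        -((s - 19.0) ** 2) / 30.0
    )


def generate_tagged_unit(
    params: TagGenParams,
    background: SpikeGenParams,
    session_duration: float = 300.0,
) -> SpikeTrain:
    """Background spikes plus a post-session laser-tagging block.

    The laser protocol starts 5 s after ``session_duration``; each pulse
    evokes a spike at ``evoked_latency`` (with small jitter) with probability
    ``evoked_prob``.  Waveform snippets are the template (evoked ones scaled
    by ``evoked_scale``) plus white noise; background firing continues through
    the tagging block so pre-pulse baselines are populated.
    """
    params.validate()
    background.validate()
    rng = np.random.default_rng(params.seed)
    pulse_times = session_duration + 5.0 + params.pulse_period * np.arange(
        params.n_pulses
    )
    full_end = pulse_times[-1] + params.pulse_period

    n_bg = rng.poisson(background.base_rate * full_end)
    bg_times = np.sort(rng.uniform(0.0, full_end, n_bg))

    evoked_mask = rng.random(params.n_pulses) < params.evoked_prob
    ev_times = (
        pulse_times[evoked_mask]
        + params.evoked_latency
        + np.abs(rng.normal(0.0, params.latency_jitter_sd, evoked_mask.sum()))
    )

    times = np.concatenate([bg_times, ev_times])
    is_evoked = np.concatenate(
        [np.zeros(n_bg, dtype=bool), np.ones(ev_times.size, dtype=bool)]
    )
    order = np.argsort(times)
    times, is_evoked = times[order], is_evoked[order]

    template = (
        params.waveform_template
        if params.waveform_template is not None
        else default_waveform_template()
    )
    template = np.asarray(template, dtype=float)
    scale = np.where(is_evoked, params.evoked_scale, 1.0)
    waveforms = scale[:, None] * template[None, :] + rng.normal(
        0.0, params.waveform_noise_sd, (times.size, template.size)
    )

    return SpikeTrain(
        unit_id="tagged-synthetic",
        spike_times=times,
        session_end=full_end,
        first_laser_time=float(pulse_times[0]),
        waveforms=waveforms,
        protocol=LaserProtocol(pulse_times, params.pulse_duration),
        ground_truth={"params": params, "is_evoked": is_evoked},
    )
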