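"""Stride segmentation and gait kinematics from tracked keypoints.

Pipeline: Savitzky-Golay smoothing -> projection of each limb onto the
nose-tail axis -> 0.5-8 Hz zero-phase band-pass -> trough/peak detection
within accepted walking bouts (trough = stance onset, peak = swing onset)
-> linear 0-360 deg phase interpolation between consecutive stance onsets.

Walking bouts are found from whole-body speed and accepted automatically by
a rhythmicity score (fraction of limb-signal variance in the gait band),
with a manual-override hook for curated sessions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import circmean

from .types import DIAGONAL_PAIRS, KEYPOINTS, LIMBS, PoseTrack, StrideTable, WalkingBout

__all__ = [
    "KinematicsConfig",
    "smooth_track",
    "interpolate_missing",
    "project_limb",
    "bandpass_gait",
    "body_speed",
    "find_walking_bouts",
    "detect_strides",
    "assign_phase",
    "segment_strides",
    "relative_limb_phase",
    "swing_time_offsets",
    "heading_series",
    "gait_summary",
]

GAIT_BAND = (0.5, 8.0)


@dataclass
class KinematicsConfig:
    """Tunable parameters of the gait pipeline (units: mm, s, deg).

    Defaults: 7-frame (~87 ms at 80 fps) cubic Savitzky-Golay window;
    3rd-order Butterworth 0.5-8 Hz band-pass run forward-backward; extrema
    separated by at least half the 8 Hz period with prominence >= 10% of the
    bout signal SD; candidate bouts need body speed > 50 mm/s sustained
    >= 0.5 s (gaps < 0.25 s merged) and a limb rhythmicity score >= 0.5.
    """

    sg_window: int = 7
    sg_order: int = 3
    band: tuple = GAIT_BAND
    min_peak_separation_hz: float = 8.0
    prominence_frac: float = 0.10
    speed_threshold: float = 50.0
    min_bout_duration: float = 0.5
    merge_gap: float = 0.25
    rhythmicity_threshold: float = 0.5
    max_gap_frames: int = 5
    edge_margin_s: float = 0.125
    overrides: dict = field(default_factory=dict)


def interpolate_missing(track: PoseTrack, max_gap_frames: int = 5) -> PoseTrack:
    """Linearly interpolate NaN keypoint samples across gaps <= max_gap_frames.

    Longer gaps are left as NaN; downstream bout selection excludes them.
    """
    coords = {}
    for k in KEYPOINTS:
        xy = track.coords[k].copy()
        for d in range(2):
            col = xy[:, d]
            bad = np.isnan(col)
            if not bad.any() or bad.all():
                coords[k] = xy
                continue
            # identify runs of NaN and fill only the short interior ones
            idx = np.arange(len(col))
            filled = np.interp(idx, idx[~bad], col[~bad])
            runs = _bool_runs(bad)
            for s, e in runs:
                if e - s <= max_gap_frames and s > 0 and e < len(col):
                    col[s:e] = filled[s:e]
            xy[:, d] = col
        coords[k] = xy
    return PoseTrack(track.frame_times, coords, track.frame_rate, track.pixel_scale)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of contiguous True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [len(mask)]
    return list(zip(starts, stops))


def smooth_track(track: PoseTrack, window_frames: int = 7, order: int = 3) -> PoseTrack:
    """3rd-order Savitzky-Golay fit of every coordinate series."""
    if window_frames % 2 == 0 or window_frames <= order:
        raise ValueError("window_frames must be odd and exceed the filter order")
    if window_frames > track.n_frames:
        raise ValueError("smoothing window longer than the track")
    coords = {
        k: sps.savgol_filter(track.coords[k], window_frames, order, axis=0)
        for k in KEYPOINTS
    }
    return PoseTrack(track.frame_times, coords, track.frame_rate, track.pixel_scale)


def project_limb(track: PoseTrack, limb: str) -> np.ndarray:
    """Project a limb onto the per-frame nose-tail axis.

    Returns (limb - tail) . unit(nose - tail) in mm; larger values are closer
    to the nose.  Frames with coincident nose/tail are flagged NaN and
    linearly interpolated when isolated.
    """
    if limb not in LIMBS:
        raise ValueError(f"unknown limb {limb!r}")
    axis = track.coords["nose"] - track.coords["tail"]
    norm = np.linalg.norm(axis, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = axis / norm[:, None]
    proj = np.einsum("ij,ij->i", track.coords[limb] - track.coords["tail"], unit)
    proj[norm == 0] = np.nan
    bad = np.isnan(proj)
    if bad.any() and not bad.all():
        idx = np.arange(len(proj))
        fill = np.interp(idx, idx[~bad], proj[~bad])
        for s, e in _bool_runs(bad):
            if e - s == 1 and 0 < s and e < len(proj):  # isolated undefined frame
                proj[s:e] = fill[s:e]
    return proj


def bandpass_gait(x: np.ndarray, frame_rate: float, band: tuple = GAIT_BAND) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass of a projected limb signal."""
    if frame_rate <= 2 * band[1]:
        raise ValueError("frame rate too low for the gait band")
    sos = sps.butter(3, band, btype="bandpass", fs=frame_rate, output="sos")
    x = np.asarray(x, dtype=float)
    x = x - np.nanmean(x)
    x = np.nan_to_num(x)
    return sps.sosfiltfilt(sos, x)


def body_speed(track: PoseTrack) -> np.ndarray:
    """Whole-body speed (mm/s): centered finite-difference of the 6-keypoint centroid."""
    c = track.centroid()
    v = np.gradient(c, 1.0 / track.frame_rate, axis=0)
    return np.linalg.norm(v, axis=1)


def _rhythmicity(track: PoseTrack, s: int, e: int, band: tuple) -> float:
    """Fraction of projected-limb variance inside the gait band, limb-averaged."""
    scores = []
    for limb in LIMBS:
        seg = project_limb(track, limb)[s:e]
        seg = seg - np.nanmean(seg)
        seg = np.nan_to_num(seg)
        total = np.var(seg)
        if total == 0:
            scores.append(0.0)
            continue
        bp = bandpass_gait(seg, track.frame_rate, band)
        scores.append(float(np.var(bp) / total))
    return float(np.mean(scores))


def find_walking_bouts(
    track: PoseTrack, config: Optional[KinematicsConfig] = None
) -> list[WalkingBout]:
    """Candidate bouts from body speed, auto-accepted by limb rhythmicity.

    Candidates are runs of speed > ``speed_threshold`` lasting at least
    ``min_bout_duration`` (gaps shorter than ``merge_gap`` merged).  Each is
    scored by the band-variance fraction of the four projected limb signals
    and accepted when the score passes ``rhythmicity_threshold``.  Manual
    review is supported through ``config.overrides`` ({bout_id: bool}),
    which wins over the automatic decision.
    """
    config = config or KinematicsConfig()
    speed = body_speed(track)
    fast = speed > config.speed_threshold
    runs = _bool_runs(fast)
    # merge runs separated by brief dips
    merged: list[list[int]] = []
    gap = int(round(config.merge_gap * track.frame_rate))
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_frames = int(round(config.min_bout_duration * track.frame_rate))
    bouts = []
    bout_id = 0
    for s, e in merged:
        if e - s < min_frames:
            continue
        score = _rhythmicity(track, s, e, config.band)
        accepted = score >= config.rhythmicity_threshold
        if bout_id in config.overrides:
            accepted = bool(config.overrides[bout_id])
        bouts.append(
            WalkingBout(
                start=s / track.frame_rate,
                stop=e / track.frame_rate,
                accepted=accepted,
                rhythmicity_score=score,
                bout_id=bout_id,
            )
        )
        bout_id += 1
    return bouts


def _alternating_extrema(
    x: np.ndarray, frame_rate: float, config: KinematicsConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Trough and peak indices, enforcing trough/peak alternation.

    Minimum separation is half the period of the band's upper edge; required
    prominence is a fraction of the segment SD.  When two same-type extrema
    are consecutive the more extreme one is kept.
    """
    dist = max(1, int(round(frame_rate / (2.0 * config.min_peak_separation_hz))))
    prom = config.prominence_frac * float(np.std(x))
    peaks, _ = sps.find_peaks(x, distance=dist, prominence=prom)
    troughs, _ = sps.find_peaks(-x, distance=dist, prominence=prom)
    events = sorted(
        [(i, +1) for i in peaks] + [(i, -1) for i in troughs], key=lambda p: p[0]
    )
    cleaned: list[tuple[int, int]] = []
    for i, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            j, _ = cleaned[-1]
            better = x[i] > x[j] if kind == +1 else x[i] < x[j]
            if better:
                cleaned[-1] = (i, kind)
        else:
            cleaned.append((i, kind))
    troughs = np.array([i for i, k in cleaned if k == -1], dtype=int)
    peaks = np.array([i for i, k in cleaned if k == +1], dtype=int)
    return troughs, peaks


def detect_strides(
    track: PoseTrack,
    bouts: Iterable[WalkingBout],
    config: Optional[KinematicsConfig] = None,
    smoothed: Optional[PoseTrack] = None,
) -> pd.DataFrame:
    """Segment strides (stance -> swing -> next stance) within accepted bouts.

    Stance onsets are troughs and swing onsets peaks of the band-passed
    nose-tail projection of each limb; incomplete cycles at bout edges are
    discarded.  Stride length is the Euclidean distance between the limb's
    (smoothed, unfiltered) positions at consecutive stance onsets.
    """
    config = config or KinematicsConfig()
    smoothed = smoothed or smooth_track(track, config.sg_window, config.sg_order)
    fr = track.frame_rate
    rows = []
    for limb in LIMBS:
        proj = project_limb(smoothed, limb)
        filt = bandpass_gait(proj, fr, config.band)
        for bout in bouts:
            if not bout.accepted:
                continue
            s = int(round(bout.start * fr))
            e = int(round(bout.stop * fr))
            seg = filt[s:e]
            if len(seg) < 3:
                continue
            troughs, peaks = _alternating_extrema(seg, fr, config)
            # zero-phase filter transients distort extrema at the bout
            # edges; drop events inside the transient margin
            margin = int(round(config.edge_margin_s * fr))
            troughs = troughs[(troughs >= margin) & (troughs < len(seg) - margin)]
            peaks = peaks[(peaks >= margin) & (peaks < len(seg) - margin)]
            for a, b in zip(troughs[:-1], troughs[1:]):
                between = peaks[(peaks > a) & (peaks < b)]
                if len(between) != 1:
                    continue
                p = int(between[0])
                i0, i1 = s + int(a), s + int(b)
                length = float(
                    np.linalg.norm(smoothed.coords[limb][i1] - smoothed.coords[limb][i0])
                )
                duration = (i1 - i0) / fr
                stance_dur = (p - a) / fr
                swing_dur = (b - p) / fr
                rows.append(
                    {
                        "limb": limb,
                        "stance_onset": i0 / fr,
                        "swing_onset": (s + p) / fr,
                        "next_stance_onset": i1 / fr,
                        "length": length,
                        "duration": duration,
                        "speed": length / duration,
                        "swing_stance_ratio": swing_dur / stance_dur,
                        "bout_id": bout.bout_id,
                    }
                )
    cols = [
        "limb",
        "stance_onset",
        "swing_onset",
        "next_stance_onset",
        "length",
        "duration",
        "speed",
        "swing_stance_ratio",
        "bout_id",
    ]
    return pd.DataFrame(rows, columns=cols)


def assign_phase(strides: pd.DataFrame, track: PoseTrack) -> dict[str, np.ndarray]:
    """Per-frame limb phase: linear from 0 deg at stance onset to 360 deg at
    the next stance onset; NaN outside strides."""
    fr = track.frame_rate
    phase = {limb: np.full(track.n_frames, np.nan) for limb in LIMBS}
    for row in strides.itertuples():
        i0 = int(round(row.stance_onset * fr))
        i1 = int(round(row.next_stance_onset * fr))
        k = np.arange(i0, i1)
        phase[row.limb][k] = 360.0 * (k - i0) / (i1 - i0)
    return phase


def segment_strides(
    track: PoseTrack, config: Optional[KinematicsConfig] = None
) -> StrideTable:
    """Full pipeline: smooth, find walking bouts, detect strides, assign phase."""
    config = config or KinematicsConfig()
    clean = interpolate_missing(track, config.max_gap_frames)
    smoothed = smooth_track(clean, config.sg_window, config.sg_order)
    bouts = find_walking_bouts(clean, config)
    strides = detect_strides(clean, bouts, config, smoothed=smoothed)
    phase = assign_phase(strides, track)
    return StrideTable(strides, phase, bouts=bouts, frame_rate=track.frame_rate)


def relative_limb_phase(
    table: StrideTable, reference: str = "LR"
) -> dict[tuple[str, str], float]:
    """Circular mean of each limb's phase sampled at the reference limb's
    stance onsets, in degrees [0, 360).

    Keys are (limb, reference).  Stance-onset frames where the other limb's
    phase is undefined are skipped; a pair with no overlap maps to NaN.
    """
    fr = table.frame_rate
    out = {}
    ref_onsets = table.limb_strides(reference)["stance_onset"].to_numpy()
    idx = np.round(ref_onsets * fr).astype(int)
    for limb in LIMBS:
        ph = table.phase[limb][idx[idx < len(table.phase[limb])]]
        ph = ph[~np.isnan(ph)]
        if len(ph) == 0:
            out[(limb, reference)] = np.nan
            continue
        out[(limb, reference)] = float(
            np.rad2deg(circmean(np.deg2rad(ph))) % 360.0
        )
    return out


def swing_time_offsets(
    table: StrideTable, reference: str = "LR"
) -> dict[str, float]:
    """Mean swing-start time of each limb relative to the reference limb.

    For each reference stride, each limb's first swing onset inside the
    stride window is taken; the offset is its delay after the reference
    limb's swing onset, in seconds (mean over strides).
    """
    out = {}
    ref = table.limb_strides(reference)
    for limb in LIMBS:
        onsets = table.limb_strides(limb)["swing_onset"].to_numpy()
        deltas = []
        for row in ref.itertuples():
            inside = onsets[(onsets >= row.stance_onset) & (onsets < row.next_stance_onset)]
            if len(inside):
                deltas.append(inside[0] - row.swing_onset)
        out[limb] = float(np.mean(deltas)) if deltas else np.nan
    return out


def heading_series(track: PoseTrack) -> np.ndarray:
    """Unwrapped tail-to-nose heading angle, degrees; positive = counter-clockwise."""
    axis = track.coords["nose"] - track.coords["tail"]
    ang = np.unwrap(np.arctan2(axis[:, 1], axis[:, 0]))
    return np.rad2deg(ang)


def gait_summary(
    table: StrideTable,
    track: PoseTrack,
    initiation_rate_per_min: Optional[float] = None,
) -> dict:
    """Session-level gait metrics.

    Per limb: mean/SD/CV of stride length, duration and speed plus the mean
    swing:stance duration ratio.  Whole body: total distance travelled by
    the centroid, mean body speed, movement-initiation rate (if supplied)
    and per-bout heading change (final minus initial heading, degrees,
    positive = contraversive/counter-clockwise for a right-hemisphere
    recording convention).
    """
    per_limb = {}
    for limb in LIMBS:
        s = table.limb_strides(limb)
        m = {}
        for col in ("length", "duration", "speed"):
            x = s[col].to_numpy()
            m[f"{col}_mean"] = float(np.mean(x)) if len(x) else np.nan
            m[f"{col}_sd"] = float(np.std(x, ddof=1)) if len(x) > 1 else np.nan
            m[f"{col}_cv"] = (
                m[f"{col}_sd"] / m[f"{col}_mean"] if len(x) > 1 and m[f"{col}_mean"] else np.nan
            )
        m["swing_stance_ratio_mean"] = (
            float(s["swing_stance_ratio"].mean()) if len(s) else np.nan
        )
        m["n_strides"] = int(len(s))
        per_limb[limb] = m

    c = track.centroid()
    total_distance = float(np.nansum(np.linalg.norm(np.diff(c, axis=0), axis=1)))
    speed = body_speed(track)
    heading = heading_series(track)
    fr = track.frame_rate
    heading_changes = []
    for bout in table.bouts:
        if not bout.accepted:
            continue
        i0, i1 = int(round(bout.start * fr)), int(round(bout.stop * fr)) - 1
        heading_changes.append(float(heading[i1] - heading[i0]))
    return {
        "per_limb": per_limb,
        "total_distance_mm": total_distance,
        "mean_body_speed_mms": float(np.mean(speed)),
        "initiation_rate_per_min": initiation_rate_per_min,
        "heading_change_deg": heading_changes,
        "mean_heading_change_deg": float(np.mean(heading_changes))
        if heading_changes
        else np.nan,
    }
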