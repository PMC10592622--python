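"""Whole-body motion-bout detection for event-aligned neural analysis.

A motion bout is a run of body speed above 50 mm/s lasting at least 0.3 s,
extended backward and forward to the frames where speed crosses 20 mm/s;
overlapping extended bouts are merged.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MotionBout", "detect_motion_bouts", "initiation_rate", "bouts_to_frame"]


@dataclass
class MotionBout:
    start: float
    stop: float
    peak_speed: float
    edge_truncated: bool = False


def detect_motion_bouts(
    speed: np.ndarray,
    frame_rate: float,
    high: float = 50.0,
    low: float = 20.0,
    min_duration: float = 0.3,
) -> list[MotionBout]:
    """Detect motion bouts from a uniform per-frame speed trace (mm/s).

    Runs with speed > ``high`` shorter than ``min_duration`` are discarded;
    surviving runs are extended to the contiguous region with speed >=
    ``low`` (ties at the threshold count as above).  Bouts touching the
    session edges are kept but flagged ``edge_truncated``.
    """
    speed = np.asarray(speed, dtype=float)
    n = len(speed)
    fast = speed > high
    min_frames = int(round(min_duration * frame_rate))
    above_low = speed >= low
    intervals = []
    i = 0
    while i < n:
        if fast[i]:
            j = i
            while j < n and fast[j]:
                j += 1
            if j - i >= min_frames:
                # scan out to the 20 mm/s crossings
                s = i
                while s > 0 and above_low[s - 1]:
                    s -= 1
                e = j - 1
                while e < n - 1 and above_low[e + 1]:
                    e += 1
                intervals.append([s, e])
            i = j
        else:
            i += 1
    # merge overlapping extended bouts
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    bouts = []
    for s, e in merged:
        bouts.append(
            MotionBout(
                start=s / frame_rate,
                stop=e / frame_rate,
                peak_speed=float(np.max(speed[s : e + 1])),
                edge_truncated=(s == 0) or (e == n - 1),
            )
        )
    return bouts


def initiation_rate(bouts: list[MotionBout], session_duration: float) -> float:
    """Movement-initiation rate: bout starts per minute."""
    if session_duration <= 0:
        raise ValueError("session duration must be positive")
    return 60.0 * len(bouts) / session_duration


def bouts_to_frame(bouts: list[MotionBout]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_s": b.start,
                "stop_s": b.stop,
                "peak_speed_mms": b.peak_speed,
                "edge_truncated": b.edge_truncated,
            }
            for b in bouts
        ],
        columns=["start_s", "stop_s", "peak_speed_mms", "edge_truncated"],
    )
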