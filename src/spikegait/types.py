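"""Core data containers shared across the pipeline.

Units are mm, seconds, and degrees throughout the public contract. A pose
track holds the six tracked body parts (four limbs, nose, tail base) in
calibrated mm; spike trains are flat sorted time lists in session time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

#: canonical keypoint order: left-front, left-rear, right-front, right-rear,
#: nose, tail base
KEYPOINTS = ("LF", "LR", "RF", "RR", "nose", "tail")
LIMBS = ("LF", "LR", "RF", "RR")
#: diagonal limb pairs move approximately in phase in a lateral-sequence walk
DIAGONAL_PAIRS = (frozenset({"LF", "RR"}), frozenset({"LR", "RF"}))


@dataclass
class PoseTrack:
    """Frame-indexed 2-D coordinates of the six keypoints, in mm.

    Parameters
    ----------
    frame_times : (n_frames,) array, seconds, strictly increasing & uniform.
    coords : dict keypoint -> (n_frames, 2) array of x, y in mm. Missing
        samples are NaN and are linearly interpolated across short gaps by
        the kinematics stage.
    frame_rate : frames per second (80 in the recordings emulated here).
    pixel_scale : mm per pixel of the original video (0.3 mm/px); kept for
        provenance, coordinates are already calibrated.
    """

    frame_times: np.ndarray
    coords: dict[str, np.ndarray]
    frame_rate: float = 80.0
    pixel_scale: float = 0.3

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.ndim != 1:
            raise ValueError("frame_times must be 1-D")
        if len(self.frame_times) > 1:
            dt = np.diff(self.frame_times)
            if np.any(dt <= 0):
                raise ValueError("frame_times must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise ValueError("frame_times must be uniform to within 1e-6 s")
        for k in KEYPOINTS:
            if k not in self.coords:
                raise ValueError(f"missing keypoint {k!r}")
            self.coords[k] = np.asarray(self.coords[k], dtype=float)
            if self.coords[k].shape != (len(self.frame_times), 2):
                raise ValueError(f"coords[{k!r}] shape mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def centroid(self) -> np.ndarray:
        """(n_frames, 2) mean position of all six keypoints."""
        return np.nanmean(np.stack([self.coords[k] for k in KEYPOINTS]), axis=0)

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, keypoint, x_mm, y_mm."""
        rows = []
        for k in KEYPOINTS:
            rows.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(self.n_frames),
                        "keypoint": k,
                        "x_mm": self.coords[k][:, 0],
                        "y_mm": self.coords[k][:, 1],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        frame_rate: float = 80.0,
        pixel_scale: float = 0.3,
        in_pixels: bool = False,
    ) -> "PoseTrack":
        """Read a long-format keypoint table.

        Accepts either calibrated columns (x_mm, y_mm) or raw pixel columns
        (x_px, y_px, optional confidence) which are scaled by ``pixel_scale``.
        """
        df = pd.read_csv(path)
        if in_pixels or "x_px" in df.columns:
            df = df.assign(x_mm=df["x_px"] * pixel_scale, y_mm=df["y_px"] * pixel_scale)
        n = int(df["frame"].max()) + 1
        coords = {}
        for k in KEYPOINTS:
            sub = df[df["keypoint"] == k].set_index("frame").sort_index()
            arr = np.full((n, 2), np.nan)
            arr[sub.index, 0] = sub["x_mm"]
            arr[sub.index, 1] = sub["y_mm"]
            coords[k] = arr
        times = np.arange(n) / frame_rate
        return cls(times, coords, frame_rate=frame_rate, pixel_scale=pixel_scale)

    def to_hdf5(self, path: str | Path) -> None:
        """Write a tracks × keypoints × xy × frames layout."""
        data = np.stack([self.coords[k].T for k in KEYPOINTS])  # (kp, 2, frames)
        with h5py.File(path, "w") as f:
            f.create_dataset("tracks", data=data[None, ...])
            f.create_dataset("node_names", data=np.array(KEYPOINTS, dtype="S"))
            f.attrs["frame_rate"] = self.frame_rate
            f.attrs["pixel_scale"] = self.pixel_scale

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PoseTrack":
        with h5py.File(path, "r") as f:
            data = f["tracks"][0]  # (kp, 2, frames)
            names = [n.decode() for n in f["node_names"][...]]
            fr = float(f.attrs.get("frame_rate", 80.0))
            px = float(f.attrs.get("pixel_scale", 0.3))
        coords = {name: data[i].T.copy() for i, name in enumerate(names)}
        times = np.arange(data.shape[-1]) / fr
        return cls(times, coords, frame_rate=fr, pixel_scale=px)


@dataclass
class WalkingBout:
    """An accepted interval of rhythmic walking."""

    start: float
    stop: float
    accepted: bool = True
    rhythmicity_score: float = np.nan
    bout_id: int = -1

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError("bout start must precede stop")


@dataclass
class StrideTable:
    """Per-limb strides plus the frame-indexed limb phase series.

    ``strides`` columns: limb, stance_onset, swing_onset, next_stance_onset,
    length, duration, speed, swing_stance_ratio (all s / mm / unitless).
    ``phase`` maps limb -> (n_frames,) degrees in [0, 360), NaN outside
    strides; phase is exactly 0 at each stance-onset frame.
    """

    strides: pd.DataFrame
    phase: dict[str, np.ndarray]
    bouts: list[WalkingBout] = field(default_factory=list)
    frame_rate: float = 80.0

    def limb_strides(self, limb: str) -> pd.DataFrame:
        return self.strides[self.strides["limb"] == limb]

    def to_csv(self, path: str | Path) -> None:
        self.strides.to_csv(path, index=False)


@dataclass
class LaserProtocol:
    """Optogenetic tagging pulse train delivered after the recording."""

    pulse_times: np.ndarray
    pulse_duration: float = 0.010
    artifact_window: float = 0.0006

    def __post_init__(self) -> None:
        self.pulse_times = np.sort(np.asarray(self.pulse_times, dtype=float))


@dataclass
class SpikeTrain:
    """One unit's sorted spike times in session time.

    ``waveforms`` is an optional (n_spikes, n_samples) snippet array aligned
    with ``spike_times``; ``ground_truth`` records generator parameters for
    recovery tests on synthetic units.
    """

    unit_id: str
    spike_times: np.ndarray
    session_end: float
    first_laser_time: Optional[float] = None
    waveforms: Optional[np.ndarray] = None
    protocol: Optional[LaserProtocol] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))
        if len(self.spike_times) and self.spike_times[0] < 0:
            raise ValueError("spike times must be nonnegative")

    @property
    def analysis_end(self) -> float:
        """Session time up to the first laser pulse (or session end)."""
        return self.session_end if self.first_laser_time is None else min(
            self.session_end, self.first_laser_time
        )

    def session_rate(self) -> float:
        """Session-wide firing rate: spikes / time until the first laser pulse."""
        t = self.analysis_end
        return float(np.sum(self.spike_times < t)) / t

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"spike_time_s": self.spike_times}).to_csv(path, index=False)
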