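"""Spike coupling to the single-limb gait cycle.

Firing rate versus limb phase is computed in 24 bins of 15 degrees with
frame-count occupancy normalization (spikes per phase bin / frames per phase
bin x frame rate).  Coupling strength and preferred phase are the mean
resultant vector length and angle of this rate-vs-phase distribution, and
significance comes from a spike-time jitter test: the vector length must
exceed more than 95% of 100 recomputations after jittering every spike by an
independent uniform draw on +/-0.5 s.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import DIAGONAL_PAIRS, LIMBS, SpikeTrain

__all__ = [
    "PhaseTuning",
    "N_BINS",
    "BIN_WIDTH_DEG",
    "rate_by_phase",
    "mean_vector",
    "jitter_test",
    "phase_tuning",
    "exclude_outliers",
    "limb_coupling_profile",
    "tuning_summary",
]

N_BINS = 24
BIN_WIDTH_DEG = 360.0 / N_BINS
BIN_CENTERS_DEG = (np.arange(N_BINS) + 0.5) * BIN_WIDTH_DEG


@dataclass
class PhaseTuning:
    """Binned firing rate vs limb phase and its resultant-vector statistics."""

    unit_id: str
    limb: str
    bin_edges: np.ndarray
    rate_per_bin: np.ndarray  # spikes/s; NaN where occupancy is zero
    occupancy_frames: np.ndarray
    n_spikes: int
    vector_length: float = np.nan
    vector_angle: float = np.nan
    jitter_p: float = np.nan
    significant: bool = False


def _phase_bins(phase: np.ndarray) -> np.ndarray:
    """Per-frame bin index 0..23, or -1 where phase is undefined."""
    bins = np.full(len(phase), -1, dtype=np.int64)
    ok = ~np.isnan(phase)
    bins[ok] = np.minimum((phase[ok] % 360.0) / BIN_WIDTH_DEG, N_BINS - 1).astype(
        np.int64
    )
    return bins


def _spike_frames(spike_times: np.ndarray, frame_rate: float, n_frames: int) -> np.ndarray:
    """Frame containing each spike: frame f covers [f/fr, (f+1)/fr)."""
    idx = np.floor(spike_times * frame_rate).astype(np.int64)
    return idx[(idx >= 0) & (idx < n_frames)]


def rate_by_phase(
    spikes: SpikeTrain | np.ndarray,
    phase: np.ndarray,
    frame_rate: float,
    unit_id: str = "",
    limb: str = "",
) -> PhaseTuning:
    """Occupancy-normalized firing rate per 15-degree phase bin.

    rate(bin) = spikes in frames whose phase falls in the bin
              / frames in the bin x frame_rate.
    Bins never occupied are NaN.  Spikes take the phase of the video frame
    containing them; spikes in frames without a defined phase are dropped.
    """
    times = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    uid = spikes.unit_id if isinstance(spikes, SpikeTrain) else unit_id
    frame_bins = _phase_bins(phase)
    occupancy = np.bincount(frame_bins[frame_bins >= 0], minlength=N_BINS)
    if occupancy.sum() == 0:
        raise ValueError("no frames with defined phase")
    idx = _spike_frames(times, frame_rate, len(phase))
    sb = frame_bins[idx]
    counts = np.bincount(sb[sb >= 0], minlength=N_BINS)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = counts / occupancy * frame_rate
    rate[occupancy == 0] = np.nan
    edges = np.arange(N_BINS + 1) * BIN_WIDTH_DEG
    return PhaseTuning(
        unit_id=uid,
        limb=limb,
        bin_edges=edges,
        rate_per_bin=rate,
        occupancy_frames=occupancy,
        n_spikes=int(counts.sum()),
    )


def mean_vector(tuning: PhaseTuning | np.ndarray) -> tuple[float, float]:
    """Resultant (length, angle_deg) of the rate-vs-phase distribution.

    Unit vectors at the bin centers are weighted by the bin rates and the
    resultant is normalized by the summed rates; length is 0-1 and the angle
    lies in [0, 360).  All-zero or all-NaN rates give length 0 with NaN angle.
    """
    rates = tuning.rate_per_bin if isinstance(tuning, PhaseTuning) else np.asarray(tuning)
    ok = ~np.isnan(rates)
    w = rates[ok]
    theta = np.deg2rad(BIN_CENTERS_DEG[ok])
    total = w.sum()
    if ok.sum() < 2 or total <= 0:
        return 0.0, np.nan
    z = np.sum(w * np.exp(1j * theta)) / total
    return float(np.abs(z)), float(np.rad2deg(np.angle(z)) % 360.0)


def _vector_length_from_counts(counts: np.ndarray, occupancy: np.ndarray) -> float:
    ok = occupancy > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = counts[ok] / occupancy[ok]
    total = w.sum()
    if total <= 0 or ok.sum() < 2:
        return 0.0
    theta = np.deg2rad(BIN_CENTERS_DEG[ok])
    return float(np.abs(np.sum(w * np.exp(1j * theta))) / total)


def jitter_test(
    spikes: SpikeTrain | np.ndarray,
    phase: np.ndarray,
    frame_rate: float,
    n_iter: int = 100,
    jitter_halfwidth: float = 0.5,
    percentile: float = 95.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, bool, float]:
    """Spike-time jitter significance test of phase coupling.

    Each iteration shifts every spike by an independent uniform draw on
    [-jitter_halfwidth, +jitter_halfwidth] s and recomputes the binned-rate
    vector length against the same phase series (jittered spikes that land on
    frames without a defined phase drop out, as in the real computation).
    Returns (jitter_p, significant, real_length); ``jitter_p`` is the
    fraction of jittered lengths >= the real one, and ``significant`` is True
    when the real length exceeds more than ``percentile``% of them.
    """
    times = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    rng = rng or np.random.default_rng(seed)
    frame_bins = _phase_bins(phase)
    occupancy = np.bincount(frame_bins[frame_bins >= 0], minlength=N_BINS)
    n_frames = len(phase)

    def _length(t: np.ndarray) -> float:
        idx = _spike_frames(t, frame_rate, n_frames)
        sb = frame_bins[idx]
        counts = np.bincount(sb[sb >= 0], minlength=N_BINS)
        return _vector_length_from_counts(counts, occupancy)

    real = _length(times)
    if len(times) == 0:
        return 1.0, False, real
    jittered = np.empty(n_iter)
    for i in range(n_iter):
        shifts = rng.uniform(-jitter_halfwidth, jitter_halfwidth, len(times))
        jittered[i] = _length(times + shifts)
    exceeds = int(np.sum(real > jittered))
    jitter_p = float(np.mean(jittered >= real))
    significant = exceeds > (percentile / 100.0) * n_iter
    return jitter_p, significant, real


def phase_tuning(
    spikes: SpikeTrain,
    phase: np.ndarray,
    frame_rate: float,
    limb: str,
    n_iter: int = 100,
    jitter_halfwidth: float = 0.5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PhaseTuning:
    """Full per-unit x per-limb tuning: binned rates, resultant, jitter test."""
    tuning = rate_by_phase(spikes, phase, frame_rate, limb=limb)
    tuning.vector_length, tuning.vector_angle = mean_vector(tuning)
    tuning.jitter_p, tuning.significant, _ = jitter_test(
        spikes,
        phase,
        frame_rate,
        n_iter=n_iter,
        jitter_halfwidth=jitter_halfwidth,
        seed=seed,
        rng=rng,
    )
    return tuning


def tuning_summary(tunings: list[PhaseTuning]) -> pd.DataFrame:
    """Flat per-unit x per-limb summary table."""
    return pd.DataFrame(
        [
            {
                "unit_id": t.unit_id,
                "limb": t.limb,
                "vector_length": t.vector_length,
                "vector_angle_deg": t.vector_angle,
                "jitter_p": t.jitter_p,
                "significant": t.significant,
                "n_spikes": t.n_spikes,
            }
            for t in tunings
        ]
    )


def exclude_outliers(summary: pd.DataFrame, cutoff: float = 0.9) -> tuple[pd.DataFrame, list]:
    """Drop units whose vector length exceeds ``cutoff`` for any limb.

    Such near-degenerate tunings (length > 0.9) are treated as outliers and
    removed from every downstream group analysis, including speed and
    start/stop coding.  Returns (filtered summary, excluded unit ids).
    """
    bad = summary.loc[summary["vector_length"] > cutoff, "unit_id"].unique().tolist()
    return summary[~summary["unit_id"].isin(bad)].copy(), bad


def limb_coupling_profile(tunings: dict[str, PhaseTuning]) -> dict:
    """Classify a unit by which limbs it is significantly coupled to.

    Classes: none / single / pair-diagonal / pair-other / multi (3+ limbs).
    Also ranks limbs by vector length (strongest first).
    """
    missing = [l for l in LIMBS if l not in tunings]
    if missing:
        raise ValueError(f"jitter tests missing for limbs {missing}")
    sig = sorted(l for l in LIMBS if tunings[l].significant)
    if len(sig) == 0:
        cls = "none"
    elif len(sig) == 1:
        cls = "single"
    elif len(sig) == 2:
        cls = "pair-diagonal" if frozenset(sig) in DIAGONAL_PAIRS else "pair-other"
    else:
        cls = "multi"
    ranked = sorted(LIMBS, key=lambda l: -np.nan_to_num(tunings[l].vector_length))
    return {"significant_limbs": sig, "coupling_class": cls, "limb_preference": ranked}
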