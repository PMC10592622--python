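"""Optogenetic tagging: classify units as D1/D2 MSNs by laser response.

Three conjunctive criteria: (1) a significant excitatory response within
6 ms of laser onset (after removing sub-0.6 ms photoelectric artifacts),
(2) Pearson r > 0.95 between the mean evoked and mean baseline waveforms,
and (3) a voltage-minimum amplitude ratio < 2 between them (Pearson
correlation is scale invariant, so the ratio criterion rejects amplitude
mismatches).  The tagged label (D1 vs D2) comes from the session genotype:
D1-Cre or A2a-Cre.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .types import LaserProtocol, SpikeTrain

__all__ = [
    "TagResult",
    "UnitWaveforms",
    "evoked_response_test",
    "waveform_criteria",
    "split_waveforms",
    "classify_unit",
]

LATENCY_WINDOW = 0.006
ARTIFACT_WINDOW = 0.0006
WAVEFORM_R_CUTOFF = 0.95
AMPLITUDE_RATIO_CUTOFF = 2.0
MIN_EVOKED_SPIKES = 10


@dataclass
class UnitWaveforms:
    """Mean spike waveforms inside and outside the evoked-latency window."""

    baseline_mean_waveform: np.ndarray
    evoked_mean_waveform: Optional[np.ndarray]
    n_evoked: int = 0


@dataclass
class TagResult:
    unit_id: str
    latency_significant: bool
    first_spike_latency: float
    waveform_r: float
    min_ratio: float
    tagged: bool
    label: str  # "D1", "D2", or "untagged"


def _remove_artifact_spikes(
    times: np.ndarray, pulse_times: np.ndarray, artifact_window: float
) -> np.ndarray:
    """Drop spikes within ``artifact_window`` of any pulse onset."""
    keep = np.ones(len(times), dtype=bool)
    j = np.searchsorted(pulse_times, times, side="right") - 1
    has_prev = j >= 0
    dt = np.where(has_prev, times - pulse_times[np.clip(j, 0, None)], np.inf)
    keep &= ~(has_prev & (dt < artifact_window))
    return times[keep]


def evoked_response_test(
    spikes: SpikeTrain,
    protocol: LaserProtocol,
    latency_window: float = LATENCY_WINDOW,
    artifact_window: float = ARTIFACT_WINDOW,
    alpha: float = 0.05,
    test: str = "ttest",
) -> tuple[bool, float]:
    """Criterion 1: significant excitatory response within 6 ms of laser onset.

    Sub-artifact-window spikes are removed; per-pulse spike counts in
    (artifact_window, latency_window] are compared one-sided against counts
    in a duration-matched window immediately preceding each pulse (paired
    t-test by default, Wilcoxon signed-rank with ``test='wilcoxon'``).
    Returns (significant, median first-spike latency among responsive pulses).
    """
    if len(protocol.pulse_times) == 0:
        raise ValueError("protocol has no pulses")
    times = _remove_artifact_spikes(
        spikes.spike_times, protocol.pulse_times, artifact_window
    )
    width = latency_window - artifact_window
    p_on = protocol.pulse_times
    post = np.searchsorted(times, p_on + latency_window) - np.searchsorted(
        times, p_on + artifact_window
    )
    pre = np.searchsorted(times, p_on) - np.searchsorted(times, p_on - width)
    diff = post - pre
    if np.all(diff == 0):
        significant = False
        p = 1.0
    elif test == "wilcoxon":
        nz = diff[diff != 0]
        p = float(stats.wilcoxon(nz, alternative="greater").pvalue) if len(nz) else 1.0
        significant = p < alpha
    else:
        p = float(stats.ttest_rel(post, pre, alternative="greater").pvalue)
        significant = p < alpha

    # first-spike latency per responsive pulse (post-artifact window)
    latencies = []
    for t0 in p_on:
        i = np.searchsorted(times, t0 + artifact_window)
        if i < len(times) and times[i] - t0 <= latency_window:
            latencies.append(times[i] - t0)
    latency = float(np.median(latencies)) if latencies else np.nan
    return bool(significant), latency


def split_waveforms(
    spikes: SpikeTrain,
    protocol: LaserProtocol,
    latency_window: float = LATENCY_WINDOW,
    artifact_window: float = ARTIFACT_WINDOW,
) -> UnitWaveforms:
    """Mean evoked (within the post-pulse latency window) and baseline waveforms."""
    if spikes.waveforms is None:
        raise ValueError("spike train carries no waveform snippets")
    times = spikes.spike_times
    j = np.searchsorted(protocol.pulse_times, times, side="right") - 1
    dt = np.where(j >= 0, times - protocol.pulse_times[np.clip(j, 0, None)], np.inf)
    artifact = dt < artifact_window
    evoked = (dt >= artifact_window) & (dt <= latency_window)
    baseline = ~evoked & ~artifact
    ev = spikes.waveforms[evoked]
    bl = spikes.waveforms[baseline]
    return UnitWaveforms(
        baseline_mean_waveform=bl.mean(axis=0) if len(bl) else np.array([]),
        evoked_mean_waveform=ev.mean(axis=0) if len(ev) else None,
        n_evoked=int(evoked.sum()),
    )


def waveform_criteria(waveforms: UnitWaveforms) -> tuple[float, float]:
    """Criteria 2 and 3: waveform correlation and voltage-minimum ratio.

    ``min_ratio`` is symmetric (max of the two ratios of |voltage minimum|,
    always >= 1) so the "< 2" cutoff is direction independent.  Undefined
    (NaN, NaN) with fewer than 10 evoked spikes.
    """
    if waveforms.evoked_mean_waveform is None or waveforms.n_evoked < MIN_EVOKED_SPIKES:
        return np.nan, np.nan
    b = np.asarray(waveforms.baseline_mean_waveform, dtype=float)
    e = np.asarray(waveforms.evoked_mean_waveform, dtype=float)
    if b.shape != e.shape:
        raise ValueError("waveform sample counts differ")
    r = float(stats.pearsonr(b, e).statistic)
    mb, me = abs(float(b.min())), abs(float(e.min()))
    if mb == 0 or me == 0:
        ratio = np.inf
    else:
        ratio = max(me / mb, mb / me)
    return r, ratio


def classify_unit(
    spikes: SpikeTrain,
    protocol: LaserProtocol,
    genotype: str = "",
    waveforms: Optional[UnitWaveforms] = None,
    test: str = "ttest",
) -> TagResult:
    """Apply all three tagging criteria; label D1/D2 from the session genotype."""
    latency_significant, latency = evoked_response_test(
        spikes, protocol, artifact_window=protocol.artifact_window, test=test
    )
    if waveforms is None:
        waveforms = split_waveforms(
            spikes, protocol, artifact_window=protocol.artifact_window
        )
    r, ratio = waveform_criteria(waveforms)
    tagged = bool(
        latency_significant
        and np.isfinite(r)
        and r > WAVEFORM_R_CUTOFF
        and np.isfinite(ratio)
        and ratio < AMPLITUDE_RATIO_CUTOFF
    )
    genotype = genotype.lower()
    if tagged and genotype.startswith("d1"):
        label = "D1"
    elif tagged and (genotype.startswith("a2a") or genotype.startswith("d2")):
        label = "D2"
    else:
        label = "untagged"
    return TagResult(
        unit_id=spikes.unit_id,
        latency_significant=latency_significant,
        first_spike_latency=latency,
        waveform_r=r,
        min_ratio=ratio,
        tagged=tagged,
        label=label,
    )
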