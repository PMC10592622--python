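"""Start/stop and speed coding of whole-body locomotion.

Start/stop coding compares each unit's mean rate in a [-5, -1] s baseline
window against a +/-0.5 s event window around motion-bout starts or stops
(paired t-test across events, p < 0.05).  The modulation index normalizes
rates by the baseline mean, bins the event window at 20 ms, and reports
|max normalized event rate - 1|.  Speed coding bins whole-session body
speed at 10 mm/s, correlates mean rate with bin-center speed, and tests the
absolute Pearson r against 100 bin-label shuffles.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .bouts import MotionBout
from .types import SpikeTrain

__all__ = [
    "StartStopResult",
    "SpeedTuning",
    "start_stop_test",
    "modulation_index",
    "speed_coding",
    "coding_categories",
]

BASELINE_WINDOW = (-5.0, -1.0)
EVENT_WINDOW = (-0.5, 0.5)
EVENT_BIN = 0.020
SPEED_BIN = 10.0


@dataclass
class StartStopResult:
    unit_id: str
    event: str  # "start" or "stop"
    baseline_rate: float
    event_rate: float
    p_value: float
    significant: bool
    modulation_index: float
    n_events: int


@dataclass
class SpeedTuning:
    unit_id: str
    speed_bin_edges: np.ndarray
    rate_per_bin: np.ndarray
    occupancy_s: np.ndarray
    score: float
    p_value: float
    significant: bool


def _event_times(bouts: list[MotionBout], event: str) -> np.ndarray:
    if event not in ("start", "stop"):
        raise ValueError("event must be 'start' or 'stop'")
    return np.array([b.start if event == "start" else b.stop for b in bouts])


def _usable_events(
    events: np.ndarray, session_end: float
) -> np.ndarray:
    """Events whose baseline and event windows fall fully inside the session."""
    lo = events + BASELINE_WINDOW[0]
    hi = events + EVENT_WINDOW[1]
    return events[(lo >= 0.0) & (hi <= session_end)]


def _window_rates(
    times: np.ndarray, events: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    dur = window[1] - window[0]
    lo = np.searchsorted(times, events + window[0])
    hi = np.searchsorted(times, events + window[1])
    return (hi - lo) / dur


def start_stop_test(
    spikes: SpikeTrain,
    bouts: list[MotionBout],
    event: str,
    alpha: float = 0.05,
) -> StartStopResult:
    """Paired t-test of event-window vs baseline-window firing across bouts."""
    times = spikes.spike_times[spikes.spike_times < spikes.analysis_end]
    events = _usable_events(_event_times(bouts, event), spikes.analysis_end)
    if len(events) < 2:
        return StartStopResult(
            spikes.unit_id, event, np.nan, np.nan, np.nan, False, np.nan, len(events)
        )
    base = _window_rates(times, events, BASELINE_WINDOW)
    ev = _window_rates(times, events, EVENT_WINDOW)
    if np.allclose(base, ev):
        p = 1.0
    else:
        p = float(stats.ttest_rel(ev, base).pvalue)
    mi = modulation_index(spikes, bouts, event)
    return StartStopResult(
        unit_id=spikes.unit_id,
        event=event,
        baseline_rate=float(np.mean(base)),
        event_rate=float(np.mean(ev)),
        p_value=p,
        significant=bool(p < alpha),
        modulation_index=mi,
        n_events=len(events),
    )


def modulation_index(
    spikes: SpikeTrain, bouts: list[MotionBout], event: str
) -> float:
    """|FR_event - FR_baseline| / FR_baseline on baseline-normalized rates.

    Rates are normalized so the baseline-window mean is ~1; the event window
    is binned at 20 ms, FR_event is the maximum bin of the event-aligned
    average, and the index reports the magnitude of its deviation from
    baseline (capturing both excitation and uniform suppression).  Undefined
    (NaN) when the baseline rate is zero or no events are usable.
    """
    times = spikes.spike_times[spikes.spike_times < spikes.analysis_end]
    events = _usable_events(_event_times(bouts, event), spikes.analysis_end)
    if len(events) == 0:
        return np.nan
    base = _window_rates(times, events, BASELINE_WINDOW)
    fr_baseline = float(np.mean(base))
    if fr_baseline <= 0:
        return np.nan
    edges = np.arange(EVENT_WINDOW[0], EVENT_WINDOW[1] + EVENT_BIN / 2, EVENT_BIN)
    peth = np.zeros(len(edges) - 1)
    for e in events:
        rel = times[(times >= e + EVENT_WINDOW[0]) & (times < e + EVENT_WINDOW[1])] - e
        peth += np.histogram(rel, bins=edges)[0]
    peth = peth / (len(events) * EVENT_BIN)  # spikes/s, event-aligned average
    fr_event = float(np.max(peth / fr_baseline))
    return abs(fr_event - 1.0)


def speed_coding(
    spikes: SpikeTrain,
    speed: np.ndarray,
    frame_rate: float,
    n_iter: int = 100,
    min_occupancy_s: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SpeedTuning:
    """Speed-coding score: |Pearson r| between binned rate and speed.

    Speed is binned at 10 mm/s over the whole session (up to the first laser
    pulse); the mean rate in each bin is occupancy-normalized from frame
    counts.  Bins occupied for less than ``min_occupancy_s`` are excluded.
    Significance: the real |r| must exceed more than 95% of ``n_iter``
    recomputations with the rate values shuffled across bins.
    """
    rng = rng or np.random.default_rng(seed)
    n_frames = int(spikes.analysis_end * frame_rate)
    speed = np.asarray(speed, dtype=float)[:n_frames]
    times = spikes.spike_times[spikes.spike_times < len(speed) / frame_rate]
    bins = np.floor(speed / SPEED_BIN).astype(np.int64)
    n_bins = int(bins.max()) + 1
    occupancy = np.bincount(bins, minlength=n_bins) / frame_rate
    idx = np.floor(times * frame_rate).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < len(speed))]
    counts = np.bincount(bins[idx], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = counts / occupancy
    centers = (np.arange(n_bins) + 0.5) * SPEED_BIN
    ok = occupancy >= min_occupancy_s
    edges = np.arange(n_bins + 1) * SPEED_BIN
    if ok.sum() < 3:
        return SpeedTuning(
            spikes.unit_id, edges, rate, occupancy, np.nan, np.nan, False
        )
    x, y = centers[ok], rate[ok]
    if np.std(y) == 0:
        score, p, sig = 0.0, 1.0, False
    else:
        score = abs(float(stats.pearsonr(x, y).statistic))
        shuf = np.empty(n_iter)
        for i in range(n_iter):
            yp = rng.permutation(y)
            shuf[i] = (
                abs(float(stats.pearsonr(x, yp).statistic)) if np.std(yp) > 0 else 0.0
            )
        sig = bool(np.sum(score > shuf) > 0.95 * n_iter)
        p = float(np.mean(shuf >= score))
    return SpeedTuning(
        unit_id=spikes.unit_id,
        speed_bin_edges=edges,
        rate_per_bin=rate,
        occupancy_s=occupancy,
        score=score,
        p_value=p,
        significant=sig,
    )


def coding_categories(
    phase_sig: bool, speed_sig: bool, start_sig: bool, stop_sig: bool
) -> set[str]:
    """Venn-category membership of one unit (phase / speed / start-stop)."""
    cats = set()
    if phase_sig:
        cats.add("phase")
    if speed_sig:
        cats.add("speed")
    if start_sig or stop_sig:
        cats.add("startstop")
    return cats
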