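"""Shared seeded constructions for the analysis drivers."""
from pathlib import Path

import numpy as np

from spikegait import kinematics as kin
from spikegait import synth
from spikegait.types import LIMBS

RESULTS = Path(__file__).resolve().parent.parent / "results"


def walking_session(seed: int = 2, duration: float = 310.0):
    """~250 s of lateral-sequence walking (about 600 strides per limb)."""
    schedule = [(5.0 + 30.0 * i, 30.0 + 30.0 * i, 150.0) for i in range(10)]
    params = synth.GaitGenParams(
        bout_schedule=schedule, session_duration=duration, seed=seed
    )
    track = synth.generate_pose_track(params)
    return track, kin.segment_strides(track)


def unit_cohort(track, table, kappa: float, n_units: int, seed0: int, base_rate=8.0):
    """Phase-coupled units with preferred phases spread over the cycle."""
    units = []
    for u in range(n_units):
        params = synth.SpikeGenParams(
            base_rate=base_rate,
            phase_kappa=kappa,
            preferred_phase=float((37 * u) % 360),
            coupled_limb=LIMBS[u % 4],
            speed_gain=0.01 if u % 3 == 0 else 0.0,
            start_transient_amp=2.0 if u % 4 == 0 else 0.0,
            seed=seed0 + u,
        )
        units.append(
            synth.generate_phase_locked_spikes(track, table, params, unit_id=f"u{seed0 + u}")
        )
    return units
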