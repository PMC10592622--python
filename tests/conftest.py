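import numpy as np
import pytest

from spikegait import kinematics as kin
from spikegait import synth
from spikegait.types import WalkingBout


@pytest.fixture(scope="session")
def noiseless_track():
    """One 10 s walking bout at 2.5 Hz with no jitter or tracking noise."""
    params = synth.GaitGenParams(
        bout_schedule=[(5.0, 15.0, 150.0)],
        session_duration=20.0,
        timing_jitter_sd=0.0,
        position_noise_sd=0.0,
        seed=1,
    )
    return synth.generate_pose_track(params)


@pytest.fixture(scope="session")
def walking_track():
    """Realistic ~250 s of walking (about 600 strides per limb)."""
    schedule = [(5.0 + 30.0 * i, 30.0 + 30.0 * i, 150.0) for i in range(10)]
    params = synth.GaitGenParams(
        bout_schedule=schedule, session_duration=310.0, seed=2
    )
    return synth.generate_pose_track(params)


@pytest.fixture(scope="session")
def walking_strides(walking_track):
    return kin.segment_strides(walking_track)


@pytest.fixture(scope="session")
def noiseless_strides(noiseless_track):
    return kin.segment_strides(noiseless_track)


@pytest.fixture
def single_bout():
    return [WalkingBout(5.0, 15.0, bout_id=0)]
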