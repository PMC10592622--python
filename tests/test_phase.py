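"""Phase tuning, the resultant vector, and the jitter null."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0, i1

from spikegait import phase as ph
from spikegait import synth
from spikegait.types import LIMBS, SpikeTrain

FR = 80.0


def _uniform_phase(n_cycles=200, frames_per_cycle=24):
    """Phase series with exactly uniform bin occupancy."""
    one = (np.arange(frames_per_cycle) + 0.5) / frames_per_cycle * 360.0
    return np.tile(one, n_cycles)


def _spikes_at_frames(idx):
    return np.asarray(idx) / FR + 0.5 / FR


# ------------------------------------------------------------ rate by phase
def test_rate_concentrates_in_occupied_bin():
    phase = _uniform_phase()
    idx = np.flatnonzero((phase >= 0) & (phase < 15.0))[:50]
    tuning = ph.rate_by_phase(_spikes_at_frames(idx), phase, FR)
    assert tuning.rate_per_bin[0] > 0
    assert np.all(tuning.rate_per_bin[1:] == 0)


def test_rate_occupancy_normalization_halves():
    # doubling bin occupancy at constant spike count halves the rate
    phase = _uniform_phase(100)
    extra = np.full(2400, 7.0)  # extra frames in bin 0, no extra spikes
    idx = np.flatnonzero((phase >= 0) & (phase < 15.0))
    spikes = _spikes_at_frames(idx)
    r1 = ph.rate_by_phase(spikes, phase, FR).rate_per_bin[0]
    r2 = ph.rate_by_phase(spikes, np.r_[phase, extra], FR).rate_per_bin[0]
    occ1 = (phase < 15.0).sum()
    assert r2 == pytest.approx(r1 * occ1 / (occ1 + len(extra)))


def test_no_defined_phase_raises():
    with pytest.raises(ValueError):
        ph.rate_by_phase(np.array([1.0]), np.full(100, np.nan), FR)


# -------------------------------------------------------------- mean vector
def test_mean_vector_flat_and_concentrated():
    flat = np.full(24, 5.0)
    L, _ = ph.mean_vector(flat)
    assert L == pytest.approx(0.0, abs=1e-12)
    conc = np.zeros(24)
    conc[4] = 10.0
    L, A = ph.mean_vector(conc)
    assert L == pytest.approx(1.0)
    assert A == pytest.approx(ph.BIN_CENTERS_DEG[4])


def test_mean_vector_von_mises_profile_matches_bessel_ratio():
    """Binned von Mises rates give a resultant within 0.01 of I1/I0."""
    for kappa in (0.5, 1.0, 2.0):
        theta = np.deg2rad(ph.BIN_CENTERS_DEG - 120.0)
        rates = np.exp(kappa * np.cos(theta))
        L, A = ph.mean_vector(rates)
        assert L == pytest.approx(i1(kappa) / i0(kappa), abs=0.01)
        assert A == pytest.approx(120.0, abs=1e-6)


@settings(deadline=None, max_examples=25)
@given(delta=st.floats(min_value=0.0, max_value=360.0))
def test_mean_vector_rotation_equivariance(delta):
    """Rotating every phase rotates the angle and preserves the length."""
    rng = np.random.default_rng(9)
    phase = rng.uniform(0, 360, 4000)
    spikes = rng.choice(len(phase), 400, replace=False)
    t1 = ph.rate_by_phase(_spikes_at_frames(spikes), phase, FR)
    t2 = ph.rate_by_phase(_spikes_at_frames(spikes), (phase + delta) % 360.0, FR)
    L1, A1 = ph.mean_vector(t1)
    L2, A2 = ph.mean_vector(t2)
    # binning quantizes the rotation to the 15-degree grid
    assert L2 == pytest.approx(L1, abs=0.05)
    d = (A2 - A1 - delta + 180.0) % 360.0 - 180.0
    assert abs(d) <= ph.BIN_WIDTH_DEG


def test_binned_vector_matches_per_spike_resultant_under_uniform_occupancy():
    rng = np.random.default_rng(4)
    phase = _uniform_phase(500)
    # spikes drawn with von Mises-weighted probability per frame
    w = np.exp(1.0 * np.cos(np.deg2rad(phase - 90.0)))
    idx = rng.choice(len(phase), 3000, replace=True, p=w / w.sum())
    spikes = _spikes_at_frames(idx)
    L_binned, _ = ph.mean_vector(ph.rate_by_phase(spikes, phase, FR))
    z = np.mean(np.exp(1j * np.deg2rad(phase[idx])))
    assert L_binned == pytest.approx(abs(z), abs=0.01)


# -------------------------------------------------------------- jitter test
def test_jitter_test_detects_locked_unit(walking_track, walking_strides):
    params = synth.SpikeGenParams(
        base_rate=8.0, phase_kappa=2.0, preferred_phase=45.0, coupled_limb="LF", seed=5
    )
    spikes = synth.generate_phase_locked_spikes(walking_track, walking_strides, params)
    p, sig, real = ph.jitter_test(
        spikes, walking_strides.phase["LF"], FR, seed=1
    )
    assert sig and p < 0.05
    assert real > 0.3


def test_jitter_test_zero_spikes_not_significant():
    phase = _uniform_phase()
    p, sig, real = ph.jitter_test(np.array([]), phase, FR, seed=0)
    assert not sig and p == 1.0


# ------------------------------------------------------- outliers & classes
def test_exclude_outliers_boundary():
    import pandas as pd

    df = pd.DataFrame(
        {
            "unit_id": ["a", "a", "b", "c"],
            "limb": ["LF", "LR", "LF", "LF"],
            "vector_length": [0.95, 0.1, 0.89, 0.5],
        }
    )
    kept, excluded = ph.exclude_outliers(df)
    assert excluded == ["a"]
    assert set(kept["unit_id"]) == {"b", "c"}
    kept2, excluded2 = ph.exclude_outliers(df.iloc[0:0])
    assert excluded2 == [] and len(kept2) == 0


@pytest.mark.parametrize(
    "sig_limbs,expected",
    [
        ([], "none"),
        (["LR"], "single"),
        (["LR", "RF"], "pair-diagonal"),
        (["LF", "RR"], "pair-diagonal"),
        (["LR", "LF"], "pair-other"),
        (["LR", "LF", "RF"], "multi"),
    ],
)
def test_limb_coupling_classes(sig_limbs, expected):
    tunings = {}
    for limb in LIMBS:
        t = ph.PhaseTuning(
            unit_id="u",
            limb=limb,
            bin_edges=np.arange(25) * 15.0,
            rate_per_bin=np.ones(24),
            occupancy_frames=np.ones(24, dtype=int),
            n_spikes=10,
            vector_length=0.3,
            significant=limb in sig_limbs,
        )
        tunings[limb] = t
    assert ph.limb_coupling_profile(tunings)["coupling_class"] == expected


def test_limb_coupling_requires_all_limbs():
    with pytest.raises(ValueError):
        ph.limb_coupling_profile({})


# ---------------------------------------------------------------- recovery
def test_vector_length_monotone_in_kappa(walking_track, walking_strides):
    lengths = []
    for kappa in (0.0, 0.5, 1.0, 2.0):
        Ls = []
        for s in range(3):
            params = synth.SpikeGenParams(
                base_rate=10.0,
                phase_kappa=kappa,
                preferred_phase=90.0,
                coupled_limb="LF",
                seed=50 + s,
            )
            spikes = synth.generate_phase_locked_spikes(
                walking_track, walking_strides, params
            )
            t = ph.rate_by_phase(spikes, walking_strides.phase["LF"], FR)
            Ls.append(ph.mean_vector(t)[0])
        lengths.append(np.mean(Ls))
    assert np.all(np.diff(lengths) > 0)
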