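"""Monte-Carlo block tests: pulse envelope, sampling discipline, bookkeeping."""

import math

import numpy as np
import pytest

from treemd import constants as C
from treemd.mc_events import (AtomicEvent, PulseConfig, TimestepTooLargeError,
                              apply_event, channel_probabilities,
                              gaussian_flux, mc_block, sample_events)
from treemd.particles import SystemState, total_charge
from treemd.rates import default_tables

TABLES = default_tables()
O = TABLES.element_index("O")
N_ORB = TABLES.capacity.shape[1]


def oxygen_state(n=1, occ_row=None, time=0.0):
    occ = np.tile(TABLES.neutral_occ[O] if occ_row is None
                  else np.asarray(occ_row), (n, 1))
    rng = np.random.default_rng(0)
    return SystemState(
        elem=np.full(n, O), apos=rng.random((n, 3)) * 50,
        avel=np.zeros((n, 3)), occ=occ.astype(np.int64),
        epos=np.empty((0, 3)), evel=np.empty((0, 3)),
        time=time, tables=TABLES)


# -- pulse --------------------------------------------------------------------

def test_flux_normalization():
    pulse = PulseConfig()
    sigma = pulse.fwhm_fs / (2 * math.sqrt(2 * math.log(2)))
    t = np.linspace(pulse.t0_fs - 6 * sigma, pulse.t0_fs + 6 * sigma, 200_001)
    integral = np.trapezoid(gaussian_flux(t, pulse), t)
    assert abs(integral - pulse.fluence_per_um2) / pulse.fluence_per_um2 <= 1e-6


def test_flux_half_maximum_at_half_fwhm():
    pulse = PulseConfig()
    peak = gaussian_flux(pulse.t0_fs, pulse)
    for t in (pulse.t0_fs - 7.5, pulse.t0_fs + 7.5):
        assert np.isclose(gaussian_flux(t, pulse), 0.5 * peak, rtol=1e-12)


def test_flux_peak_closed_form():
    pulse = PulseConfig()
    expected = 3.5e12 * 2 * math.sqrt(math.log(2) / math.pi) / 15.0
    assert np.isclose(gaussian_flux(0.0, pulse), expected, rtol=1e-12)


# -- sampling -----------------------------------------------------------------

def test_zero_fluence_no_events():
    state = oxygen_state(50)
    pulse = PulseConfig(fluence_per_um2=0.0)
    rng = np.random.default_rng(1)
    for _ in range(20):
        assert sample_events(state, TABLES, pulse, C.AS_ATU, rng) == []


def test_empty_orbital_channel_excluded():
    # fully stripped O: no occupied orbital -> no photoionization channel
    state = oxygen_state(10, occ_row=np.zeros(N_ORB))
    probs = channel_probabilities(state, TABLES, PulseConfig(), C.AS_ATU)
    assert np.all(probs[:, :N_ORB] == 0)


def test_event_frequency_matches_binomial():
    # 10^5 independent single-draw trials in one call (one atom each)
    n = 100_000
    state = oxygen_state(n)
    pulse = PulseConfig()
    probs = channel_probabilities(state, TABLES, pulse, C.AS_ATU)
    p = probs[0].sum()
    assert 0 < p < 0.1
    events = sample_events(state, TABLES, pulse, C.AS_ATU,
                           np.random.default_rng(42))
    se = math.sqrt(n * p * (1 - p))
    assert abs(len(events) - n * p) <= 3 * se


def test_one_draw_per_atom_in_index_order():
    n = 1000
    state = oxygen_state(n)
    pulse = PulseConfig(fluence_per_um2=3.5e14)   # higher rate, more events
    with pytest.warns(UserWarning):               # p > 0.1 advisory
        ev1 = sample_events(state, TABLES, pulse, C.AS_ATU,
                            np.random.default_rng(7))
    with pytest.warns(UserWarning):
        ev2 = sample_events(state, TABLES, pulse, C.AS_ATU,
                            np.random.default_rng(7))
    assert ev1 == ev2
    assert [e.atom for e in ev1] == sorted(e.atom for e in ev1)
    assert len({e.atom for e in ev1}) == len(ev1)     # at most one per atom


def test_timestep_too_large_raises():
    state = oxygen_state(5)
    pulse = PulseConfig(fluence_per_um2=1e19)
    with pytest.raises(TimestepTooLargeError):
        sample_events(state, TABLES, pulse, C.AS_ATU,
                      np.random.default_rng(0))


# -- event application --------------------------------------------------------

def test_photoionization_bookkeeping():
    state = oxygen_state(1)
    pulse = PulseConfig()
    rng = np.random.default_rng(3)
    apply_event(state, AtomicEvent("photo", 0, 0, 0), pulse, TABLES, rng)
    assert state.occ[0, 0] == 1
    assert state.charge_state[0] == 1
    assert state.n_electrons == 1
    ke = 0.5 * float(state.evel[0] @ state.evel[0]) * C.HARTREE_EV
    assert np.isclose(ke, 7120.0 - 543.1, rtol=1e-12)
    assert total_charge(state) == 0


def test_auger_bookkeeping():
    state = oxygen_state(1, occ_row=[1, 2, 4])    # 1s core hole (charge +1)
    q0 = total_charge(state)
    rng = np.random.default_rng(4)
    apply_event(state, AtomicEvent("auger", 0, 0, 0), PulseConfig(), TABLES, rng)
    assert state.occ[0, 0] == 2                   # hole filled
    assert state.occ[0, 1:].sum() == 4            # two outer electrons gone
    assert state.n_electrons == 1
    ke = 0.5 * float(state.evel[0] @ state.evel[0]) * C.HARTREE_EV
    assert np.isclose(ke, 500.0, rtol=1e-12)
    assert total_charge(state) == q0


def test_fluorescence_conserves_charge_and_electrons():
    state = oxygen_state(1, occ_row=[1, 2, 4])
    q0 = total_charge(state)
    apply_event(state, AtomicEvent("fluor", 0, 0, 0), PulseConfig(), TABLES,
                np.random.default_rng(5))
    assert state.occ[0, 0] == 2 and state.occ[0, 1:].sum() == 5
    assert state.n_electrons == 0
    assert total_charge(state) == q0


def test_mc_block_charge_conservation_and_determinism():
    pulse = PulseConfig(fluence_per_um2=3.5e14)
    digests = []
    for _ in range(2):
        state = oxygen_state(2000)
        q0 = total_charge(state)
        with pytest.warns(UserWarning):           # p > 0.1 advisory
            ev = mc_block(state, TABLES, pulse, C.AS_ATU,
                          np.random.default_rng(11), seed=11)
        assert total_charge(state) == q0
        assert state.n_electrons == sum(e.kind != "fluor" for e in ev)
        digests.append(state.digest())
    assert digests[0] == digests[1]
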