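import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crtsim import (
    ConductanceState,
    IntegratorConfig,
    ReceptorSpec,
    SynapseKinetics,
    gap_current,
    nmda_gate,
    receptor_current,
    step_sd_conductance,
)
from crtsim.config import TAU_TABLE

CFG = IntegratorConfig()


def _single_spike_waveform(kind, n_ms=None):
    kin = SynapseKinetics.from_table(kind)
    tau_f = TAU_TABLE[kind][1]
    n = round((n_ms or 5 * tau_f) / CFG.step_h)
    state = ConductanceState.zeros(1)
    g = np.empty(n)
    for k in range(n):
        spikes = np.array([k == 0])
        state = step_sd_conductance(state, spikes, kin, CFG)
        g[k] = state.g[0]
    return g


def test_no_spikes_zero_stays_zero():
    kin = SynapseKinetics.from_table("fast")
    state = ConductanceState.zeros(3)
    for _ in range(100):
        state = step_sd_conductance(state, np.zeros(3, bool), kin, CFG)
    assert np.all(state.q == 0) and np.all(state.g == 0)


@pytest.mark.parametrize("kind", list(TAU_TABLE))
def test_single_spike_psp_shape(kind):
    tau_r, tau_f = TAU_TABLE[kind]
    g = _single_spike_waveform(kind)
    peak_idx = int(np.argmax(g))
    peak_t = (peak_idx + 1) * CFG.step_h
    assert 0 < g[peak_idx] <= 1
    assert tau_r < peak_t < tau_f
    assert g[-1] < 0.05 * g[peak_idx]  # decays away


@pytest.mark.parametrize("kind", list(TAU_TABLE))
def test_sustained_drive_saturates_below_one(kind):
    kin = SynapseKinetics.from_table(kind)
    tau_f = TAU_TABLE[kind][1]
    cfg = IntegratorConfig(spike_pulse_duration=1e9)  # K held at 1
    state = ConductanceState.zeros(1)
    state = step_sd_conductance(state, np.array([True]), kin, cfg)
    for _ in range(round(20 * tau_f / cfg.step_h)):
        state = step_sd_conductance(state, np.array([False]), kin, cfg)
    assert 0 < state.q[0] <= 1
    assert 0 < state.g[0] <= 1


def test_pv_kinetics_faster_than_fast_ampa():
    g_pv = _single_spike_waveform("pv_fast", n_ms=50)
    g_fast = _single_spike_waveform("fast", n_ms=50)

    def decay_time(g):
        peak = np.argmax(g)
        below = np.nonzero(g[peak:] < 0.1 * g[peak])[0]
        return (peak + below[0]) * CFG.step_h

    assert decay_time(g_pv) < decay_time(g_fast) / 5


@settings(derandomize=True, deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_conductances_bounded_for_random_trains(seed):
    rng = np.random.RandomState(seed)
    kin = SynapseKinetics.from_table("fast")
    state = ConductanceState.zeros(4)
    for _ in range(400):
        state = step_sd_conductance(state, rng.random_sample(4) < 0.05, kin, CFG)
        assert np.all((state.q >= 0) & (state.q <= 1))
        assert np.all((state.g >= 0) & (state.g <= 1))


def test_invalid_kinetics_rejected():
    with pytest.raises(ValueError):
        SynapseKinetics(10.0, 2.0)


def test_nmda_gate_limits_and_value():
    assert nmda_gate(-500.0) == pytest.approx(0.0, abs=1e-12)
    assert nmda_gate(0.0) == pytest.approx(1.0 / 1.4202)
    v = np.linspace(-90, 30, 500)
    assert np.all(np.diff(nmda_gate(v)) > 0)


@pytest.mark.parametrize("kind", ["ampa", "nmda", "gaba_a", "gaba_b"])
def test_zero_conductance_gives_zero_current(kind):
    w = np.ones((3, 2))
    i = receptor_current(ReceptorSpec(kind), np.full(3, -65.0), w, np.zeros(2))
    assert np.all(i == 0)


def test_currents_vanish_at_reversal_and_flip_sign():
    w = np.ones((1, 1))
    g = np.array([0.5])
    for kind, rev in (("gaba_a", -70.0), ("gaba_b", -90.0), ("ampa", 0.0)):
        spec = ReceptorSpec(kind)
        assert receptor_current(spec, np.array([rev]), w, g)[0] == 0.0
        below = receptor_current(spec, np.array([rev - 5]), w, g)[0]
        above = receptor_current(spec, np.array([rev + 5]), w, g)[0]
        assert below > 0 > above


def test_ampa_depolarizes_at_rest():
    i = receptor_current(
        ReceptorSpec("ampa"), np.array([-65.0]), np.ones((1, 1)), np.array([0.2])
    )
    assert i[0] > 0


def test_receptor_shape_mismatch_raises():
    with pytest.raises(ValueError):
        receptor_current(
            ReceptorSpec("ampa"), np.zeros(3), np.ones((2, 2)), np.zeros(2)
        )


def test_gap_current_arithmetic_and_conservation():
    w = np.array([[0.0, 0.3], [0.3, 0.0]])
    i = gap_current(w, np.array([0.0, 10.0]))
    assert i == pytest.approx([3.0, -3.0])
    assert gap_current(w, np.array([5.0, 5.0])) == pytest.approx([0.0, 0.0])
    rng = np.random.default_rng(0)
    n = 6
    w = rng.random((n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    assert gap_current(w, rng.normal(size=n)).sum() == pytest.approx(0.0, abs=1e-12)


def test_gap_asymmetric_matrix_rejected():
    w = np.array([[0.0, 0.3], [0.1, 0.0]])
    with pytest.raises(ValueError):
        gap_current(w, np.zeros(2))
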