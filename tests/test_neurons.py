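import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crtsim import (
    FS_PARAMS,
    IntegratorConfig,
    IzhikevichParams,
    PopulationState,
    RS_PARAMS,
    init_population,
    step_izhikevich,
)

CFG = IntegratorConfig()


def _scalar_params(nominal):
    return IzhikevichParams(*(np.array([x]) for x in nominal))


def test_published_parameter_sets():
    assert RS_PARAMS == (0.02, 0.2, -65.0, 0.0)
    assert FS_PARAMS == (0.1, 0.2, -65.0, 2.0)


def test_zero_jitter_gives_identical_neurons():
    params, state = init_population(7, RS_PARAMS, jitter_frac=0.0, seed=0)
    for name, nominal in zip("abcd", RS_PARAMS):
        assert np.all(getattr(params, name) == nominal)
    assert np.all(state.v == -65.0)
    assert np.all(state.u == 0.2 * -65.0)
    assert not state.spiked.any()


@pytest.mark.parametrize("seed", [0, 17, 991])
def test_jitter_stays_within_five_percent(seed):
    params, state = init_population(200, RS_PARAMS, jitter_frac=0.05, seed=seed)
    for name, nominal in zip("abcd", RS_PARAMS):
        vals = getattr(params, name)
        if nominal == 0.0:
            assert np.all(vals == 0.0)
        else:
            ratio = vals / nominal
            assert np.all((ratio >= 0.95) & (ratio <= 1.05))
    assert np.all(state.u == params.b * state.v)


def test_seeded_reproducibility():
    a, sa = init_population(50, FS_PARAMS, 0.05, seed=42)
    b, sb = init_population(50, FS_PARAMS, 0.05, seed=42)
    assert np.array_equal(a.a, b.a) and np.array_equal(sa.v, sb.v)


def test_invalid_arguments_raise():
    with pytest.raises(ValueError):
        init_population(0, RS_PARAMS, 0.05, 0)
    with pytest.raises(ValueError):
        init_population(3, RS_PARAMS, 1.0, 0)


def test_resting_fixed_point_is_stationary():
    # (v, u) = (-70, -14) solves 0.04 v^2 + 4.8 v + 140 = 0 with u = b v
    state = PopulationState(np.array([-70.0]), np.array([-14.0]), np.zeros(1, bool))
    params = _scalar_params(RS_PARAMS)
    for _ in range(1000):
        state = step_izhikevich(state, params, np.zeros(1), CFG)
    assert state.v[0] == pytest.approx(-70.0)
    assert state.u[0] == pytest.approx(-14.0)
    assert not state.spiked.any()


def test_after_spike_reset_applies_c_and_d():
    params = _scalar_params(FS_PARAMS)
    state = PopulationState(np.array([29.9]), np.array([0.0]), np.zeros(1, bool))
    state = step_izhikevich(state, params, np.array([100.0]), CFG)
    assert state.spiked[0]
    assert state.v[0] == -65.0
    # u was incremented by d on top of its Euler update
    assert state.u[0] > 1.9


def _tonic_spike_times(h, duration_ms=1000.0, current=10.0):
    cfg = IntegratorConfig(step_h=h, spike_pulse_duration=h)
    params = _scalar_params(RS_PARAMS)
    state = PopulationState(np.array([-70.0]), np.array([-14.0]), np.zeros(1, bool))
    times = []
    n = round(duration_ms / h)
    for k in range(n):
        state = step_izhikevich(state, params, np.array([current]), cfg)
        if state.spiked[0]:
            times.append((k + 1) * h)
    return np.array(times)


def test_tonic_spiking_is_regular_and_step_insensitive():
    t1 = _tonic_spike_times(0.025)
    t2 = _tonic_spike_times(0.0125)
    assert len(t1) > 5
    assert abs(len(t1) - len(t2)) / len(t2) < 0.05
    isis = np.diff(t1[20:])  # discard the adaptation transient
    assert np.std(isis) / np.mean(isis) < 0.05


def test_nonfinite_state_raises_numeric_failure():
    params = _scalar_params(RS_PARAMS)
    state = PopulationState(np.array([np.nan]), np.array([0.0]), np.zeros(1, bool))
    with pytest.raises(FloatingPointError):
        step_izhikevich(state, params, np.zeros(1), CFG)
    state = PopulationState(np.array([-65.0]), np.array([0.0]), np.zeros(1, bool))
    with pytest.raises(FloatingPointError):
        step_izhikevich(state, params, np.array([np.inf]), CFG)


def test_input_length_mismatch_raises():
    params, state = init_population(4, RS_PARAMS, 0.0, 0)
    with pytest.raises(ValueError):
        step_izhikevich(state, params, np.zeros(5), CFG)


@settings(derandomize=True, deadline=None, max_examples=50)
@given(
    v=st.lists(st.floats(-90, 29.99), min_size=1, max_size=8),
    current=st.floats(-200, 200),
)
def test_no_neuron_left_above_threshold(v, current):
    n = len(v)
    params, _ = init_population(n, RS_PARAMS, 0.0, 0)
    state = PopulationState(np.array(v), 0.2 * np.array(v), np.zeros(n, bool))
    out = step_izhikevich(state, params, np.full(n, current), CFG)
    assert np.all(out.v < params.spike_threshold)
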