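import numpy as np
import pytest

from crtsim import (
    IntegratorConfig,
    NetworkConfig,
    TaskSpec,
    build_connectome,
    build_network,
    compute_currents,
    gaussian_weights,
    mln_dendritic_input,
    run_trial,
    step_network,
)
from crtsim.perturbations import Modifiers

from reference_loop import ScalarReferenceNetwork

CFG = IntegratorConfig()
TOY = NetworkConfig(n_t=4, n_r=4, n_pv=4, n_cb=4, n_m=4, n_d=4)
SMALL = NetworkConfig(n_t=8, n_r=8, n_pv=8, n_cb=8, n_m=8, n_d=8)


def test_connectome_matches_parameter_table():
    conn = build_connectome(NetworkConfig())
    # aligned normalized positions: exp(0) = 1 times the table amplitude
    assert conn.w_d_t[39, 119] == pytest.approx(0.04)   # 120/120 == 40/40
    assert conn.w_t_m_p[119, 39] == pytest.approx(4.8)
    assert np.all(conn.w_r_t == 0.32)
    assert np.array_equal(conn.w_r_r_gap, conn.w_r_r_gap.T)
    assert np.all(np.diag(conn.w_r_r_gap) == 0)


def test_gaussian_rows_peak_aligned_and_decay():
    w = gaussian_weights(120, 40, 0.05, 1.0)
    for j in (0, 19, 39):
        row = w[j]
        peak = np.argmax(row)
        assert abs((peak + 1) / 120 - (j + 1) / 40) < 0.02
        assert np.all(np.diff(row[peak:]) <= 0)
        assert np.all(np.diff(row[: peak + 1]) >= 0)


def test_mln_dendritic_input_rectification():
    conn = build_connectome(NetworkConfig())
    v_m = np.full(120, -65.0)
    g_t = np.full(40, 0.1)
    base = mln_dendritic_input(v_m, g_t, np.zeros(40), conn)
    prox = (0.0 - v_m) * (conn.w_t_m_p @ g_t)
    dist = (0.0 - v_m) * (conn.w_t_m_d @ g_t)
    assert base == pytest.approx(prox + dist)
    # saturating CB drive wipes out the distal branch but not the proximal
    huge_cb = mln_dendritic_input(v_m, g_t, np.full(40, 50.0), conn)
    assert huge_cb == pytest.approx(prox)


def test_distal_footprint_wider_than_proximal():
    conn = build_connectome(NetworkConfig())
    g_t = np.zeros(40)
    g_t[19] = 1.0  # point thalamic source
    prox = conn.w_t_m_p @ g_t
    dist = conn.w_t_m_d @ g_t
    frac = lambda x: np.sum(x > 0.05 * x.max())
    assert frac(dist) > 3 * frac(prox)


def test_cb_and_d_receive_no_inhibition():
    params, state = build_network(SMALL, seed=0)
    rng = np.random.default_rng(5)
    for cond in state.cond.values():
        cond.g[:] = rng.random(cond.g.size)
    currents = compute_currents(state, params)
    assert np.all(currents["cb"] >= 0)
    assert np.all(currents["d"] >= 0)


def test_silent_network_stays_silent():
    params, state = build_network(SMALL, seed=0)
    total = 0
    for _ in range(round(100.0 / CFG.step_h)):
        state = step_network(state, params, np.zeros(8, bool), CFG)
        total += sum(int(state.pops[p].spiked.sum()) for p in state.pops)
    assert total == 0


def test_vectorized_step_matches_scalar_reference():
    """Spike-for-spike agreement with an independent loop-based
    implementation on a 4-neurons-per-group network over 100 ms."""
    params, state = build_network(TOY, seed=11)
    ref = ScalarReferenceNetwork(params, state, CFG)
    rng = np.random.RandomState(2)
    n_steps = round(100.0 / CFG.step_h)
    total = 0
    for _ in range(n_steps):
        ext = rng.random_sample(4) < 0.006  # ~240 sp/s afferents
        state = step_network(state, params, ext, CFG)
        ref.step(list(ext))
        for p in state.pops:
            assert np.array_equal(state.pops[p].spiked, np.array(ref.spiked[p]))
            total += int(state.pops[p].spiked.sum())
    assert total > 0  # the comparison exercised actual spiking


def test_engines_agree_spike_for_spike():
    task = TaskSpec.pursuit(duration=0.1)
    a = run_trial(task, seed=3, engine="numba")
    b = run_trial(task, seed=3, engine="numpy")
    for p in a.spikes:
        assert np.array_equal(a.spikes[p][0], b.spikes[p][0])
        assert np.array_equal(a.spikes[p][1], b.spikes[p][1])
    assert np.array_equal(a.eye, b.eye)
    assert np.allclose(a.mln_sum, b.mln_sum)


def test_trial_is_deterministic_per_seed():
    task = TaskSpec.pursuit(duration=0.2)
    a = run_trial(task, seed=9)
    b = run_trial(task, seed=9)
    assert np.array_equal(a.eye, b.eye)
    assert np.array_equal(a.mln_sum, b.mln_sum)
    assert np.array_equal(a.p_t, b.p_t)
    for p in a.spikes:
        assert np.array_equal(a.spikes[p][0], b.spikes[p][0])


def test_dstp_causally_isolated_until_cortex_fires():
    """With the plasticity scale zeroed (P_T pinned at 1), trajectories match
    the default network exactly until the slow cortical conductance first
    departs from zero."""
    params, s_on = build_network(SMALL, seed=0)
    s_off = s_on.copy()
    rng = np.random.RandomState(4)
    pinned = Modifiers(a_stp_scale=0.0)
    for _ in range(2000):
        ext = rng.random_sample(8) < 0.006
        s_on = step_network(s_on, params, ext, CFG)
        s_off = step_network(s_off, params, ext, CFG, pinned)
        if np.any(s_on.cond["d_xslow"].g > 0):
            break
        assert np.array_equal(s_on.pops["t"].v, s_off.pops["t"].v)
        assert np.all(s_off.p_t == 1.0)


def test_disinhibition_islands_during_converged_pursuit(trial_bank):
    rec = trial_bank("smooth_pursuit", seed=0)
    window = rec.p_t[1600:2400].mean(axis=0)  # 4-6 s
    assert window.min() < 0.3          # aligned loop strongly disinhibited
    assert window[:5].min() > 0.9      # distal loops keep full inhibition
    assert window[-5:].min() > 0.9


def _trn_pairwise_correlation(cfg, seed):
    rec = run_trial(TaskSpec.pursuit(duration=2.0), seed=seed, net_cfg=cfg)
    t, idx = rec.spikes["r"]
    bins = np.arange(0.0, 2.0001, 0.005)
    counts = np.stack([np.histogram(t[idx == i], bins=bins)[0] for i in range(40)])
    active = counts[counts.sum(axis=1) > 5]
    corr = np.corrcoef(active)
    return corr[np.triu_indices(len(active), 1)].mean()


def test_gap_junctions_promote_trn_synchrony():
    with_gap = np.mean([_trn_pairwise_correlation(NetworkConfig(), s) for s in (0, 1)])
    without = np.mean(
        [_trn_pairwise_correlation(NetworkConfig(a_r_r_gap=0.0), s) for s in (0, 1)]
    )
    assert with_gap > without
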