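import numpy as np
import pytest

from crtsim import (
    GazeState,
    IntegratorConfig,
    TaskSpec,
    motor_signals,
    run_trial,
    sample_input_spikes,
    stimulus_rates,
    target_position,
    update_gaze,
)

CFG = IntegratorConfig()


def test_pursuit_sinusoid_range_and_period():
    spec = TaskSpec.pursuit()
    t = np.linspace(0, 7, 14001)
    x = target_position(spec, t)
    assert x.min() == pytest.approx(11.0, abs=1e-6)
    assert x.max() == pytest.approx(30.0, abs=1e-6)
    assert np.allclose(x, target_position(spec, t + 1.0))


def test_fixation_target_constant():
    spec = TaskSpec.fixation()
    assert float(target_position(spec, 3.3)) == 10.0
    assert spec.distractor_pos == 25.0


def test_target_position_out_of_range_raises():
    with pytest.raises(ValueError):
        target_position(TaskSpec.pursuit(), 9.0)


def test_stimulus_rates_peak_floor_and_symmetry():
    spec = TaskSpec.pursuit()
    # target foveated: bump centered exactly on afferent 20
    rates = stimulus_rates(x_c=20.5, x_target=20.5, distractor=None, spec=spec)
    assert rates.max() == pytest.approx(250.0)
    assert int(np.argmax(rates)) == 19
    assert rates.min() == pytest.approx(30.0)
    peak = np.argmax(rates)
    assert rates[peak - 2] == pytest.approx(rates[peak + 2])
    assert np.all(rates <= 250.0)


def test_distractor_combines_by_maximum_under_ceiling():
    spec = TaskSpec.fixation()
    rates = stimulus_rates(10.0, 10.0, 25.0, spec)
    assert rates.max() == pytest.approx(250.0)
    assert np.all(rates <= 250.0)
    # two separate bumps: one at the fovea, one at retinal position 35
    assert rates[19] == pytest.approx(250.0)
    assert rates[34] == pytest.approx(250.0)
    assert rates[27] < 40.0


def test_poisson_sampling_statistics_and_determinism():
    rates = np.full(4000, 250.0)
    rng = np.random.RandomState(0)
    count = sum(
        sample_input_spikes(rates, CFG, rng).sum() for _ in range(100)
    )  # 400k Bernoullis at p = 0.00625
    expect = 4000 * 100 * 250 * CFG.step_h / 1000.0
    assert abs(count - expect) < 3 * np.sqrt(expect)
    a = sample_input_spikes(rates, CFG, np.random.RandomState(5))
    b = sample_input_spikes(rates, CFG, np.random.RandomState(5))
    assert np.array_equal(a, b)
    assert not sample_input_spikes(np.zeros(10), CFG, rng).any()


def test_poisson_rate_too_high_for_step_raises():
    with pytest.raises(ValueError):
        sample_input_spikes(np.array([1e8]), CFG, np.random.RandomState(0))


def test_motor_signals_symmetry_and_eccentric_weighting():
    assert motor_signals(np.zeros(120)) == (0.0, 0.0)
    # the printed 1-based ramps are offset by one index, so mirror-symmetric
    # activity balances to within one ramp increment (1/60), not exactly
    half = np.random.default_rng(3).random(60)
    l_sig, r_sig = motor_signals(np.concatenate([half, half[::-1]]))
    assert l_sig == pytest.approx(r_sig, rel=0.05)
    g = np.zeros(120)
    g[119] = 1.0
    l_sig, r_sig = motor_signals(g)
    assert (l_sig, r_sig) == (0.0, pytest.approx(0.025))


def test_update_gaze_integrates_and_clamps():
    assert update_gaze(GazeState(20.0), 0.1, 0.4).x_c == pytest.approx(20.3)
    assert update_gaze(GazeState(20.0), 0.2, 0.2).x_c == 20.0
    assert update_gaze(GazeState(36.0), 0.0, 5.0).x_c == 36.0
    assert update_gaze(GazeState(5.0), 5.0, 0.0).x_c == 5.0


def test_invalid_task_specs_rejected():
    with pytest.raises(ValueError):
        TaskSpec(kind="saccade")
    with pytest.raises(ValueError):
        TaskSpec.fixation(duration=1.0)  # distractor onset at 2 s is too late


def test_trial_record_traces_and_roundtrip(tmp_path):
    task = TaskSpec.pursuit(duration=0.5)
    rec = run_trial(task, seed=1)
    assert rec.time.size == int(0.5 * 400)
    assert rec.eye.size == rec.target.size == rec.mln_sum.size == rec.time.size
    assert rec.p_t.shape == (rec.time.size, 40)
    assert np.all(np.isfinite(rec.eye))
    assert np.all((rec.eye >= 5.0) & (rec.eye <= 36.0))
    for t_s, _ in rec.spikes.values():
        assert np.all(np.diff(t_s) >= 0)  # rasters sorted by time
    frame = rec.to_frame()
    assert list(frame.columns) == ["time_s", "eye", "target", "distractor", "mln_sum"]

    path = tmp_path / "trial.h5"
    rec.save(path)
    from crtsim import TrialRecord

    back = TrialRecord.load(path)
    assert np.array_equal(back.eye, rec.eye)
    assert np.array_equal(back.spikes["m"][0], rec.spikes["m"][0])
    assert back.seed == rec.seed
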