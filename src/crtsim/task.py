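"""Closed perception-action loop: stimulus field, gaze control, full trials.

The target (and optional distractor) is a near-Gaussian bump in the Poisson
rate of the 40 thalamic afferents, expressed in retinal coordinates: the
bump peaks where the afferent's retinal position matches the target's offset
from the current gaze direction, so a perfectly foveated target sits at the
center of the input map.  The middle cortical layer acts as a motor error
map: its left/right halves drive left/right gaze displacements through
rectified linear ramps, and the gaze state integrates their difference at
every step.  There is no prediction of target motion; tracking is purely
error-driven, which is what makes the pre-convergence alpha oscillation and
the post-convergence small residual jitter emerge.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd

from .config import IntegratorConfig, NetworkConfig
from .network import build_network, step_network, POPULATIONS
from .perturbations import PerturbationSpec, resolve_perturbation

__all__ = [
    "TaskSpec",
    "GazeState",
    "TrialRecord",
    "target_position",
    "stimulus_rates",
    "sample_input_spikes",
    "motor_signals",
    "motor_weights",
    "update_gaze",
    "run_trial",
]

GAZE_BOUNDS = (5.0, 36.0)
MOTOR_SLOPE = 0.025
GAZE_START = 20.5  # map center; trials begin with a nonzero retinal error


@dataclass(frozen=True)
class TaskSpec:
    """Behavioral task: smooth pursuit of a 1 Hz sinusoid, or fixation with
    an optional equal-amplitude distractor appearing at 2 s."""

    kind: str = "smooth_pursuit"
    duration: float = 8.0            # s
    pursuit_center: float = 20.5     # afferent-index units
    pursuit_amplitude: float = 9.5   # sinusoid between indices 11 and 30
    pursuit_freq: float = 1.0        # Hz
    fixation_pos: float = 10.0
    distractor_pos: float | None = None
    distractor_onset: float = 2.0    # s
    rate_floor: float = 30.0         # sp/s
    rate_peak: float = 250.0         # sp/s
    bump_exponent: int = 4           # quartic bump; 2 gives a plain Gaussian

    def __post_init__(self) -> None:
        if self.kind not in ("smooth_pursuit", "fixation"):
            raise ValueError(f"unknown task kind: {self.kind!r}")
        if self.distractor_pos is not None and not (
            0 <= self.distractor_onset < self.duration
        ):
            raise ValueError("distractor onset must precede trial end")
        if not 0 < self.rate_floor < self.rate_peak:
            raise ValueError("need 0 < rate_floor < rate_peak")

    @classmethod
    def pursuit(cls, **kw) -> "TaskSpec":
        return cls(kind="smooth_pursuit", **kw)

    @classmethod
    def fixation(cls, distractor: bool = True, **kw) -> "TaskSpec":
        return cls(
            kind="fixation",
            distractor_pos=25.0 if distractor else None,
            **kw,
        )


@dataclass
class GazeState:
    x_c: float = GAZE_START
    bounds: tuple[float, float] = GAZE_BOUNDS


def target_position(spec: TaskSpec, t: float) -> float:
    """Target center (afferent-index units) at trial time t (s)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > spec.duration):
        raise ValueError("t outside the trial duration")
    if spec.kind == "fixation":
        return np.broadcast_to(spec.fixation_pos, t.shape)[()] + 0.0 * t
    return spec.pursuit_center + spec.pursuit_amplitude * np.sin(
        2.0 * np.pi * spec.pursuit_freq * t
    )


def _bump(u: np.ndarray, exponent: int) -> np.ndarray:
    u2 = u * u
    return np.exp(-(u2 * u2 if exponent == 4 else u2) / 2.0)


def stimulus_rates(
    x_c: float,
    x_target: float,
    distractor: float | None,
    spec: TaskSpec,
    n_t: int = 40,
) -> np.ndarray:
    """Poisson rate (sp/s) of each thalamic afferent.

    rate_i = floor + (peak - floor) * bump(0.5 N_T - i - (x_c - x))
    evaluated for the target and, if present, the distractor; the two bumps
    combine by element-wise maximum so the ceiling stays at the peak rate.
    """
    i = np.arange(1, n_t + 1, dtype=float)
    amp = spec.rate_peak - spec.rate_floor
    u = 0.5 * n_t - i - (x_c - x_target)
    bump = _bump(u, spec.bump_exponent)
    if distractor is not None:
        u_d = 0.5 * n_t - i - (x_c - distractor)
        bump = np.maximum(bump, _bump(u_d, spec.bump_exponent))
    return np.minimum(spec.rate_floor + amp * bump, spec.rate_peak)


def sample_input_spikes(
    rates: np.ndarray, cfg: IntegratorConfig, rng: np.random.RandomState
) -> np.ndarray:
    """One Bernoulli draw per afferent for this step, p = rate * h / 1000."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    p = rates * cfg.step_h / 1000.0
    if np.any(p > 1):
        raise ValueError("rate * step exceeds one spike per step")
    return rng.random_sample(rates.size) < p


def motor_weights(n_m: int = 120) -> tuple[np.ndarray, np.ndarray]:
    """Rectified linear ramps of the left/right movement readout."""
    i = np.arange(1, n_m + 1, dtype=float)
    half = 0.5 * n_m
    w_l = MOTOR_SLOPE * np.maximum((half - i) / half, 0.0)
    w_r = MOTOR_SLOPE * np.maximum((i - half) / half, 0.0)
    return w_l, w_r


def motor_signals(g_m_fast: np.ndarray) -> tuple[float, float]:
    """Leftward and rightward movement signals from the MLN error map.

    The left half of the map (low indices) votes for leftward movement, the
    right half for rightward, each through a linear ramp that weights
    eccentric neurons most.
    """
    g = np.asarray(g_m_fast, dtype=float)
    n_m = g.size
    w_l, w_r = motor_weights(n_m)
    half = n_m // 2
    return float(w_l[:half] @ g[:half]), float(w_r[half:] @ g[half:])


def update_gaze(state: GazeState, l_sig: float, r_sig: float) -> GazeState:
    lo, hi = state.bounds
    return GazeState(float(np.clip(state.x_c + r_sig - l_sig, lo, hi)), state.bounds)


@dataclass
class TrialRecord:
    """Everything one trial produced, sampled at the recording rate."""

    time: np.ndarray           # s, length duration * record_rate
    eye: np.ndarray            # gaze center, afferent-index units
    target: np.ndarray
    distractor: np.ndarray     # NaN while absent
    mln_sum: np.ndarray        # summed MLN membrane voltage
    p_t: np.ndarray            # (n_samples, n_t) disinhibition factor
    spikes: dict[str, tuple[np.ndarray, np.ndarray]]  # pop -> (t_s, neuron)
    seed: int
    task: TaskSpec
    perturbation: PerturbationSpec
    record_rate: float = 400.0

    def to_frame(self) -> pd.DataFrame:
        """Flat tabular export of the behavioral traces."""
        return pd.DataFrame(
            {
                "time_s": self.time,
                "eye": self.eye,
                "target": self.target,
                "distractor": self.distractor,
                "mln_sum": self.mln_sum,
            }
        )

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("time", "eye", "target", "distractor", "mln_sum", "p_t"):
                f.create_dataset(name, data=getattr(self, name))
            grp = f.create_group("spikes")
            for pop, (t, idx) in self.spikes.items():
                g = grp.create_group(pop)
                g.create_dataset("t", data=t)
                g.create_dataset("neuron", data=idx)
            f.attrs["seed"] = self.seed
            f.attrs["record_rate"] = self.record_rate
            f.attrs["task_kind"] = self.task.kind
            f.attrs["perturbation_kind"] = self.perturbation.kind
            f.attrs["perturbation_strength"] = self.perturbation.strength

    @classmethod
    def load(cls, path) -> "TrialRecord":
        with h5py.File(path, "r") as f:
            spikes = {
                pop: (f["spikes"][pop]["t"][:], f["spikes"][pop]["neuron"][:])
                for pop in f["spikes"]
            }
            task = (
                TaskSpec.pursuit()
                if f.attrs["task_kind"] == "smooth_pursuit"
                else TaskSpec.fixation()
            )
            return cls(
                time=f["time"][:],
                eye=f["eye"][:],
                target=f["target"][:],
                distractor=f["distractor"][:],
                mln_sum=f["mln_sum"][:],
                p_t=f["p_t"][:],
                spikes=spikes,
                seed=int(f.attrs["seed"]),
                task=task,
                perturbation=PerturbationSpec(
                    kind=str(f.attrs["perturbation_kind"]),
                    strength=float(f.attrs["perturbation_strength"]),
                ),
                record_rate=float(f.attrs["record_rate"]),
            )


def _trial_seeds(seed: int) -> tuple[np.random.Generator, int]:
    """Expand one trial seed into a jitter generator and a Poisson seed."""
    ss = np.random.SeedSequence(seed)
    js, ps = ss.generate_state(2)
    return np.random.default_rng(int(js)), int(ps % 2**31)


def run_trial(
    task: TaskSpec,
    perturb: PerturbationSpec = PerturbationSpec(),
    net_cfg: NetworkConfig | None = None,
    seed: int = 0,
    int_cfg: IntegratorConfig | None = None,
    engine: str = "numba",
) -> TrialRecord:
    """Run one full closed-loop trial.

    Every integration step: stimulus rates from the current gaze ->
    Bernoulli afferent spikes -> network step -> motor error readout ->
    gaze update.  Traces are sampled at the recording-rate boundaries
    (entry state of the boundary step); perturbation modifiers are active
    only inside their scheduled window.  Identical seeds and configurations
    give identical records.

    ``engine="numba"`` runs the fused compiled kernel (default);
    ``engine="numpy"`` runs the modular reference step (slow, used for
    cross-checking).
    """
    net_cfg = net_cfg or NetworkConfig()
    int_cfg = int_cfg or IntegratorConfig()
    for pos in (task.fixation_pos, task.distractor_pos):
        if pos is not None and not 1 <= pos <= net_cfg.n_t:
            raise ValueError("task positions must lie within [1, N_T]")
    if engine == "numba":
        from ._kernel import run_trial_kernel

        return run_trial_kernel(task, perturb, net_cfg, seed, int_cfg)
    if engine != "numpy":
        raise ValueError(f"unknown engine: {engine!r}")

    jitter_rng, poisson_seed = _trial_seeds(seed)
    params, state = build_network(net_cfg, jitter_rng)
    rs = np.random.RandomState(poisson_seed)
    gaze = GazeState()
    h = int_cfg.step_h
    stride = int_cfg.record_stride
    n_steps = round(task.duration * 1000.0 / h)
    n_rec = n_steps // stride

    rec_eye = np.empty(n_rec)
    rec_target = np.empty(n_rec)
    rec_dis = np.full(n_rec, np.nan)
    rec_mln = np.empty(n_rec)
    rec_pt = np.empty((n_rec, net_cfg.n_t))
    spike_t = {p: [] for p in POPULATIONS}
    spike_i = {p: [] for p in POPULATIONS}

    for k in range(n_steps):
        t = k * h / 1000.0
        x_t = float(target_position(task, t))
        distractor = (
            task.distractor_pos
            if task.distractor_pos is not None and t >= task.distractor_onset
            else None
        )
        if k % stride == 0:
            r = k // stride
            rec_eye[r] = gaze.x_c
            rec_target[r] = x_t
            if distractor is not None:
                rec_dis[r] = distractor
            rec_mln[r] = state.pops["m"].v.sum()
            rec_pt[r] = state.p_t
        rates = stimulus_rates(gaze.x_c, x_t, distractor, task, net_cfg.n_t)
        ext_spikes = sample_input_spikes(rates, int_cfg, rs)
        mod = resolve_perturbation(perturb, t)
        state = step_network(state, params, ext_spikes, int_cfg, mod)
        for p in POPULATIONS:
            idx = np.nonzero(state.pops[p].spiked)[0]
            if idx.size:
                spike_t[p].append(np.full(idx.size, (k + 1) * h / 1000.0))
                spike_i[p].append(idx)
        l_sig, r_sig = motor_signals(state.cond["m_fast"].g)
        gaze = update_gaze(gaze, l_sig, r_sig)

    spikes = {
        p: (
            np.concatenate(spike_t[p]) if spike_t[p] else np.empty(0),
            np.concatenate(spike_i[p]).astype(np.int64)
            if spike_i[p]
            else np.empty(0, dtype=np.int64),
        )
        for p in POPULATIONS
    }
    return TrialRecord(
        time=np.arange(n_rec) * stride * h / 1000.0,
        eye=rec_eye,
        target=rec_target,
        distractor=rec_dis,
        mln_sum=rec_mln,
        p_t=rec_pt,
        spikes=spikes,
        seed=seed,
        task=task,
        perturbation=perturb,
        record_rate=int_cfg.record_rate,
    )
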