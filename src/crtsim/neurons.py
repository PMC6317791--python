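"""Izhikevich neuron populations with forward-Euler integration.

Each neuron follows the two-variable quadratic integrate-and-reset model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_total
    du/dt = a (b v - u)

with the after-spike rule: if v >= 30 mV then v <- c, u <- u + d.  The
regular-spiking (RS) parameter set is used for all excitatory groups and the
CB interneurons; the fast-spiking (FS) set for PV interneurons.  Per-neuron
parameters carry independent multiplicative jitter so no two neurons in a
population are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import IntegratorConfig

__all__ = [
    "RS_PARAMS",
    "FS_PARAMS",
    "IzhikevichParams",
    "PopulationState",
    "init_population",
    "step_izhikevich",
]

#: (a, b, c, d) regular-spiking nominal set.
RS_PARAMS = (0.02, 0.2, -65.0, 0.0)
#: (a, b, c, d) fast-spiking nominal set (PV interneurons).
FS_PARAMS = (0.1, 0.2, -65.0, 2.0)

SPIKE_THRESHOLD = 30.0  # mV


@dataclass
class IzhikevichParams:
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    spike_threshold: float = SPIKE_THRESHOLD


@dataclass
class PopulationState:
    v: np.ndarray        # membrane voltage, mV
    u: np.ndarray        # recovery variable
    spiked: np.ndarray   # bool, spikes detected in the most recent step

    def copy(self) -> "PopulationState":
        return PopulationState(self.v.copy(), self.u.copy(), self.spiked.copy())


def _jitter(rng: np.random.Generator, nominal: float, n: int, frac: float) -> np.ndarray:
    return nominal * rng.uniform(1.0 - frac, 1.0 + frac, size=n)


def init_population(
    n: int,
    nominal: tuple[float, float, float, float] = RS_PARAMS,
    jitter_frac: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[IzhikevichParams, PopulationState]:
    """Create a jittered population at its resting state.

    Each of a, b, c, d is drawn independently per neuron as
    ``nominal * U(1 - jitter_frac, 1 + jitter_frac)``.  Initial conditions
    are v = c (jittered) and u = b * v.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if not 0 <= jitter_frac < 1:
        raise ValueError("jitter_frac must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b, c, d = (_jitter(rng, x, n, jitter_frac) for x in nominal)
    v = c.copy()
    u = b * v
    return (
        IzhikevichParams(a, b, c, d),
        PopulationState(v, u, np.zeros(n, dtype=bool)),
    )


def step_izhikevich(
    state: PopulationState,
    params: IzhikevichParams,
    total_input: np.ndarray,
    cfg: IntegratorConfig,
) -> PopulationState:
    """Advance one Euler step and apply the after-spike reset.

    v and u are updated synchronously from the pre-step state; neurons whose
    updated voltage reaches threshold are flagged, reset to c, and have d
    added to u, so no neuron is ever left above threshold.
    """
    v, u = state.v, state.u
    total_input = np.asarray(total_input, dtype=float)
    if total_input.shape != v.shape:
        raise ValueError("total_input length must equal population size")
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(total_input))):
        raise FloatingPointError("non-finite membrane state or input current")
    h = cfg.scaled_step
    v_new = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + total_input)
    u_new = u + h * params.a * (params.b * v - u)
    spiked = v_new >= params.spike_threshold
    v_new = np.where(spiked, params.c, v_new)
    u_new = np.where(spiked, u_new + params.d, u_new)
    return PopulationState(v_new, u_new, spiked)
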