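"""Low-threshold T-type calcium channel (GHK form) with rebound-burst gating.

The channel carries the current

    I_Ca = A_Ca * s * m^2 h * Phi(v, Ca_int)

where Phi is the Goldman-Hodgkin-Katz flux of Ca2+ through an open channel
and s is a fixed unit-folding scale (the published parameterization leaves
the unit chain of the amplitude open; the calibration contract is
hyperpolarization-driven rebound bursting, not absolute current).  The
activation gate m opens with depolarization and the inactivation gate h is
removed by hyperpolarization, so a neuron held hyperpolarized and then
released produces a transient depolarizing calcium surge — the substrate of
thalamic and reticular rebound bursts in the alpha/delta range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import IntegratorConfig

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "CA_UNIT_SCALE",
    "TChannelParams",
    "TChannelState",
    "t_gate_functions",
    "ghk_flux",
    "t_channel_current",
    "step_t_channel",
]

FARADAY = 96485.3       # C/mol
GAS_CONSTANT = 8.314    # J/(mol K)
CA_REST = 0.00024       # mM, resting internal calcium

#: Unit-folding scale applied to the raw GHK flux so that channel currents
#: land on the same footing as the dimensionless synaptic currents: with the
#: published amplitudes, subthreshold leak is O(0.01) and a full rebound
#: burst peaks at O(100) current units.
CA_UNIT_SCALE = 1e-6


@dataclass
class TChannelParams:
    amplitude: float            # A_Ca: 20 for thalamus, 12 for TRN
    p_ca: float = 30.0          # max open-channel permeability, cm^3/s
    z: int = 2                  # calcium ion charge
    temperature: float = 298.0  # K
    ca_ext: float = 2.0         # mM
    unit_scale: float = CA_UNIT_SCALE

    def __post_init__(self) -> None:
        if min(self.amplitude, self.p_ca, self.temperature, self.ca_ext) <= 0:
            raise ValueError("T-channel parameters must be positive")


@dataclass
class TChannelState:
    m: np.ndarray        # activation gate in [0, 1]
    h: np.ndarray        # inactivation gate in [0, 1]
    ca_int: np.ndarray   # internal calcium, mM

    @classmethod
    def at_rest(cls, v: np.ndarray) -> "TChannelState":
        """Gates at their steady state for voltage v, calcium at rest."""
        m_inf, h_inf, _, _ = t_gate_functions(v)
        return cls(m_inf, h_inf, np.full(np.shape(v), CA_REST))

    def copy(self) -> "TChannelState":
        return TChannelState(self.m.copy(), self.h.copy(), self.ca_int.copy())


def t_gate_functions(v):
    """Steady states and time constants of the T-channel gates at voltage v (mV).

    m_inf half-activates at -79 mV, h_inf half-inactivates at -92 mV; the
    voltage-dependent time constants follow the standard thalamic relay /
    reticular T-current parameterization (ms).
    """
    v = np.asarray(v, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(v + 79.0) / 6.2))
    h_inf = 1.0 / (1.0 + np.exp((v + 92.0) / 4.0))
    tau_m = 0.999 + 0.333 / (np.exp((v + 31.0) / 10.0) + np.exp(-(v + 106.0) / 15.0))
    tau_h = (
        30.8 + (211.4 + np.exp((v + 119.2) / 5.0)) / (1.0 + np.exp((v + 90.0) / 3.2))
    ) / 3.7373
    return m_inf, h_inf, tau_m, tau_h


def ghk_flux(v_mv, ca_int, p_ca=30.0, z=2, temperature=298.0, ca_ext=2.0):
    """Goldman-Hodgkin-Katz flux factor for Ca2+ at voltage v (mV).

    Phi = P z^2 F^2 V / (R T) * (Ca_int - Ca_ext e^{-zFV/RT}) / (1 - e^{-zFV/RT})

    with V in volts.  The removable singularity at V = 0 is evaluated by its
    limit P z F (Ca_int - Ca_ext) (plus the first-order term), so the flux
    is continuous across 0 mV.  Negative below the calcium reversal, i.e.
    inward-flux sign convention.
    """
    v = np.asarray(v_mv, dtype=float) / 1000.0
    ca_int = np.asarray(ca_int, dtype=float)
    zf = z * FARADAY
    x = zf * v / (GAS_CONSTANT * temperature)
    small = np.abs(x) < 1e-5
    x_safe = np.where(small, 1.0, x)
    exact = p_ca * zf * x_safe * (ca_int - ca_ext * np.exp(-x_safe)) / (
        1.0 - np.exp(-x_safe)
    )
    series = p_ca * zf * ((ca_int - ca_ext) + x * (ca_int + ca_ext) / 2.0)
    return np.where(small, series, exact)


def t_channel_current(
    state: TChannelState, v: np.ndarray, params: TChannelParams
) -> np.ndarray:
    """Channel current at the current state; positive (depolarizing) at
    subthreshold voltages."""
    m, hh = state.m, state.h
    return (
        -params.amplitude
        * params.unit_scale
        * m * m * hh
        * ghk_flux(
            np.asarray(v, dtype=float),
            state.ca_int,
            params.p_ca,
            params.z,
            params.temperature,
            params.ca_ext,
        )
    )


def step_t_channel(
    state: TChannelState,
    v: np.ndarray,
    params: TChannelParams,
    cfg: IntegratorConfig,
) -> tuple[TChannelState, np.ndarray]:
    """One Euler step of the gates and calcium pool; returns the new state
    and the channel current evaluated from the *entry* state (currents are
    always computed from pre-step quantities).

    The calcium pool relaxes to its 0.00024 mM rest level with a 0.2 /ms
    rate and responds to the rectified channel current.
    """
    v = np.asarray(v, dtype=float)
    m, hh, ca = state.m, state.h, state.ca_int
    i_ca = t_channel_current(state, v, params)
    m_inf, h_inf, tau_m, tau_h = t_gate_functions(v)
    h_step = cfg.step_h
    m_new = np.clip(m + h_step * (m_inf - m) / tau_m, 0.0, 1.0)
    h_new = np.clip(hh + h_step * (h_inf - hh) / tau_h, 0.0, 1.0)
    zf = params.z * FARADAY
    dca = -(10.0 / zf) * np.maximum(i_ca, 0.0) - 0.2 * (ca - CA_REST)
    ca_new = np.maximum(ca + h_step * dca, 1e-9)
    return TChannelState(m_new, h_new, ca_new), i_ca
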