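"""Model configuration: integration settings and the full parameter table.

All times are in milliseconds unless a field name says otherwise.  The
default :class:`NetworkConfig` reproduces the published parameter table of
the cortico-reticulo-thalamic (CRT) circuit: six neuron groups (thalamus T,
reticular nucleus R, middle- and deep-layer pyramids M and D, and the PV and
CB interneuron classes), Gaussian topographic connectivity, and the synaptic
kinetics families (fast AMPA/GABA_A, NMDA, PV-fast, GABA_B, and the
extra-slow conductance driving disinhibitory short-term plasticity).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["IntegratorConfig", "NetworkConfig", "TAU_TABLE"]

#: (tau_rise, tau_fall) in ms for each synapse kinetics family.
TAU_TABLE: dict[str, tuple[float, float]] = {
    "fast": (2.0, 10.0),
    "nmda": (8.0, 100.0),
    "pv_fast": (0.1, 0.5),
    "gaba_b": (8.0, 30.0),
    "xslow": (200.0, 400.0),
}


@dataclass(frozen=True)
class IntegratorConfig:
    """Forward-Euler integration settings.

    The spike-dependent transmitter signal K is a rectangular pulse whose
    duration is specified in milliseconds, so halving the step size doubles
    the number of pulse steps and leaves the injected transmitter unchanged
    (the step-size compensation rule for the discrete spike signal).
    """

    step_h: float = 0.025            # ms
    tau_s: float = 1.0               # ms; time-scale constant of the membrane
    #                                  and synaptic equations (effective value;
    #                                  see the methods note on its units)
    record_rate: float = 400.0       # Hz; behavioral/neural trace sampling
    spike_pulse_duration: float = 0.025   # ms
    spike_pulse_magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.step_h <= 0 or self.tau_s <= 0:
            raise ValueError("step_h and tau_s must be positive")
        if self.spike_pulse_duration <= 0 or self.spike_pulse_magnitude <= 0:
            raise ValueError("spike pulse parameters must be strictly positive")
        interval = 1000.0 / self.record_rate
        stride = interval / self.step_h
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError(
                "record interval (%g ms) must be an integer multiple of step_h"
                % interval
            )

    @property
    def record_stride(self) -> int:
        """Integration steps between recorded samples (100 at defaults)."""
        return round(1000.0 / self.record_rate / self.step_h)

    @property
    def scaled_step(self) -> float:
        """Euler step divided by the time-scale constant, h / tau_s."""
        return self.step_h / self.tau_s

    @property
    def pulse_steps(self) -> int:
        """Duration of the spike pulse K in integration steps (>= 1)."""
        return max(1, round(self.spike_pulse_duration / self.step_h))


@dataclass
class NetworkConfig:
    """Population sizes, connectivity widths/amplitudes, and cell parameters.

    Field names mirror the published parameter table: ``sigma_<pre>_<post>``
    is the Gaussian width of the topographic projection in normalized
    position units (index / population size), ``a_<pre>_<post>`` its peak
    weight.  ``a_r_t`` is the uniform all-to-all weight of the inhibitory
    reticulo-thalamic projection; islands of disinhibition arise only
    through the short-term-plasticity factor, never through the weights.
    """

    # population sizes
    n_t: int = 40
    n_r: int = 40
    n_pv: int = 40
    n_cb: int = 40
    n_m: int = 120
    n_d: int = 120

    # Gaussian connectivity widths (normalized position units)
    sigma_d_t: float = 0.05
    sigma_t_m_p: float = 0.0625
    sigma_t_m_d: float = 0.9375
    sigma_m_d: float = 0.0125
    sigma_t_r: float = 0.0938
    sigma_d_r: float = 0.0125
    sigma_r_r_gap: float = 0.0313
    sigma_pv_pv: float = 0.0313
    sigma_pv_m: float = 0.4375
    sigma_cb_m: float = 1.25
    sigma_m_pv: float = 0.025
    sigma_m_cb: float = 0.125

    # Gaussian peak weights
    a_d_t: float = 0.04
    a_t_m_p: float = 4.8
    a_t_m_d: float = 1.2
    a_m_d: float = 1.4
    a_t_r: float = 0.15
    a_d_r: float = 1.0
    a_r_r_gap: float = 0.3
    a_pv_pv: float = 10.0
    a_pv_m: float = 50.0
    a_cb_m: float = 1.0

    # receptor amplitudes (dimensionless; 1 unless listed in the table)
    a_m_pv_ampa: float = 0.5
    a_m_pv_nmda: float = 4.0
    a_m_cb_ampa: float = 0.03
    a_m_cb_nmda: float = 1.0
    a_ext_ampa: float = 1.0
    a_ext_nmda: float = 1.0

    # reticulo-thalamic inhibition (uniform all-to-all weight)
    a_r_t: float = 0.32

    # T-type calcium channel amplitudes
    a_t_ca: float = 20.0
    a_r_ca: float = 12.0

    # disinhibitory short-term plasticity scale
    a_stp: float = 3000.0

    # unit-folding scale of the T-type calcium current (see crtsim.channels)
    ca_unit_scale: float = 1e-6

    # per-neuron parameter variability (multiplicative, +/- fraction)
    jitter_frac: float = 0.05

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("sigma_") and v <= 0:
                raise ValueError(f"{f.name} must be positive")
            if f.name.startswith(("a_", "n_")) and v < 0:
                raise ValueError(f"{f.name} must be nonnegative")
        if not 0 <= self.jitter_frac < 1:
            raise ValueError("jitter_frac must lie in [0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
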