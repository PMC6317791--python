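"""Inhibitory perturbation protocols as pure parameter-modifier schedules.

Each protocol degrades one inhibitory mechanism of the circuit from a fixed
onset (default 6 s, the final quarter of an 8 s trial) to trial end:

- ``pv_nmda`` / ``cb_nmda``: scale the NMDA receptor amplitude on PV / CB
  interneurons (glutamatergic hypofunction of cortical inhibitory cells);
- ``combined_nmda``: both NMDA amplitudes jointly;
- ``pv_gaba_direct``: scale the PV output weights (A_PV->PV and A_PV->M
  jointly; direct GABA deficit);
- ``cb_gaba_direct``: scale the CB output weight A_CB->M;
- ``trn_hyperpolarize``: add a constant hyperpolarizing current I_hyp to
  every reticular neuron, deinactivating T-type calcium channels;
- ``dstp_reduce``: scale the disinhibitory short-term plasticity constant
  A_STP;
- ``none``: identity.

Modifiers never mutate the baseline configuration; strength 1 (or I_hyp 0)
reproduces the unperturbed trajectory exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["PerturbationSpec", "Modifiers", "resolve_perturbation", "SWEEP_GRIDS"]

KINDS = (
    "none",
    "pv_nmda",
    "cb_nmda",
    "combined_nmda",
    "pv_gaba_direct",
    "cb_gaba_direct",
    "trn_hyperpolarize",
    "dstp_reduce",
)

#: Strength grids of the published parametric sweeps (scale factors, except
#: trn_hyperpolarize which lists I_hyp currents).
SWEEP_GRIDS = {
    "pv_nmda": (0.5, 0.4, 0.3, 0.2, 0.1),
    "cb_nmda": (0.5, 0.4, 0.3, 0.2, 0.1),
    "combined_nmda": (0.5, 0.4, 0.3, 0.2, 0.1),
    "dstp_reduce": (0.5, 0.4, 0.3, 0.2, 0.1),
    "pv_gaba_direct": (0.9, 0.8, 0.7, 0.6, 0.5),
    "cb_gaba_direct": (0.5, 0.4, 0.3, 0.2, 0.1),
    "trn_hyperpolarize": (-15.0, -30.0, -45.0, -60.0, -75.0),
}


@dataclass(frozen=True)
class Modifiers:
    """Multiplicative parameter scales (and additive TRN current) in force."""

    nmda_pv_scale: float = 1.0
    nmda_cb_scale: float = 1.0
    pv_gaba_scale: float = 1.0
    cb_gaba_scale: float = 1.0
    a_stp_scale: float = 1.0
    i_hyp: float = 0.0


IDENTITY = Modifiers()


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str = "none"
    strength: float = 1.0   # scale factor, or I_hyp current for the TRN kind
    onset: float = 6.0      # s
    offset: float = 8.0     # s

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind: {self.kind!r}")
        if self.onset >= self.offset:
            raise ValueError("need onset < offset")

    def modifiers(self) -> Modifiers:
        """The modifiers active inside [onset, offset)."""
        k, s = self.kind, self.strength
        if k == "none":
            return IDENTITY
        if k == "pv_nmda":
            return Modifiers(nmda_pv_scale=s)
        if k == "cb_nmda":
            return Modifiers(nmda_cb_scale=s)
        if k == "combined_nmda":
            return Modifiers(nmda_pv_scale=s, nmda_cb_scale=s)
        if k == "pv_gaba_direct":
            return Modifiers(pv_gaba_scale=s)
        if k == "cb_gaba_direct":
            return Modifiers(cb_gaba_scale=s)
        if k == "trn_hyperpolarize":
            return Modifiers(i_hyp=s)
        return Modifiers(a_stp_scale=s)  # dstp_reduce


def resolve_perturbation(spec: PerturbationSpec, t: float) -> Modifiers:
    """Modifiers in force at trial time t (s); identity outside the window."""
    if spec.onset <= t < spec.offset:
        return spec.modifiers()
    return IDENTITY
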