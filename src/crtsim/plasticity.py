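"""Disinhibitory short-term plasticity (dSTP) of reticulo-thalamic synapses.

Sustained firing in deep-layer cortical neurons (DLNs) builds an extra-slow
conductance g_xslow (200/400 ms kinetics).  Routed through the topographic
cortico-thalamic weights, it multiplicatively weakens the GABA_B inhibition
each thalamic neuron receives from the reticular nucleus:

    P_Ti = 1 / (1 + A_STP * sum_j W_{Dj->Ti} (g_xslow_j)^6)

P_T = 1 means full inhibition; persistent DLN activity (~200 ms or longer)
drives P_T toward 0 for the topographically aligned thalamic neurons only,
carving focal "islands" of thalamic disinhibition that underlie continuous
attention to a tracked stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synapses import ConductanceState

__all__ = ["DstpState", "dstp_factor"]

#: Exponent on g_xslow; makes disinhibition engage sharply only once the
#: slow conductance is well developed.
DSTP_EXPONENT = 6


@dataclass
class DstpState:
    """Slow cortical conductance and the thalamic disinhibition factor."""

    g_xslow: ConductanceState   # over DLNs
    p_t: np.ndarray             # over thalamic neurons, in (0, 1]

    @classmethod
    def zeros(cls, n_d: int, n_t: int) -> "DstpState":
        return cls(ConductanceState.zeros(n_d), np.ones(n_t))


def dstp_factor(g_xslow: np.ndarray, w_d_to_t: np.ndarray, a_stp: float) -> np.ndarray:
    """Disinhibition factor P_T for each thalamic neuron.

    ``w_d_to_t`` is the weighted cortico-thalamic matrix, shape (n_t, n_d).
    P_T is 1 at zero cortical drive (or A_STP = 0), bounded in (0, 1], and
    component-wise non-increasing in g_xslow.
    """
    g_xslow = np.asarray(g_xslow, dtype=float)
    if np.any(g_xslow < 0):
        raise ValueError("g_xslow must be nonnegative")
    if a_stp < 0:
        raise ValueError("A_STP must be nonnegative")
    g2 = g_xslow * g_xslow
    drive = w_d_to_t @ (g2 * g2 * g2)
    return 1.0 / (1.0 + a_stp * drive)
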