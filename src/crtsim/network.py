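"""The six-population CRT network: connectome, state, and the full step.

Populations (sizes at defaults): thalamus T (40), reticular nucleus R (40),
middle-layer pyramids M (120), deep-layer pyramids D (120), PV interneurons
(40), CB interneurons (40).  Projections are topographic Gaussians over
normalized position (index / population size),

    W[pre i -> post j] = A exp(-((i/N_pre - j/N_post) / sigma)^2),

except the reticulo-thalamic inhibition, which is uniformly all-to-all.
Input currents per population:

    T:  external AMPA + NMDA, D->T AMPA, T-type Ca;  minus P_T-scaled
        R->T GABA_B (the only synapse subject to disinhibitory plasticity)
    R:  T->R + D->R AMPA, T-type Ca, gap coupling; plus I_hyp if scheduled
    M:  proximal + rectified distal thalamic drive (CB inhibits only the
        distal branch); minus PV->M GABA_A
    PV: M AMPA + NMDA; minus PV->PV GABA_A
    CB: M AMPA + NMDA; no inhibition
    D:  M AMPA; no inhibition
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import (
    TChannelParams,
    TChannelState,
    step_t_channel,
    t_channel_current,
)
from .config import IntegratorConfig, NetworkConfig, TAU_TABLE
from .neurons import (
    FS_PARAMS,
    RS_PARAMS,
    IzhikevichParams,
    PopulationState,
    init_population,
    step_izhikevich,
)
from .plasticity import DstpState, dstp_factor
from .synapses import (
    ConductanceState,
    SynapseKinetics,
    gap_current,
    nmda_gate,
    step_sd_conductance,
)
from .perturbations import IDENTITY, Modifiers

__all__ = [
    "gaussian_weights",
    "Connectome",
    "NetworkParams",
    "NetworkState",
    "build_connectome",
    "build_network",
    "mln_dendritic_input",
    "compute_currents",
    "step_network",
]

POPULATIONS = ("t", "r", "m", "pv", "cb", "d")

#: (presynaptic population, kinetics family) for every conductance the
#: network tracks.  "ext" are the external thalamic afferents (one Poisson
#: train per afferent, shared by its AMPA and NMDA conductances).
CONDUCTANCES = (
    ("t_fast", "t", "fast"),
    ("r_gabab", "r", "gaba_b"),
    ("m_fast", "m", "fast"),
    ("m_nmda", "m", "nmda"),
    ("d_fast", "d", "fast"),
    ("d_xslow", "d", "xslow"),
    ("pv", "pv", "pv_fast"),
    ("cb_fast", "cb", "fast"),
    ("ext_fast", "ext", "fast"),
    ("ext_nmda", "ext", "nmda"),
)


def gaussian_weights(
    n_pre: int, n_post: int, sigma: float, amplitude: float = 1.0
) -> np.ndarray:
    """Topographic Gaussian weight matrix, shape (n_post, n_pre).

    Indices run 1..N and are normalized by population size, so the 120-unit
    cortical groups align retinotopically with the 40-unit thalamic groups.
    """
    i = np.arange(1, n_pre + 1) / n_pre
    j = np.arange(1, n_post + 1) / n_post
    return amplitude * np.exp(-(((i[None, :] - j[:, None]) / sigma) ** 2))


@dataclass
class Connectome:
    """All weight matrices, amplitudes included, shape (n_post, n_pre)."""

    w_d_t: np.ndarray
    w_t_m_p: np.ndarray
    w_t_m_d: np.ndarray
    w_m_d: np.ndarray
    w_t_r: np.ndarray
    w_d_r: np.ndarray
    w_m_pv: np.ndarray
    w_m_cb: np.ndarray
    w_pv_pv: np.ndarray
    w_pv_m: np.ndarray
    w_cb_m: np.ndarray
    w_r_r_gap: np.ndarray
    w_r_t: np.ndarray

    def save(self, path) -> None:
        """Labeled matrix archive for inspection."""
        np.savez(path, **{f: getattr(self, f) for f in self.__dataclass_fields__})


def build_connectome(cfg: NetworkConfig) -> Connectome:
    """Deterministic weight matrices from the configuration table."""
    g = gaussian_weights
    gap = g(cfg.n_r, cfg.n_r, cfg.sigma_r_r_gap, cfg.a_r_r_gap)
    np.fill_diagonal(gap, 0.0)
    return Connectome(
        w_d_t=g(cfg.n_d, cfg.n_t, cfg.sigma_d_t, cfg.a_d_t),
        w_t_m_p=g(cfg.n_t, cfg.n_m, cfg.sigma_t_m_p, cfg.a_t_m_p),
        w_t_m_d=g(cfg.n_t, cfg.n_m, cfg.sigma_t_m_d, cfg.a_t_m_d),
        w_m_d=g(cfg.n_m, cfg.n_d, cfg.sigma_m_d, cfg.a_m_d),
        w_t_r=g(cfg.n_t, cfg.n_r, cfg.sigma_t_r, cfg.a_t_r),
        w_d_r=g(cfg.n_d, cfg.n_r, cfg.sigma_d_r, cfg.a_d_r),
        w_m_pv=g(cfg.n_m, cfg.n_pv, cfg.sigma_m_pv, 1.0),
        w_m_cb=g(cfg.n_m, cfg.n_cb, cfg.sigma_m_cb, 1.0),
        w_pv_pv=g(cfg.n_pv, cfg.n_pv, cfg.sigma_pv_pv, cfg.a_pv_pv),
        w_pv_m=g(cfg.n_pv, cfg.n_m, cfg.sigma_pv_m, cfg.a_pv_m),
        w_cb_m=g(cfg.n_cb, cfg.n_m, cfg.sigma_cb_m, cfg.a_cb_m),
        w_r_r_gap=gap,
        w_r_t=np.full((cfg.n_t, cfg.n_r), cfg.a_r_t),
    )


@dataclass
class NetworkParams:
    """Static (per-trial) parameters: jittered cell and synapse parameters."""

    cfg: NetworkConfig
    conn: Connectome
    izh: dict[str, IzhikevichParams]
    kinetics: dict[str, SynapseKinetics]
    tchan_t: TChannelParams
    tchan_r: TChannelParams


@dataclass
class NetworkState:
    pops: dict[str, PopulationState]
    cond: dict[str, ConductanceState]
    tchan_t: TChannelState
    tchan_r: TChannelState
    p_t: np.ndarray

    def copy(self) -> "NetworkState":
        return NetworkState(
            {k: s.copy() for k, s in self.pops.items()},
            {k: s.copy() for k, s in self.cond.items()},
            self.tchan_t.copy(),
            self.tchan_r.copy(),
            self.p_t.copy(),
        )

    @property
    def dstp(self) -> DstpState:
        return DstpState(self.cond["d_xslow"], self.p_t)


def _pop_sizes(cfg: NetworkConfig) -> dict[str, int]:
    return {
        "t": cfg.n_t, "r": cfg.n_r, "m": cfg.n_m,
        "pv": cfg.n_pv, "cb": cfg.n_cb, "d": cfg.n_d,
        "ext": cfg.n_t,
    }


def build_network(
    cfg: NetworkConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[NetworkParams, NetworkState]:
    """Jittered populations and synapses at rest; reproducible per seed.

    Cell parameters (a, b, c, d), initial voltages, and synaptic rise/fall
    times all carry independent +/- jitter_frac multiplicative variability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = _pop_sizes(cfg)
    izh, pops = {}, {}
    for name in POPULATIONS:
        nominal = FS_PARAMS if name == "pv" else RS_PARAMS
        izh[name], pops[name] = init_population(
            sizes[name], nominal, cfg.jitter_frac, rng
        )
    kinetics, cond = {}, {}
    for cname, pre, family in CONDUCTANCES:
        tr, tf = TAU_TABLE[family]
        n = sizes[pre]
        lo, hi = 1.0 - cfg.jitter_frac, 1.0 + cfg.jitter_frac
        kinetics[cname] = SynapseKinetics(
            tr * rng.uniform(lo, hi, n), tf * rng.uniform(lo, hi, n), family
        )
        cond[cname] = ConductanceState.zeros(n)
    params = NetworkParams(
        cfg=cfg,
        conn=build_connectome(cfg),
        izh=izh,
        kinetics=kinetics,
        tchan_t=TChannelParams(cfg.a_t_ca, unit_scale=cfg.ca_unit_scale),
        tchan_r=TChannelParams(cfg.a_r_ca, unit_scale=cfg.ca_unit_scale),
    )
    state = NetworkState(
        pops=pops,
        cond=cond,
        tchan_t=TChannelState.at_rest(pops["t"].v),
        tchan_r=TChannelState.at_rest(pops["r"].v),
        p_t=np.ones(cfg.n_t),
    )
    return params, state


def mln_dendritic_input(
    v_m: np.ndarray,
    g_t: np.ndarray,
    g_cb: np.ndarray,
    conn: Connectome,
    cb_scale: float = 1.0,
) -> np.ndarray:
    """Thalamic drive onto middle-layer pyramids, proximal + distal branch.

    The proximal branch is a plain weighted AMPA drive.  On the distal
    branch the CB interneuron conductance is subtracted *inside* a rectified
    bracket, so CB inhibition can cancel distal excitation but can never
    spill onto the proximal branch nor invert the sign of the drive.
    """
    v_m = np.asarray(v_m, dtype=float)
    if conn.w_t_m_p.shape[0] != v_m.size:
        raise ValueError("v_m length does not match the connectome")
    drive = 0.0 - v_m
    proximal = drive * (conn.w_t_m_p @ g_t)
    distal = drive * np.maximum(
        conn.w_t_m_d @ g_t - cb_scale * (conn.w_cb_m @ g_cb), 0.0
    )
    return proximal + distal


def compute_currents(
    state: NetworkState,
    params: NetworkParams,
    mod: Modifiers = IDENTITY,
) -> dict[str, np.ndarray]:
    """Total input current per population, assembled from the current state.

    Structural contract: the CB and D populations receive no inhibitory
    term, the reticulo-thalamic GABA_B term is the only current scaled by
    the disinhibition factor P_T, and CB conductances enter only the
    rectified distal branch of the thalamo-cortical drive.
    """
    ncfg, conn = params.cfg, params.conn
    v = {p: state.pops[p].v for p in POPULATIONS}
    g = {c: state.cond[c].g for c in state.cond}
    i_ca_t = t_channel_current(state.tchan_t, v["t"], params.tchan_t)
    i_ca_r = t_channel_current(state.tchan_r, v["r"], params.tchan_r)
    i_t = (
        (0.0 - v["t"])
        * (
            ncfg.a_ext_ampa * g["ext_fast"]
            + ncfg.a_ext_nmda * nmda_gate(v["t"]) * g["ext_nmda"]
        )
        + (0.0 - v["t"]) * (conn.w_d_t @ g["d_fast"])
        + i_ca_t
        + state.p_t * (-90.0 - v["t"]) * (conn.w_r_t @ g["r_gabab"])
    )
    i_r = (
        (0.0 - v["r"]) * (conn.w_t_r @ g["t_fast"] + conn.w_d_r @ g["d_fast"])
        + i_ca_r
        + gap_current(conn.w_r_r_gap, v["r"])
        + mod.i_hyp
    )
    i_m = (
        mln_dendritic_input(v["m"], g["t_fast"], g["cb_fast"], conn, mod.cb_gaba_scale)
        + mod.pv_gaba_scale * (-70.0 - v["m"]) * (conn.w_pv_m @ g["pv"])
    )
    i_pv = (
        (0.0 - v["pv"])
        * (
            ncfg.a_m_pv_ampa * (conn.w_m_pv @ g["m_fast"])
            + mod.nmda_pv_scale
            * ncfg.a_m_pv_nmda
            * nmda_gate(v["pv"])
            * (conn.w_m_pv @ g["m_nmda"])
        )
        + mod.pv_gaba_scale * (-70.0 - v["pv"]) * (conn.w_pv_pv @ g["pv"])
    )
    i_cb = (0.0 - v["cb"]) * (
        ncfg.a_m_cb_ampa * (conn.w_m_cb @ g["m_fast"])
        + mod.nmda_cb_scale
        * ncfg.a_m_cb_nmda
        * nmda_gate(v["cb"])
        * (conn.w_m_cb @ g["m_nmda"])
    )
    i_d = (0.0 - v["d"]) * (conn.w_m_d @ g["m_fast"])
    return {"t": i_t, "r": i_r, "m": i_m, "pv": i_pv, "cb": i_cb, "d": i_d}


def step_network(
    state: NetworkState,
    params: NetworkParams,
    ext_spikes: np.ndarray,
    cfg: IntegratorConfig,
    mod: Modifiers = IDENTITY,
) -> NetworkState:
    """Advance the whole network one Euler step.

    Order: (1) all input currents from entry-state quantities, (2) advance
    conductances, T-channel gates and the plasticity factor, (3) advance
    membrane states, (4) detect and reset spikes.
    """
    ncfg, conn = params.cfg, params.conn
    currents = compute_currents(state, params, mod)
    tchan_t_new, _ = step_t_channel(
        state.tchan_t, state.pops["t"].v, params.tchan_t, cfg
    )
    tchan_r_new, _ = step_t_channel(
        state.tchan_r, state.pops["r"].v, params.tchan_r, cfg
    )

    ext_spikes = np.asarray(ext_spikes)
    cond_new = {}
    for cname, pre, _family in CONDUCTANCES:
        spikes = ext_spikes if pre == "ext" else state.pops[pre].spiked
        cond_new[cname] = step_sd_conductance(
            state.cond[cname], spikes, params.kinetics[cname], cfg
        )
    p_t_new = dstp_factor(
        cond_new["d_xslow"].g, conn.w_d_t, mod.a_stp_scale * ncfg.a_stp
    )

    pops_new = {
        p: step_izhikevich(state.pops[p], params.izh[p], currents[p], cfg)
        for p in POPULATIONS
    }
    return NetworkState(pops_new, cond_new, tchan_t_new, tchan_r_new, p_t_new)
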