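"""Fused compiled trial loop.

This mirrors :func:`crtsim.network.step_network` plus the task loop of
:func:`crtsim.task.run_trial` (same update order, same Mersenne-Twister
Poisson stream), so the compiled engine and the modular numpy engine produce
the same trajectories; an equivalence test holds them together at
spike-for-spike agreement over a short horizon (summation-order rounding
eventually decorrelates the chaotic spike trains over longer runs).

For speed, topographic Gaussian matrices are applied as banded products:
entries below ~1e-18 of the matrix peak are outside the band, a sub-ulp
truncation.  Keep this module in sync with network.py when editing either.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import IntegratorConfig, NetworkConfig
from .network import build_network, POPULATIONS, CONDUCTANCES
from .perturbations import PerturbationSpec

__all__ = ["run_trial_kernel"]


@njit(cache=True, fastmath=True)
def _banded_matvec(w, lo, hi, x, out):
    for r in range(out.size):
        s = 0.0
        for c in range(lo[r], hi[r]):
            s += w[r, c] * x[c]
        out[r] = s


@njit(cache=True)
def _sd_step(q, g, pulse, spk, tau_r, tau_f, coef, h, pulse_steps, pulse_mag):
    for i in range(q.size):
        pu = pulse_steps if spk[i] else pulse[i]
        k = pulse_mag if pu > 0 else 0.0
        qi = q[i]
        g_new = g[i] + h * (coef[i] * (1.0 - g[i]) * qi - g[i] / tau_f[i])
        q_new = qi + h * ((1.0 - qi) * k - qi / tau_r[i])
        # flush exponentially-decayed tails to exact zero (avoids denormals)
        g[i] = 0.0 if abs(g_new) < 1e-30 else g_new
        q[i] = 0.0 if abs(q_new) < 1e-30 else q_new
        pulse[i] = pu - 1 if pu > 0 else 0


@njit(cache=True)
def _izh_step(v, u, spiked, a, b, c, d, current, h):
    for i in range(v.size):
        vi, ui = v[i], u[i]
        v_new = vi + h * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + current[i])
        u_new = ui + h * a[i] * (b[i] * vi - ui)
        if v_new >= 30.0:
            spiked[i] = True
            v[i] = c[i]
            u[i] = u_new + d[i]
        else:
            spiked[i] = False
            v[i] = v_new
            u[i] = u_new


@njit(cache=True)
def _tchan_current_and_step(
    m, hh, ca, v, amp, p_ca, zf, rt, ca_ext, unit_scale, h_step, i_out
):
    """Channel current from the entry state; gates and calcium advanced."""
    for i in range(v.size):
        x = zf * (v[i] / 1000.0) / rt
        if abs(x) < 1e-5:
            flux = p_ca * zf * ((ca[i] - ca_ext) + x * (ca[i] + ca_ext) / 2.0)
        else:
            flux = p_ca * zf * x * (ca[i] - ca_ext * np.exp(-x)) / (1.0 - np.exp(-x))
        i_ca = -amp * unit_scale * m[i] * m[i] * hh[i] * flux
        i_out[i] = i_ca
        vi = v[i]
        m_inf = 1.0 / (1.0 + np.exp(-(vi + 79.0) / 6.2))
        h_inf = 1.0 / (1.0 + np.exp((vi + 92.0) / 4.0))
        tau_m = 0.999 + 0.333 / (
            np.exp((vi + 31.0) / 10.0) + np.exp(-(vi + 106.0) / 15.0)
        )
        tau_h = (
            30.8
            + (211.4 + np.exp((vi + 119.2) / 5.0)) / (1.0 + np.exp((vi + 90.0) / 3.2))
        ) / 3.7373
        m_new = m[i] + h_step * (m_inf - m[i]) / tau_m
        h_new = hh[i] + h_step * (h_inf - hh[i]) / tau_h
        m[i] = min(max(m_new, 0.0), 1.0)
        hh[i] = min(max(h_new, 0.0), 1.0)
        rect = i_ca if i_ca > 0.0 else 0.0
        dca = -(10.0 / zf) * rect - 0.2 * (ca[i] - 0.00024)
        ca_new = ca[i] + h_step * dca
        ca[i] = ca_new if ca_new > 1e-9 else 1e-9


@njit(cache=True)
def _record_spikes(spiked, step, buf_step, buf_idx, count, cap):
    for i in range(spiked.size):
        if spiked[i] and count < cap:
            buf_step[count] = step
            buf_idx[count] = i
            count += 1
    return count


@njit(cache=True)
def _simulate(
    n_steps, h, h_sc, stride, pulse_steps, pulse_mag,
    izh, v0, u0,                 # tuples over populations (t, r, m, pv, cb, d)
    kin,                         # tuple over CONDUCTANCES of (tau_r, tau_f, coef)
    wmats, wlo, whi,             # Gaussian matrices with band limits
    gap_rowsum, a_r_t,
    a_ext_ampa, a_ext_nmda, a_m_pv_ampa, a_m_pv_nmda, a_m_cb_ampa, a_m_cb_nmda,
    a_stp, amp_ca_t, amp_ca_r, p_ca, zf, rt, ca_ext, ca_unit_scale,
    m_t0, h_t0, ca_t0, m_r0, h_r0, ca_r0,
    task_is_fixation, pursuit_center, pursuit_amp, pursuit_freq, fixation_pos,
    has_distractor, distractor_pos, distractor_onset,
    rate_floor, rate_peak, bump_exp,
    x_c0, gaze_lo, gaze_hi, w_l_half, w_r_half,
    pert_onset, pert_offset, nmda_pv_s, nmda_cb_s, pv_gaba_s, cb_gaba_s,
    astp_s, i_hyp_s, poisson_seed,
    rec_eye, rec_mln, rec_pt,
    spk_step, spk_idx, spk_cap,
):
    np.random.seed(poisson_seed)
    (a_t, b_t, c_t, d_t) = izh[0]
    (a_r, b_r, c_r, d_r) = izh[1]
    (a_m, b_m, c_m, d_m) = izh[2]
    (a_pv, b_pv, c_pv, d_pv) = izh[3]
    (a_cb, b_cb, c_cb, d_cb) = izh[4]
    (a_d, b_d, c_d, d_d) = izh[5]
    v_t, v_r, v_m = v0[0].copy(), v0[1].copy(), v0[2].copy()
    v_pv, v_cb, v_d = v0[3].copy(), v0[4].copy(), v0[5].copy()
    u_t, u_r, u_m = u0[0].copy(), u0[1].copy(), u0[2].copy()
    u_pv, u_cb, u_d = u0[3].copy(), u0[4].copy(), u0[5].copy()
    # matrix order: d_t, t_m_p, t_m_d, m_d, t_r, d_r, m_pv, m_cb, pv_pv,
    #               pv_m, cb_m, r_r_gap
    (w_d_t, w_t_m_p, w_t_m_d, w_m_d, w_t_r, w_d_r,
     w_m_pv, w_m_cb, w_pv_pv, w_pv_m, w_cb_m, w_gap) = wmats
    n_t_pop, n_r_pop, n_m_pop = v_t.size, v_r.size, v_m.size
    n_pv_pop, n_cb_pop, n_d_pop = v_pv.size, v_cb.size, v_d.size
    half_m = n_m_pop // 2

    spk_t = np.zeros(n_t_pop, dtype=np.bool_)
    spk_r = np.zeros(n_r_pop, dtype=np.bool_)
    spk_m = np.zeros(n_m_pop, dtype=np.bool_)
    spk_pv = np.zeros(n_pv_pop, dtype=np.bool_)
    spk_cb = np.zeros(n_cb_pop, dtype=np.bool_)
    spk_d = np.zeros(n_d_pop, dtype=np.bool_)
    ext_spk = np.zeros(n_t_pop, dtype=np.bool_)

    # conductance states, ordered as CONDUCTANCES
    q_tf, g_tf, p_tf = np.zeros(n_t_pop), np.zeros(n_t_pop), np.zeros(n_t_pop, np.int64)
    q_rb, g_rb, p_rb = np.zeros(n_r_pop), np.zeros(n_r_pop), np.zeros(n_r_pop, np.int64)
    q_mf, g_mf, p_mf = np.zeros(n_m_pop), np.zeros(n_m_pop), np.zeros(n_m_pop, np.int64)
    q_mn, g_mn, p_mn = np.zeros(n_m_pop), np.zeros(n_m_pop), np.zeros(n_m_pop, np.int64)
    q_df, g_df, p_df = np.zeros(n_d_pop), np.zeros(n_d_pop), np.zeros(n_d_pop, np.int64)
    q_dx, g_dx, p_dx = np.zeros(n_d_pop), np.zeros(n_d_pop), np.zeros(n_d_pop, np.int64)
    q_pv, g_pv, p_pv = (
        np.zeros(n_pv_pop), np.zeros(n_pv_pop), np.zeros(n_pv_pop, np.int64),
    )
    q_cb, g_cb, p_cb = (
        np.zeros(n_cb_pop), np.zeros(n_cb_pop), np.zeros(n_cb_pop, np.int64),
    )
    q_ef, g_ef, p_ef = np.zeros(n_t_pop), np.zeros(n_t_pop), np.zeros(n_t_pop, np.int64)
    q_en, g_en, p_en = np.zeros(n_t_pop), np.zeros(n_t_pop), np.zeros(n_t_pop, np.int64)

    m_t, h_t, ca_t = m_t0.copy(), h_t0.copy(), ca_t0.copy()
    m_r, h_r, ca_r = m_r0.copy(), h_r0.copy(), ca_r0.copy()
    i_ca_t = np.zeros(n_t_pop)
    i_ca_r = np.zeros(n_r_pop)
    p_t_fac = np.ones(n_t_pop)
    g6 = np.zeros(n_d_pop)

    # matvec buffers
    mv_dt = np.zeros(n_t_pop)
    mv_tr = np.zeros(n_r_pop)
    mv_dr = np.zeros(n_r_pop)
    mv_gap = np.zeros(n_r_pop)
    mv_mp = np.zeros(n_m_pop)
    mv_md_ = np.zeros(n_m_pop)
    mv_cbm = np.zeros(n_m_pop)
    mv_pvm = np.zeros(n_m_pop)
    mv_mpv_f = np.zeros(n_pv_pop)
    mv_mpv_n = np.zeros(n_pv_pop)
    mv_pvpv = np.zeros(n_pv_pop)
    mv_mcb_f = np.zeros(n_cb_pop)
    mv_mcb_n = np.zeros(n_cb_pop)
    mv_md = np.zeros(n_d_pop)
    mv_stp = np.zeros(n_t_pop)

    i_t = np.zeros(n_t_pop)
    i_r = np.zeros(n_r_pop)
    i_m = np.zeros(n_m_pop)
    i_pv = np.zeros(n_pv_pop)
    i_cb = np.zeros(n_cb_pop)
    i_d = np.zeros(n_d_pop)

    rates_amp = rate_peak - rate_floor
    spk_counts = np.zeros(6, dtype=np.int64)
    x_c = x_c0

    for k in range(n_steps):
        t = k * h / 1000.0
        if task_is_fixation:
            x_target = fixation_pos
        else:
            x_target = pursuit_center + pursuit_amp * np.sin(
                2.0 * np.pi * pursuit_freq * t
            )
        dis_active = has_distractor and t >= distractor_onset

        if k % stride == 0:
            r = k // stride
            rec_eye[r] = x_c
            s = 0.0
            for i in range(n_m_pop):
                s += v_m[i]
            rec_mln[r] = s
            for i in range(n_t_pop):
                rec_pt[r, i] = p_t_fac[i]

        # --- external Poisson afferents (one uniform draw per afferent) ---
        for i in range(n_t_pop):
            u_pos = 0.5 * n_t_pop - (i + 1.0) - (x_c - x_target)
            if bump_exp == 4:
                u2 = u_pos * u_pos
                bump = np.exp(-(u2 * u2) / 2.0)
            else:
                bump = np.exp(-(u_pos * u_pos) / 2.0)
            if dis_active:
                u_pos = 0.5 * n_t_pop - (i + 1.0) - (x_c - distractor_pos)
                if bump_exp == 4:
                    u2 = u_pos * u_pos
                    bump_d = np.exp(-(u2 * u2) / 2.0)
                else:
                    bump_d = np.exp(-(u_pos * u_pos) / 2.0)
                if bump_d > bump:
                    bump = bump_d
            rate = rate_floor + rates_amp * bump
            if rate > rate_peak:
                rate = rate_peak
            ext_spk[i] = np.random.random() < rate * h / 1000.0

        pert_on = pert_onset <= t < pert_offset
        nmda_pv = nmda_pv_s if pert_on else 1.0
        nmda_cb = nmda_cb_s if pert_on else 1.0
        pv_gaba = pv_gaba_s if pert_on else 1.0
        cb_gaba = cb_gaba_s if pert_on else 1.0
        astp_eff = astp_s * a_stp if pert_on else a_stp
        i_hyp = i_hyp_s if pert_on else 0.0

        # --- input currents from entry-state quantities -------------------
        _tchan_current_and_step(
            m_t, h_t, ca_t, v_t, amp_ca_t, p_ca, zf, rt, ca_ext,
            ca_unit_scale, h, i_ca_t,
        )
        _tchan_current_and_step(
            m_r, h_r, ca_r, v_r, amp_ca_r, p_ca, zf, rt, ca_ext,
            ca_unit_scale, h, i_ca_r,
        )

        _banded_matvec(w_d_t, wlo[0], whi[0], g_df, mv_dt)
        _banded_matvec(w_t_m_p, wlo[1], whi[1], g_tf, mv_mp)
        _banded_matvec(w_t_m_d, wlo[2], whi[2], g_tf, mv_md_)
        _banded_matvec(w_m_d, wlo[3], whi[3], g_mf, mv_md)
        _banded_matvec(w_t_r, wlo[4], whi[4], g_tf, mv_tr)
        _banded_matvec(w_d_r, wlo[5], whi[5], g_df, mv_dr)
        _banded_matvec(w_m_pv, wlo[6], whi[6], g_mf, mv_mpv_f)
        _banded_matvec(w_m_pv, wlo[6], whi[6], g_mn, mv_mpv_n)
        _banded_matvec(w_m_cb, wlo[7], whi[7], g_mf, mv_mcb_f)
        _banded_matvec(w_m_cb, wlo[7], whi[7], g_mn, mv_mcb_n)
        _banded_matvec(w_pv_pv, wlo[8], whi[8], g_pv, mv_pvpv)
        _banded_matvec(w_pv_m, wlo[9], whi[9], g_pv, mv_pvm)
        _banded_matvec(w_cb_m, wlo[10], whi[10], g_cb, mv_cbm)
        _banded_matvec(w_gap, wlo[11], whi[11], v_r, mv_gap)

        # uniform all-to-all reticulo-thalamic inhibition
        g_rb_sum = 0.0
        for i in range(n_r_pop):
            g_rb_sum += g_rb[i]
        rt_drive = a_r_t * g_rb_sum

        for i in range(n_t_pop):
            vi = v_t[i]
            gate = 1.0 / (1.0 + 0.4202 * np.exp(-0.062 * vi))
            i_t[i] = (
                (0.0 - vi) * (a_ext_ampa * g_ef[i] + a_ext_nmda * gate * g_en[i])
                + (0.0 - vi) * mv_dt[i]
                + i_ca_t[i]
                + p_t_fac[i] * (-90.0 - vi) * rt_drive
            )
        for i in range(n_r_pop):
            vi = v_r[i]
            i_r[i] = (
                (0.0 - vi) * (mv_tr[i] + mv_dr[i])
                + i_ca_r[i]
                + (mv_gap[i] - gap_rowsum[i] * vi)
                + i_hyp
            )
        for i in range(n_m_pop):
            vi = v_m[i]
            distal = mv_md_[i] - cb_gaba * mv_cbm[i]
            if distal < 0.0:
                distal = 0.0
            i_m[i] = ((0.0 - vi) * mv_mp[i] + (0.0 - vi) * distal) + (
                pv_gaba * (-70.0 - vi) * mv_pvm[i]
            )
        for i in range(n_pv_pop):
            vi = v_pv[i]
            gate = 1.0 / (1.0 + 0.4202 * np.exp(-0.062 * vi))
            i_pv[i] = (
                (0.0 - vi)
                * (
                    a_m_pv_ampa * mv_mpv_f[i]
                    + nmda_pv * a_m_pv_nmda * gate * mv_mpv_n[i]
                )
                + pv_gaba * (-70.0 - vi) * mv_pvpv[i]
            )
        for i in range(n_cb_pop):
            vi = v_cb[i]
            gate = 1.0 / (1.0 + 0.4202 * np.exp(-0.062 * vi))
            i_cb[i] = (0.0 - vi) * (
                a_m_cb_ampa * mv_mcb_f[i] + nmda_cb * a_m_cb_nmda * gate * mv_mcb_n[i]
            )
        for i in range(n_d_pop):
            i_d[i] = (0.0 - v_d[i]) * mv_md[i]

        # --- conductances, plasticity -------------------------------------
        _sd_step(q_tf, g_tf, p_tf, spk_t, kin[0][0], kin[0][1], kin[0][2], h_sc, pulse_steps, pulse_mag)
        _sd_step(q_rb, g_rb, p_rb, spk_r, kin[1][0], kin[1][1], kin[1][2], h_sc, pulse_steps, pulse_mag)
        _sd_step(q_mf, g_mf, p_mf, spk_m, kin[2][0], kin[2][1], kin[2][2], h_sc, pulse_steps, pulse_mag)
        _sd_step(q_mn, g_mn, p_mn, spk_m, kin[3][0], kin[3][1], kin[3][2], h_sc, pulse_steps, pulse_mag)
        _sd_step(q_df, g_df, p_df, spk_d, kin[4][0], kin[4][1], kin[4][2], h_sc, pulse_steps, pulse_mag)
        _sd_step(q_dx, g_dx, p_dx, spk_d, kin[5][0], kin[5][1], kin[5][2], h_sc, pulse_steps, pulse_mag)
        _sd_step(q_pv, g_pv, p_pv, spk_pv, kin[6][0], kin[6][1], kin[6][2], h_sc, pulse_steps, pulse_mag)
        _sd_step(q_cb, g_cb, p_cb, spk_cb, kin[7][0], kin[7][1], kin[7][2], h_sc, pulse_steps, pulse_mag)
        _sd_step(q_ef, g_ef, p_ef, ext_spk, kin[8][0], kin[8][1], kin[8][2], h_sc, pulse_steps, pulse_mag)
        _sd_step(q_en, g_en, p_en, ext_spk, kin[9][0], kin[9][1], kin[9][2], h_sc, pulse_steps, pulse_mag)
        for i in range(n_d_pop):
            g2 = g_dx[i] * g_dx[i]
            g6[i] = g2 * g2 * g2
        _banded_matvec(w_d_t, wlo[0], whi[0], g6, mv_stp)
        for i in range(n_t_pop):
            p_t_fac[i] = 1.0 / (1.0 + astp_eff * mv_stp[i])

        # --- membrane updates and spike detection -------------------------
        _izh_step(v_t, u_t, spk_t, a_t, b_t, c_t, d_t, i_t, h_sc)
        _izh_step(v_r, u_r, spk_r, a_r, b_r, c_r, d_r, i_r, h_sc)
        _izh_step(v_m, u_m, spk_m, a_m, b_m, c_m, d_m, i_m, h_sc)
        _izh_step(v_pv, u_pv, spk_pv, a_pv, b_pv, c_pv, d_pv, i_pv, h_sc)
        _izh_step(v_cb, u_cb, spk_cb, a_cb, b_cb, c_cb, d_cb, i_cb, h_sc)
        _izh_step(v_d, u_d, spk_d, a_d, b_d, c_d, d_d, i_d, h_sc)

        spk_counts[0] = _record_spikes(spk_t, k + 1, spk_step[0], spk_idx[0], spk_counts[0], spk_cap)
        spk_counts[1] = _record_spikes(spk_r, k + 1, spk_step[1], spk_idx[1], spk_counts[1], spk_cap)
        spk_counts[2] = _record_spikes(spk_m, k + 1, spk_step[2], spk_idx[2], spk_counts[2], spk_cap)
        spk_counts[3] = _record_spikes(spk_pv, k + 1, spk_step[3], spk_idx[3], spk_counts[3], spk_cap)
        spk_counts[4] = _record_spikes(spk_cb, k + 1, spk_step[4], spk_idx[4], spk_counts[4], spk_cap)
        spk_counts[5] = _record_spikes(spk_d, k + 1, spk_step[5], spk_idx[5], spk_counts[5], spk_cap)

        # --- motor error readout and gaze update --------------------------
        l_sig = 0.0
        for i in range(half_m):
            l_sig += w_l_half[i] * g_mf[i]
        r_sig = 0.0
        for i in range(half_m, n_m_pop):
            r_sig += w_r_half[i - half_m] * g_mf[i]
        x_c = x_c + r_sig - l_sig
        if x_c < gaze_lo:
            x_c = gaze_lo
        elif x_c > gaze_hi:
            x_c = gaze_hi

    return spk_counts


def _band_limits(w: np.ndarray, rel_cutoff: float = 1e-18):
    """First/last significant column per row (sub-ulp truncation)."""
    thresh = rel_cutoff * np.abs(w).max()
    lo = np.empty(w.shape[0], dtype=np.int64)
    hi = np.empty(w.shape[0], dtype=np.int64)
    for r, row in enumerate(np.abs(w) > thresh):
        nz = np.nonzero(row)[0]
        lo[r], hi[r] = (nz[0], nz[-1] + 1) if nz.size else (0, 0)
    return lo, hi


def run_trial_kernel(
    task,
    perturb: PerturbationSpec,
    net_cfg: NetworkConfig,
    seed: int,
    int_cfg: IntegratorConfig,
):
    """Build the jittered network and run the compiled loop; returns a
    :class:`~crtsim.task.TrialRecord` matching the numpy engine's."""
    from .channels import FARADAY, GAS_CONSTANT
    from .task import (
        GAZE_BOUNDS,
        GAZE_START,
        TrialRecord,
        _trial_seeds,
        motor_weights,
        target_position,
    )

    jitter_rng, poisson_seed = _trial_seeds(seed)
    params, state = build_network(net_cfg, jitter_rng)
    conn = params.conn
    h = int_cfg.step_h
    stride = int_cfg.record_stride
    n_steps = round(task.duration * 1000.0 / h)
    n_rec = n_steps // stride

    izh = tuple(
        (params.izh[p].a, params.izh[p].b, params.izh[p].c, params.izh[p].d)
        for p in POPULATIONS
    )
    v0 = tuple(state.pops[p].v for p in POPULATIONS)
    u0 = tuple(state.pops[p].u for p in POPULATIONS)
    kin = tuple(
        (
            np.asarray(params.kinetics[c].tau_rise, dtype=float),
            np.asarray(params.kinetics[c].tau_fall, dtype=float),
            np.asarray(params.kinetics[c].rise_coefficient, dtype=float),
        )
        for c, _, _ in CONDUCTANCES
    )
    wmats = (
        conn.w_d_t, conn.w_t_m_p, conn.w_t_m_d, conn.w_m_d, conn.w_t_r,
        conn.w_d_r, conn.w_m_pv, conn.w_m_cb, conn.w_pv_pv, conn.w_pv_m,
        conn.w_cb_m, conn.w_r_r_gap,
    )
    limits = [_band_limits(w) for w in wmats]
    wlo = tuple(l for l, _ in limits)
    whi = tuple(hh for _, hh in limits)

    mod = perturb.modifiers()
    w_l, w_r = motor_weights(net_cfg.n_m)
    half = net_cfg.n_m // 2

    rec_eye = np.empty(n_rec)
    rec_mln = np.empty(n_rec)
    rec_pt = np.empty((n_rec, net_cfg.n_t))
    sizes = [net_cfg.n_t, net_cfg.n_r, net_cfg.n_m, net_cfg.n_pv, net_cfg.n_cb, net_cfg.n_d]
    spk_cap = int(max(sizes) * n_steps * h)  # ~1 kHz per neuron headroom
    spk_step = tuple(np.zeros(spk_cap, dtype=np.int64) for _ in range(6))
    spk_idx = tuple(np.zeros(spk_cap, dtype=np.int64) for _ in range(6))

    counts = _simulate(
        n_steps, h, int_cfg.scaled_step, stride, int_cfg.pulse_steps,
        int_cfg.spike_pulse_magnitude,
        izh, v0, u0, kin,
        wmats, wlo, whi,
        conn.w_r_r_gap.sum(axis=1), net_cfg.a_r_t,
        net_cfg.a_ext_ampa, net_cfg.a_ext_nmda,
        net_cfg.a_m_pv_ampa, net_cfg.a_m_pv_nmda,
        net_cfg.a_m_cb_ampa, net_cfg.a_m_cb_nmda,
        net_cfg.a_stp,
        params.tchan_t.amplitude, params.tchan_r.amplitude,
        params.tchan_t.p_ca, params.tchan_t.z * FARADAY,
        GAS_CONSTANT * params.tchan_t.temperature, params.tchan_t.ca_ext,
        params.tchan_t.unit_scale,
        state.tchan_t.m, state.tchan_t.h, state.tchan_t.ca_int,
        state.tchan_r.m, state.tchan_r.h, state.tchan_r.ca_int,
        task.kind == "fixation",
        task.pursuit_center, task.pursuit_amplitude, task.pursuit_freq,
        task.fixation_pos,
        task.distractor_pos is not None,
        task.distractor_pos if task.distractor_pos is not None else 0.0,
        task.distractor_onset,
        task.rate_floor, task.rate_peak, task.bump_exponent,
        GAZE_START, GAZE_BOUNDS[0], GAZE_BOUNDS[1],
        np.ascontiguousarray(w_l[:half]), np.ascontiguousarray(w_r[half:]),
        perturb.onset, perturb.offset,
        mod.nmda_pv_scale, mod.nmda_cb_scale, mod.pv_gaba_scale,
        mod.cb_gaba_scale, mod.a_stp_scale, mod.i_hyp,
        poisson_seed,
        rec_eye, rec_mln, rec_pt, spk_step, spk_idx, spk_cap,
    )

    time = np.arange(n_rec) * stride * h / 1000.0
    rec_target = np.asarray(target_position(task, time), dtype=float)
    rec_dis = np.full(n_rec, np.nan)
    if task.distractor_pos is not None:
        rec_dis[time >= task.distractor_onset] = task.distractor_pos
    spikes = {
        p: (
            spk_step[j][: counts[j]] * h / 1000.0,
            spk_idx[j][: counts[j]].copy(),
        )
        for j, p in enumerate(POPULATIONS)
    }
    return TrialRecord(
        time=time,
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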