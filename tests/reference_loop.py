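"""Scalar, loop-based reference implementation of one network step.

Written directly from the model equations with per-neuron Python loops and
no vectorization; used as an independent oracle against the vectorized
step.  It shares only the jittered parameter values and weight matrices
(as nested lists) with the implementation under test.
"""

from __future__ import annotations

import math

FARADAY = 96485.3
GAS_CONSTANT = 8.314


def _lists(a):
    return [list(r) for r in a] if getattr(a[0], "__len__", None) else list(a)


class ScalarReferenceNetwork:
    """Pure-Python CRT network stepping one Euler step at a time."""

    def __init__(self, params, state, int_cfg):
        cfg = params.cfg
        self.cfg = cfg
        self.h = int_cfg.step_h
        self.h_sc = int_cfg.step_h / int_cfg.tau_s
        self.pulse_steps = int_cfg.pulse_steps
        self.pulse_mag = int_cfg.spike_pulse_magnitude
        self.sizes = {
            "t": cfg.n_t, "r": cfg.n_r, "m": cfg.n_m,
            "pv": cfg.n_pv, "cb": cfg.n_cb, "d": cfg.n_d,
        }
        self.izh = {
            p: tuple(_lists(getattr(params.izh[p], f)) for f in "abcd")
            for p in self.sizes
        }
        self.v = {p: list(state.pops[p].v) for p in self.sizes}
        self.u = {p: list(state.pops[p].u) for p in self.sizes}
        self.spiked = {p: [False] * self.sizes[p] for p in self.sizes}
        conn = params.conn
        self.w = {
            name: _lists(getattr(conn, name))
            for name in (
                "w_d_t", "w_t_m_p", "w_t_m_d", "w_m_d", "w_t_r", "w_d_r",
                "w_m_pv", "w_m_cb", "w_pv_pv", "w_pv_m", "w_cb_m",
                "w_r_r_gap", "w_r_t",
            )
        }
        # conductances: name -> (pre pop or "ext", tau_r, tau_f, coef lists)
        self.kin = {}
        self.q = {}
        self.g = {}
        self.pulse = {}
        for name, kin in params.kinetics.items():
            n = len(kin.tau_rise)
            self.kin[name] = (
                list(kin.tau_rise),
                list(kin.tau_fall),
                list(kin.rise_coefficient),
            )
            self.q[name] = [0.0] * n
            self.g[name] = [0.0] * n
            self.pulse[name] = [0] * n
        self.pre_of = {
            "t_fast": "t", "r_gabab": "r", "m_fast": "m", "m_nmda": "m",
            "d_fast": "d", "d_xslow": "d", "pv": "pv", "cb_fast": "cb",
            "ext_fast": "ext", "ext_nmda": "ext",
        }
        self.tchan = {}
        for pop, tp, ts in (
            ("t", params.tchan_t, state.tchan_t),
            ("r", params.tchan_r, state.tchan_r),
        ):
            self.tchan[pop] = {
                "amp": tp.amplitude, "p_ca": tp.p_ca, "z": tp.z,
                "temp": tp.temperature, "ca_ext": tp.ca_ext,
                "scale": tp.unit_scale,
                "m": list(ts.m), "h": list(ts.h), "ca": list(ts.ca_int),
            }
        self.p_t = [1.0] * cfg.n_t

    # --- elementary pieces -------------------------------------------------
    @staticmethod
    def _nmda_gate(v):
        return 1.0 / (1.0 + 0.4202 * math.exp(-0.062 * v))

    def _ghk(self, ch, i, v):
        zf = ch["z"] * FARADAY
        x = zf * (v / 1000.0) / (GAS_CONSTANT * ch["temp"])
        ci, ce = ch["ca"][i], ch["ca_ext"]
        if abs(x) < 1e-5:
            return ch["p_ca"] * zf * ((ci - ce) + x * (ci + ce) / 2.0)
        return ch["p_ca"] * zf * x * (ci - ce * math.exp(-x)) / (1.0 - math.exp(-x))

    def _i_ca(self, pop, i):
        ch = self.tchan[pop]
        v = self.v[pop][i]
        return (
            -ch["amp"] * ch["scale"] * ch["m"][i] * ch["m"][i] * ch["h"][i]
            * self._ghk(ch, i, v)
        )

    def _wsum(self, wname, gname, j):
        w = self.w[wname]
        g = self.g[gname]
        return sum(w[j][i] * g[i] for i in range(len(g)))

    # --- one step ----------------------------------------------------------
    def step(self, ext_spikes, mod=None):
        from crtsim.perturbations import IDENTITY

        mod = mod or IDENTITY
        cfg = self.cfg
        currents = {}

        i_t = []
        for j in range(cfg.n_t):
            v = self.v["t"][j]
            ext = (
                cfg.a_ext_ampa * self.g["ext_fast"][j]
                + cfg.a_ext_nmda * self._nmda_gate(v) * self.g["ext_nmda"][j]
            )
            i_t.append(
                (0.0 - v) * ext
                + (0.0 - v) * self._wsum("w_d_t", "d_fast", j)
                + self._i_ca("t", j)
                + self.p_t[j] * (-90.0 - v) * self._wsum("w_r_t", "r_gabab", j)
            )
        currents["t"] = i_t

        i_r = []
        for j in range(cfg.n_r):
            v = self.v["r"][j]
            gap = sum(
                self.w["w_r_r_gap"][j][i] * (self.v["r"][i] - v)
                for i in range(cfg.n_r)
            )
            i_r.append(
                (0.0 - v)
                * (self._wsum("w_t_r", "t_fast", j) + self._wsum("w_d_r", "d_fast", j))
                + self._i_ca("r", j)
                + gap
                + mod.i_hyp
            )
        currents["r"] = i_r

        i_m = []
        for j in range(cfg.n_m):
            v = self.v["m"][j]
            distal = self._wsum("w_t_m_d", "t_fast", j) - mod.cb_gaba_scale * self._wsum(
                "w_cb_m", "cb_fast", j
            )
            if distal < 0.0:
                distal = 0.0
            i_m.append(
                (0.0 - v) * self._wsum("w_t_m_p", "t_fast", j)
                + (0.0 - v) * distal
                + mod.pv_gaba_scale * (-70.0 - v) * self._wsum("w_pv_m", "pv", j)
            )
        currents["m"] = i_m

        i_pv = []
        for j in range(cfg.n_pv):
            v = self.v["pv"][j]
            i_pv.append(
                (0.0 - v)
                * (
                    cfg.a_m_pv_ampa * self._wsum("w_m_pv", "m_fast", j)
                    + mod.nmda_pv_scale
                    * cfg.a_m_pv_nmda
                    * self._nmda_gate(v)
                    * self._wsum("w_m_pv", "m_nmda", j)
                )
                + mod.pv_gaba_scale * (-70.0 - v) * self._wsum("w_pv_pv", "pv", j)
            )
        currents["pv"] = i_pv

        i_cb = []
        for j in range(cfg.n_cb):
            v = self.v["cb"][j]
            i_cb.append(
                (0.0 - v)
                * (
                    cfg.a_m_cb_ampa * self._wsum("w_m_cb", "m_fast", j)
                    + mod.nmda_cb_scale
                    * cfg.a_m_cb_nmda
                    * self._nmda_gate(v)
                    * self._wsum("w_m_cb", "m_nmda", j)
                )
            )
        currents["cb"] = i_cb

        currents["d"] = [
            (0.0 - self.v["d"][j]) * self._wsum("w_m_d", "m_fast", j)
            for j in range(cfg.n_d)
        ]

        # conductances
        for name, (tau_r, tau_f, coef) in self.kin.items():
            pre = self.pre_of[name]
            spk = ext_spikes if pre == "ext" else self.spiked[pre]
            q, g, pulse = self.q[name], self.g[name], self.pulse[name]
            for i in range(len(q)):
                pu = self.pulse_steps if spk[i] else pulse[i]
                k = self.pulse_mag if pu > 0 else 0.0
                qi = q[i]
                g_new = g[i] + self.h_sc * (
                    coef[i] * (1.0 - g[i]) * qi - g[i] / tau_f[i]
                )
                q_new = qi + self.h_sc * ((1.0 - qi) * k - qi / tau_r[i])
                g[i] = 0.0 if abs(g_new) < 1e-30 else g_new
                q[i] = 0.0 if abs(q_new) < 1e-30 else q_new
                pulse[i] = pu - 1 if pu > 0 else 0

        # T-channel gates and calcium
        for pop in ("t", "r"):
            ch = self.tchan[pop]
            zf = ch["z"] * FARADAY
            for i in range(self.sizes[pop]):
                v = self.v[pop][i]
                i_ca = self._i_ca(pop, i)
                m_inf = 1.0 / (1.0 + math.exp(-(v + 79.0) / 6.2))
                h_inf = 1.0 / (1.0 + math.exp((v + 92.0) / 4.0))
                tau_m = 0.999 + 0.333 / (
                    math.exp((v + 31.0) / 10.0) + math.exp(-(v + 106.0) / 15.0)
                )
                tau_h = (
                    30.8
                    + (211.4 + math.exp((v + 119.2) / 5.0))
                    / (1.0 + math.exp((v + 90.0) / 3.2))
                ) / 3.7373
                ch["m"][i] = min(
                    max(ch["m"][i] + self.h * (m_inf - ch["m"][i]) / tau_m, 0.0), 1.0
                )
                ch["h"][i] = min(
                    max(ch["h"][i] + self.h * (h_inf - ch["h"][i]) / tau_h, 0.0), 1.0
                )
                rect = i_ca if i_ca > 0.0 else 0.0
                dca = -(10.0 / zf) * rect - 0.2 * (ch["ca"][i] - 0.00024)
                ca_new = ch["ca"][i] + self.h * dca
                ch["ca"][i] = ca_new if ca_new > 1e-9 else 1e-9

        # disinhibition factor
        astp = mod.a_stp_scale * cfg.a_stp
        gx = self.g["d_xslow"]
        for j in range(cfg.n_t):
            drive = 0.0
            for i in range(cfg.n_d):
                g2 = gx[i] * gx[i]
                drive += self.w["w_d_t"][j][i] * (g2 * g2 * g2)
            self.p_t[j] = 1.0 / (1.0 + astp * drive)

        # membranes
        for pop in self.sizes:
            a, b, c, d = self.izh[pop]
            v, u, spk = self.v[pop], self.u[pop], self.spiked[pop]
            cur = currents[pop]
            for i in range(len(v)):
                vi, ui = v[i], u[i]
                v_new = vi + self.h_sc * (
                    0.04 * vi * vi + 5.0 * vi + 140.0 - ui + cur[i]
                )
                u_new = ui + self.h_sc * a[i] * (b[i] * vi - ui)
                if v_new >= 30.0:
                    spk[i] = True
                    v[i] = c[i]
                    u[i] = u_new + d[i]
                else:
                    spk[i] = False
                    v[i] = v_new
                    u[i] = u_new
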