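"""Compiled fixed-step RK4 integration core.

The whole network state is packed into one flat vector ``y``:

    [ V(0..C-1) | m | h | n | w | q | s(0..G-1) ]

with ``C`` compartments and ``G`` synaptic gates.  Synaptic gates are
deduplicated: the gate ODE depends only on the presynaptic voltage and the
receptor time constants, so all edges sharing (presynaptic cell, receptor)
share a single gate, while the edge list keeps per-edge conductance and
reversal.

Gate steady states and (inverse) time constants are evaluated through
piecewise-linear lookup tables on a 0.02 mV grid over [-130, 70] mV, built
once from :mod:`betacol.kinetics`; the interpolation error is orders of
magnitude below the integration error at dt = 0.01 ms.  External EPSC-train
arrivals are snapped to the integration grid and applied at step boundaries
either as superposed conductance increments (default) or as saturating
resets to g_max; within a step the train conductance decays exactly
(exponential factors at the RK4 stage times).

Instantaneous activation gates (NaF ``m`` of the ``inh`` and ``fs``
families) are evaluated algebraically from the stage voltage; their slots in
the state vector are unused.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import kinetics as kin
from .synapses import presyn_drive

# lookup-table grid
LUT_V0 = -130.0
LUT_V1 = 70.0
LUT_DV = 0.02
LUT_N = int(round((LUT_V1 - LUT_V0) / LUT_DV)) + 1
LUT_INV_DV = 1.0 / LUT_DV

# row layout of the kinetics lookup table (inf rows even, inverse-tau odd)
R_M_INF_EXC, R_M_ITAU_EXC = 0, 1
R_H_INF_EXC, R_H_ITAU_EXC = 2, 3
R_N_INF_EXC, R_N_ITAU_EXC = 4, 5
R_M_INF_INH = 6
R_H_INF_INH, R_H_ITAU_INH = 7, 8
R_N_INF_INH, R_N_ITAU_INH = 9, 10
R_M_INF_FS = 11
R_H_INF_FS, R_H_ITAU_FS = 12, 13
R_N_INF_FS, R_N_ITAU_FS = 14, 15
R_W_INF, R_W_ITAU = 16, 17
R_Q_INF, R_Q_ITAU = 18, 19
R_DRIVE = 20
N_ROWS = 21

FAM_EXC, FAM_INH, FAM_FS = 0, 1, 2

SPIKE_THRESH = 0.0
SPIKE_DEAD_MS = 2.0
V_DIVERGE = 200.0


def build_lut() -> np.ndarray:
    """Evaluate the kinetics table on the voltage grid."""
    v = LUT_V0 + LUT_DV * np.arange(LUT_N)
    lut = np.empty((N_ROWS, LUT_N))

    def put(inf_row, itau_row, gate, family):
        x_inf, tau = kin.gate_steady_state(v, kin.GateKinetics(gate, family))
        lut[inf_row] = x_inf
        if itau_row is not None:
            lut[itau_row] = 1.0 / tau

    put(R_M_INF_EXC, R_M_ITAU_EXC, "m", "exc")
    put(R_H_INF_EXC, R_H_ITAU_EXC, "h", "exc")
    put(R_N_INF_EXC, R_N_ITAU_EXC, "n", "exc")
    put(R_M_INF_INH, None, "m", "inh")
    put(R_H_INF_INH, R_H_ITAU_INH, "h", "inh")
    put(R_N_INF_INH, R_N_ITAU_INH, "n", "inh")
    put(R_M_INF_FS, None, "m", "fs")
    put(R_H_INF_FS, R_H_ITAU_FS, "h", "fs")
    put(R_N_INF_FS, R_N_ITAU_FS, "n", "fs")
    put(R_W_INF, R_W_ITAU, "w", "exc")
    put(R_Q_INF, R_Q_ITAU, "q", "exc")
    lut[R_DRIVE] = presyn_drive(v)
    return lut


@njit(inline="always")
def _lv(row, v):
    x = (v - LUT_V0) * LUT_INV_DV
    if x < 0.0:
        x = 0.0
    elif x > LUT_N - 1.000001:
        x = LUT_N - 1.000001
    i = int(x)
    f = x - i
    return row[i] + (row[i + 1] - row[i]) * f


@njit(cache=True, fastmath=True)
def _rhs(
    y,
    dy,
    lut,
    n_comp,
    fam,
    g_naf,
    g_kdr,
    g_leak,
    g_m,
    g_cah,
    e_na,
    e_k,
    e_leak,
    e_ca,
    inv_c,
    i_tonic,
    cpl_a,
    cpl_b,
    cpl_g,
    gate_pre,
    gate_inv_tr,
    gate_inv_td,
    edge_gate,
    edge_post,
    edge_g,
    edge_e,
    edge_mg,
    att_post,
    g_att,
    att_fac,
    i_acc,
):
    off_s = 6 * n_comp
    # synaptic gate dynamics, driven by presynaptic voltage
    for g in range(gate_pre.shape[0]):
        d = _lv(lut[R_DRIVE], y[gate_pre[g]])
        s = y[off_s + g]
        dy[off_s + g] = d * (1.0 - s) * gate_inv_tr[g] - s * gate_inv_td[g]

    # net membrane current accumulator (inward positive)
    for i in range(n_comp):
        i_acc[i] = 0.0
    for e in range(edge_gate.shape[0]):
        p = edge_post[e]
        cur = edge_g[e] * y[off_s + edge_gate[e]] * (y[p] - edge_e[e])
        if edge_mg[e] == 1:
            # optional NMDA magnesium block (1 mM)
            cur /= 1.0 + 0.2801 * np.exp(-0.062 * y[p])
        i_acc[p] -= cur
    for a in range(att_post.shape[0]):
        p = att_post[a]
        i_acc[p] -= g_att[a] * att_fac * y[p]  # E_rev = 0 mV
    for c in range(cpl_a.shape[0]):
        d = cpl_g[c] * (y[cpl_b[c]] - y[cpl_a[c]])
        i_acc[cpl_a[c]] += d
        i_acc[cpl_b[c]] -= d

    for i in range(n_comp):
        v = y[i]
        fa = fam[i]
        h = y[2 * n_comp + i]
        n = y[3 * n_comp + i]
        if fa == FAM_EXC:
            m = y[n_comp + i]
            dy[n_comp + i] = (_lv(lut[R_M_INF_EXC], v) - m) * _lv(lut[R_M_ITAU_EXC], v)
            dy[2 * n_comp + i] = (_lv(lut[R_H_INF_EXC], v) - h) * _lv(lut[R_H_ITAU_EXC], v)
            dy[3 * n_comp + i] = (_lv(lut[R_N_INF_EXC], v) - n) * _lv(lut[R_N_ITAU_EXC], v)
        elif fa == FAM_INH:
            m = _lv(lut[R_M_INF_INH], v)
            dy[n_comp + i] = 0.0
            dy[2 * n_comp + i] = (_lv(lut[R_H_INF_INH], v) - h) * _lv(lut[R_H_ITAU_INH], v)
            dy[3 * n_comp + i] = (_lv(lut[R_N_INF_INH], v) - n) * _lv(lut[R_N_ITAU_INH], v)
        else:
            m = _lv(lut[R_M_INF_FS], v)
            dy[n_comp + i] = 0.0
            dy[2 * n_comp + i] = (_lv(lut[R_H_INF_FS], v) - h) * _lv(lut[R_H_ITAU_FS], v)
            dy[3 * n_comp + i] = (_lv(lut[R_N_INF_FS], v) - n) * _lv(lut[R_N_ITAU_FS], v)

        i_ion = g_leak[i] * (v - e_leak[i])
        i_ion += g_naf[i] * m * m * m * h * (v - e_na[i])
        n2 = n * n
        i_ion += g_kdr[i] * n2 * n2 * (v - e_k[i])
        if g_m[i] > 0.0:
            w = y[4 * n_comp + i]
            i_ion += g_m[i] * w * (v - e_k[i])
            dy[4 * n_comp + i] = (_lv(lut[R_W_INF], v) - w) * _lv(lut[R_W_ITAU], v)
        else:
            dy[4 * n_comp + i] = 0.0
        if g_cah[i] > 0.0:
            q = y[5 * n_comp + i]
            i_ion += g_cah[i] * q * q * (v - e_ca[i])
            dy[5 * n_comp + i] = (_lv(lut[R_Q_INF], v) - q) * _lv(lut[R_Q_ITAU], v)
        else:
            dy[5 * n_comp + i] = 0.0

        dy[i] = (-i_ion - i_tonic[i] + i_acc[i]) * inv_c[i]


@njit(cache=True, fastmath=True)
def run_network(
    y,
    lut,
    n_comp,
    fam,
    g_naf,
    g_kdr,
    g_leak,
    g_m,
    g_cah,
    e_na,
    e_k,
    e_leak,
    e_ca,
    inv_c,
    i_tonic,
    cpl_a,
    cpl_b,
    cpl_g,
    gate_pre,
    gate_inv_tr,
    gate_inv_td,
    edge_gate,
    edge_post,
    edge_g,
    edge_e,
    edge_mg,
    att_post,
    att_gmax,
    att_mode,
    g_att,
    dec_half,
    dec_full,
    ev_step,
    ev_att,
    dt,
    n_steps,
    det_comp,
    spike_cell_slot,
    spike_t,
    max_spikes,
    lfp_edge_idx,
    lfp_att_idx,
    lfp_slot,
    lfp_out,
    rec_stride,
    lfp_on,
    v_out,
    v_stride,
):
    """Advance the packed state ``y`` by ``n_steps`` RK4 steps.

    Returns (n_spikes, err_comp, err_step); err_comp >= 0 flags divergence.
    """
    n_state = y.shape[0]
    k1 = np.empty(n_state)
    k2 = np.empty(n_state)
    k3 = np.empty(n_state)
    k4 = np.empty(n_state)
    yt = np.empty(n_state)
    i_acc = np.empty(n_comp)
    n_det = det_comp.shape[0]
    v_prev = np.empty(n_det)
    last_spike = np.full(n_det, -1.0e9)
    n_spikes = 0
    ep = 0
    n_ev = ev_step.shape[0]
    half = 0.5 * dt
    sixth = dt / 6.0

    # sample 0 at t = 0
    if lfp_on:
        _record_lfp(y, n_comp, edge_gate, edge_post, edge_g, edge_e, edge_mg, att_post, g_att, lfp_edge_idx, lfp_att_idx, lfp_slot, lfp_out, 0)
    if v_stride > 0:
        for i in range(n_comp):
            v_out[0, i] = y[i]

    for istep in range(n_steps):
        # EPSC arrivals snapped to this step boundary: superposed exponentials
        # (mode 0) or saturating reset to g_max (mode 1)
        while ep < n_ev and ev_step[ep] == istep:
            a = ev_att[ep]
            if att_mode[a] == 0:
                g_att[a] += att_gmax[a]
            else:
                g_att[a] = att_gmax[a]
            ep += 1

        for i in range(n_det):
            v_prev[i] = y[det_comp[i]]

        _rhs(y, k1, lut, n_comp, fam, g_naf, g_kdr, g_leak, g_m, g_cah, e_na, e_k, e_leak, e_ca, inv_c, i_tonic, cpl_a, cpl_b, cpl_g, gate_pre, gate_inv_tr, gate_inv_td, edge_gate, edge_post, edge_g, edge_e, edge_mg, att_post, g_att, 1.0, i_acc)
        for i in range(n_state):
            yt[i] = y[i] + half * k1[i]
        _rhs(yt, k2, lut, n_comp, fam, g_naf, g_kdr, g_leak, g_m, g_cah, e_na, e_k, e_leak, e_ca, inv_c, i_tonic, cpl_a, cpl_b, cpl_g, gate_pre, gate_inv_tr, gate_inv_td, edge_gate, edge_post, edge_g, edge_e, edge_mg, att_post, g_att, dec_half, i_acc)
        for i in range(n_state):
            yt[i] = y[i] + half * k2[i]
        _rhs(yt, k3, lut, n_comp, fam, g_naf, g_kdr, g_leak, g_m, g_cah, e_na, e_k, e_leak, e_ca, inv_c, i_tonic, cpl_a, cpl_b, cpl_g, gate_pre, gate_inv_tr, gate_inv_td, edge_gate, edge_post, edge_g, edge_e, edge_mg, att_post, g_att, dec_half, i_acc)
        for i in range(n_state):
            yt[i] = y[i] + dt * k3[i]
        _rhs(yt, k4, lut, n_comp, fam, g_naf, g_kdr, g_leak, g_m, g_cah, e_na, e_k, e_leak, e_ca, inv_c, i_tonic, cpl_a, cpl_b, cpl_g, gate_pre, gate_inv_tr, gate_inv_td, edge_gate, edge_post, edge_g, edge_e, edge_mg, att_post, g_att, dec_full, i_acc)
        for i in range(n_state):
            y[i] += sixth * (k1[i] + 2.0 * (k2[i] + k3[i]) + k4[i])

        # clamp gates and synaptic open fractions to [0, 1]
        for i in range(n_comp, n_state):
            if y[i] < 0.0:
                y[i] = 0.0
            elif y[i] > 1.0:
                y[i] = 1.0

        for a in range(g_att.shape[0]):
            g_att[a] *= dec_full

        t_next = (istep + 1) * dt
        for i in range(n_det):
            v_new = y[det_comp[i]]
            if v_prev[i] < SPIKE_THRESH and v_new >= SPIKE_THRESH:
                t_cross = t_next - dt + dt * (SPIKE_THRESH - v_prev[i]) / (v_new - v_prev[i])
                if t_cross - last_spike[i] >= SPIKE_DEAD_MS:
                    last_spike[i] = t_cross
                    if n_spikes < max_spikes:
                        spike_cell_slot[n_spikes] = i
                        spike_t[n_spikes] = t_cross
                        n_spikes += 1

        if (istep + 1) % rec_stride == 0:
            k = (istep + 1) // rec_stride
            for i in range(n_comp):
                v = y[i]
                if not np.isfinite(v) or v > V_DIVERGE or v < -V_DIVERGE:
                    return n_spikes, i, istep + 1
            if lfp_on:
                _record_lfp(y, n_comp, edge_gate, edge_post, edge_g, edge_e, edge_mg, att_post, g_att, lfp_edge_idx, lfp_att_idx, lfp_slot, lfp_out, k)
        if v_stride > 0 and (istep + 1) % v_stride == 0:
            kv = (istep + 1) // v_stride
            for i in range(n_comp):
                v_out[kv, i] = y[i]

    return n_spikes, -1, -1


@njit(cache=True, fastmath=True)
def _record_lfp(y, n_comp, edge_gate, edge_post, edge_g, edge_e, edge_mg, att_post, g_att, lfp_edge_idx, lfp_att_idx, lfp_slot, lfp_out, k):
    """Summed synaptic current onto each recorded cell (outward positive),
    including external EPSC-train currents."""
    off_s = 6 * n_comp
    for j in range(lfp_edge_idx.shape[0]):
        e = lfp_edge_idx[j]
        p = edge_post[e]
        cur = edge_g[e] * y[off_s + edge_gate[e]] * (y[p] - edge_e[e])
        if edge_mg[e] == 1:
            cur /= 1.0 + 0.2801 * np.exp(-0.062 * y[p])
        lfp_out[lfp_slot[p], k] += cur
    for j in range(lfp_att_idx.shape[0]):
        a = lfp_att_idx[j]
        p = att_post[a]
        lfp_out[lfp_slot[p], k] += g_att[a] * y[p]
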