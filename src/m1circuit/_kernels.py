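"""Numba kernels for the network integrator.

Units: mV, ms, nA, uS, nF, mM.  The voltage step is a theta-method implicit
solve (theta = 0.5, Crank-Nicolson-like) of the cable equation on each
cell's compartment tree via Hines elimination; channel gates advance by
exponential Euler on precomputed voltage-indexed lookup tables; synaptic
receptors are aggregated double-exponential conductances per (receptor kind,
compartment), incremented event-wise through a delay ring buffer.

Gate/channel model (shared kinetics, per-class conductance densities):
  Na: m^3 h, Kdr: n, Ka: a b, Kd: c d, HCN: q (+ proportional shunt),
  CaL: e^2, CaN: f^2, KCa: ca/(ca+kd) with a single-pool Ca2+ ladder.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Gate enumeration for the lookup tables.
GATE_NAMES = ("na_m", "na_h", "kdr_n", "ka_a", "ka_b", "kd_c", "kd_d", "hcn_q", "cal_e", "can_f")
N_GATES = len(GATE_NAMES)

# Receptor kinds.
KIND_AMPA, KIND_NMDA, KIND_GA_FAST, KIND_GA_SLOW, KIND_GABAB = 0, 1, 2, 3, 4
N_KINDS = 5

V_MIN, V_MAX, V_STEP = -120.0, 60.0, 0.05

# Ca2+ pool constants: resting level and relaxation time; phi converts nA of
# Ca current on a compartment of unit area into mM/ms (divided by area when
# packing).
CA_REST_MM = 5.0e-5
CA_TAU_MS = 80.0
CA_GAMMA = 1.0e-8  # mM * cm^2 / (nA * ms)
KCA_KD_MM = 5.0e-4


def _bell(v, amp, vmid, k1, k2, floor):
    return floor + amp / (np.exp((v - vmid) / k1) + np.exp(-(v - vmid) / k2))


def gate_tables(dt_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Lookup tables (xinf, exp(-dt/tau)) for each gate on the V grid."""
    v = np.arange(V_MIN, V_MAX + V_STEP / 2, V_STEP)
    xinf = np.empty((N_GATES, v.size))
    tau = np.empty((N_GATES, v.size))

    def sig(vh, k):
        return 1.0 / (1.0 + np.exp(-(v - vh) / k))

    xinf[0] = sig(-38.0, 6.0)          # Na m
    tau[0] = _bell(v, 0.25, -38.0, 16.0, 16.0, 0.08)
    xinf[1] = sig(-53.0, -7.0)         # Na h
    tau[1] = _bell(v, 6.0, -57.0, 10.0, 12.0, 0.3)
    xinf[2] = sig(-18.0, 6.0)          # Kdr n
    tau[2] = _bell(v, 3.0, -25.0, 14.0, 16.0, 0.5)
    xinf[3] = sig(-35.0, 12.0)         # Ka a
    tau[3] = _bell(v, 0.6, -40.0, 20.0, 20.0, 0.4)
    xinf[4] = sig(-75.0, -5.0)         # Ka b
    tau[4] = np.full_like(v, 20.0)
    xinf[5] = sig(-50.0, 10.0)         # Kd c
    tau[5] = np.full_like(v, 2.0)
    xinf[6] = sig(-65.0, -7.0)         # Kd d
    tau[6] = np.full_like(v, 800.0)
    xinf[7] = sig(-82.0, -8.0)         # HCN q
    tau[7] = _bell(v, 180.0, -80.0, 12.0, 12.0, 25.0)
    xinf[8] = sig(-30.0, 6.0)          # CaL e
    tau[8] = np.full_like(v, 2.0)
    xinf[9] = sig(-25.0, 7.0)          # CaN f
    tau[9] = np.full_like(v, 1.5)

    edt = np.exp(-dt_ms / tau)
    return xinf, edt


@njit(cache=True, inline="always")
def _tab(table, gate, vv):
    """Linear interpolation of a gate table at voltage vv."""
    x = (vv - V_MIN) / V_STEP
    if x < 0.0:
        x = 0.0
    nmax = table.shape[1] - 1
    if x > nmax - 1e-9:
        x = nmax - 1e-9
    i = int(x)
    f = x - i
    return table[gate, i] * (1.0 - f) + table[gate, i + 1] * f


@njit(cache=True)
def run_kernel(
    n_steps,
    dt,
    theta,
    # tree structure
    parent, cm_nf, g_ax,
    # channel conductances (uS, absolute) and reversals
    g_leak, g_na, g_kdr, g_ka, g_kd, g_hcn, g_cal, g_can, g_kca, shunt_gain,
    e_leak, e_na, e_k, e_ca, e_h, e_shunt_arr,
    # per-channel compartment lists
    na_c, kdr_c, ka_c, kd_c, hcn_c, cal_c, can_c, ca_c,
    # Ca pool
    ca_phi,
    # gate tables
    xinf_t, edt_t,
    # synapse state
    syn_ar, syn_ad, syn_nf, syn_erev, mg_scale,
    # local fanout CSR (per presynaptic cell)
    lf_ptr, lf_comp, lf_kind, lf_g, lf_dstep,
    # long-range events (sorted by step) and unit fanout CSR
    lr_step, lr_unit, uf_ptr, uf_comp, uf_kind, uf_g, uf_dstep,
    # external events (sorted by step): delivered directly
    ex_step, ex_comp, ex_kind, ex_g,
    # current injections
    inj_comp, inj_amp, inj_start, inj_stop,
    # cells and spikes
    soma_comp, cell_of_comp, refr_steps,
    # recording
    v_rec_idx, v_stride, i_stride,
    # outputs
    v0,
):
    nc = parent.shape[0]
    ncell = soma_comp.shape[0]

    V = v0.copy()
    gates = np.empty((N_GATES, nc))
    for g in range(N_GATES):
        for c in range(nc):
            gates[g, c] = _tab(xinf_t, g, V[c])
    ca = np.full(nc, CA_REST_MM)
    A = np.zeros((N_KINDS, nc))
    B = np.zeros((N_KINDS, nc))

    # delay ring buffer
    max_d = 1
    for i in range(lf_dstep.shape[0]):
        if lf_dstep[i] > max_d:
            max_d = lf_dstep[i]
    for i in range(uf_dstep.shape[0]):
        if uf_dstep[i] > max_d:
            max_d = uf_dstep[i]
    ring_len = max_d + 1
    acc = np.zeros((ring_len, N_KINDS, nc))

    # spike buffer
    cap = max(100000, ncell * 64)
    spk_cell = np.empty(cap, np.int32)
    spk_time = np.empty(cap, np.float64)
    n_spk = 0
    last_spike = np.full(ncell, -10**9, np.int64)

    # recording buffers
    n_vrec = v_rec_idx.shape[0]
    nv_samp = (n_steps - 1) // v_stride + 1 if n_steps > 0 else 0
    v_out = np.zeros((nv_samp, n_vrec))
    ni_samp = (n_steps - 1) // i_stride + 1 if n_steps > 0 else 0
    i_out = np.zeros((ni_samp, nc), np.float32)
    t_i = np.zeros(ni_samp)

    diag = np.empty(nc)
    rhs = np.empty(nc)
    gtot = np.empty(nc)
    ge = np.empty(nc)
    imem = np.empty(nc)

    lr_i = 0
    ex_i = 0
    n_lr = lr_step.shape[0]
    n_ex = ex_step.shape[0]
    status = 0

    for s in range(n_steps):
        slot = s % ring_len
        # a) deliver events scheduled for this step
        for k in range(N_KINDS):
            for c in range(nc):
                w = acc[slot, k, c]
                if w != 0.0:
                    A[k, c] += w
                    B[k, c] += w
                    acc[slot, k, c] = 0.0
        while lr_i < n_lr and lr_step[lr_i] == s:
            u = lr_unit[lr_i]
            for j in range(uf_ptr[u], uf_ptr[u + 1]):
                tgt = (s + uf_dstep[j]) % ring_len
                acc[tgt, uf_kind[j], uf_comp[j]] += uf_g[j]
            lr_i += 1
        while ex_i < n_ex and ex_step[ex_i] == s:
            A[ex_kind[ex_i], ex_comp[ex_i]] += ex_g[ex_i]
            B[ex_kind[ex_i], ex_comp[ex_i]] += ex_g[ex_i]
            ex_i += 1

        # b+c) gates (exponential Euler at V_t)
        for ii in range(na_c.shape[0]):
            c = na_c[ii]
            vv = V[c]
            m = gates[0, c]
            gates[0, c] = m + (_tab(xinf_t, 0, vv) - m) * (1.0 - _tab(edt_t, 0, vv))
            h = gates[1, c]
            gates[1, c] = h + (_tab(xinf_t, 1, vv) - h) * (1.0 - _tab(edt_t, 1, vv))
        for ii in range(kdr_c.shape[0]):
            c = kdr_c[ii]
            vv = V[c]
            n = gates[2, c]
            gates[2, c] = n + (_tab(xinf_t, 2, vv) - n) * (1.0 - _tab(edt_t, 2, vv))
        for ii in range(ka_c.shape[0]):
            c = ka_c[ii]
            vv = V[c]
            a = gates[3, c]
            gates[3, c] = a + (_tab(xinf_t, 3, vv) - a) * (1.0 - _tab(edt_t, 3, vv))
            b = gates[4, c]
            gates[4, c] = b + (_tab(xinf_t, 4, vv) - b) * (1.0 - _tab(edt_t, 4, vv))
        for ii in range(kd_c.shape[0]):
            c = kd_c[ii]
            vv = V[c]
            x = gates[5, c]
            gates[5, c] = x + (_tab(xinf_t, 5, vv) - x) * (1.0 - _tab(edt_t, 5, vv))
            x = gates[6, c]
            gates[6, c] = x + (_tab(xinf_t, 6, vv) - x) * (1.0 - _tab(edt_t, 6, vv))
        for ii in range(hcn_c.shape[0]):
            c = hcn_c[ii]
            vv = V[c]
            q = gates[7, c]
            gates[7, c] = q + (_tab(xinf_t, 7, vv) - q) * (1.0 - _tab(edt_t, 7, vv))
        for ii in range(cal_c.shape[0]):
            c = cal_c[ii]
            vv = V[c]
            e = gates[8, c]
            gates[8, c] = e + (_tab(xinf_t, 8, vv) - e) * (1.0 - _tab(edt_t, 8, vv))
        for ii in range(can_c.shape[0]):
            c = can_c[ii]
            vv = V[c]
            f = gates[9, c]
            gates[9, c] = f + (_tab(xinf_t, 9, vv) - f) * (1.0 - _tab(edt_t, 9, vv))

        # d) membrane conductance accumulation
        for c in range(nc):
            gl = g_leak[c]
            gtot[c] = gl
            ge[c] = gl * e_leak
        for ii in range(na_c.shape[0]):
            c = na_c[ii]
            m = gates[0, c]
            g = g_na[c] * m * m * m * gates[1, c]
            gtot[c] += g
            ge[c] += g * e_na
        for ii in range(kdr_c.shape[0]):
            c = kdr_c[ii]
            g = g_kdr[c] * gates[2, c]
            gtot[c] += g
            ge[c] += g * e_k
        for ii in range(ka_c.shape[0]):
            c = ka_c[ii]
            g = g_ka[c] * gates[3, c] * gates[4, c]
            gtot[c] += g
            ge[c] += g * e_k
        for ii in range(kd_c.shape[0]):
            c = kd_c[ii]
            g = g_kd[c] * gates[5, c] * gates[6, c]
            gtot[c] += g
            ge[c] += g * e_k
        for ii in range(hcn_c.shape[0]):
            c = hcn_c[ii]
            q = gates[7, c]
            g = g_hcn[c] * q
            gtot[c] += g
            ge[c] += g * e_h
            # static shunt leak proportional to the HCN conductance density:
            # it persists when depolarization deactivates q, which is what
            # turns strong I_h from net excitation into net inhibition under
            # synaptic bombardment
            gs = shunt_gain[c] * g_hcn[c]
            gtot[c] += gs
            ge[c] += gs * e_shunt_arr[c]
        for ii in range(ca_c.shape[0]):
            c = ca_c[ii]
            ica = 0.0
            if g_cal[c] > 0.0:
                e = gates[8, c]
                g = g_cal[c] * e * e
                gtot[c] += g
                ge[c] += g * e_ca
                ica += g * (V[c] - e_ca)
            if g_can[c] > 0.0:
                f = gates[9, c]
                g = g_can[c] * f * f
                gtot[c] += g
                ge[c] += g * e_ca
                ica += g * (V[c] - e_ca)
            if g_kca[c] > 0.0:
                g = g_kca[c] * ca[c] * ca[c] / (ca[c] * ca[c] + KCA_KD_MM * KCA_KD_MM)
                gtot[c] += g
                ge[c] += g * e_k
            # Ca pool (explicit)
            ca[c] += dt * (-ca_phi[c] * ica - (ca[c] - CA_REST_MM) / CA_TAU_MS)
            if ca[c] < 1.0e-6:
                ca[c] = 1.0e-6

        # synaptic conductances
        for k in range(N_KINDS):
            for c in range(nc):
                gs = syn_nf[k] * (B[k, c] - A[k, c])
                if gs > 1.0e-12:
                    if k == KIND_NMDA:
                        gs = gs / (1.0 + mg_scale * np.exp(-0.062 * V[c]))
                    gtot[c] += gs
                    ge[c] += gs * syn_erev[k]

        # e) assemble theta-method system
        for c in range(nc):
            diag[c] = cm_nf[c] / dt + theta * gtot[c]
            rhs[c] = cm_nf[c] / dt * V[c] + ge[c] - (1.0 - theta) * gtot[c] * V[c]
        for c in range(nc):
            p = parent[c]
            if p >= 0:
                ax = g_ax[c]
                diag[c] += theta * ax
                diag[p] += theta * ax
                flow = ax * (V[p] - V[c])  # explicit part
                rhs[c] += (1.0 - theta) * flow
                rhs[p] -= (1.0 - theta) * flow
        for ii in range(inj_comp.shape[0]):
            if inj_start[ii] <= s < inj_stop[ii]:
                rhs[inj_comp[ii]] += inj_amp[ii]

        # Hines elimination (children ordered after parents)
        for c in range(nc - 1, 0, -1):
            p = parent[c]
            if p >= 0:
                off = -theta * g_ax[c]
                f = off / diag[c]
                diag[p] -= f * off
                rhs[p] -= f * rhs[c]
        v_new = rhs  # reuse
        for c in range(nc):
            p = parent[c]
            if p < 0:
                v_new[c] = rhs[c] / diag[c]
            else:
                v_new[c] = (rhs[c] + theta * g_ax[c] * v_new[p]) / diag[c]

        # f) receptor decay
        for k in range(N_KINDS):
            ark = syn_ar[k]
            adk = syn_ad[k]
            for c in range(nc):
                A[k, c] *= ark
                B[k, c] *= adk

        # g) spike detection on somata + fanout scheduling
        for cell in range(ncell):
            sc = soma_comp[cell]
            if V[sc] <= 0.0 and v_new[sc] > 0.0 and s - last_spike[cell] > refr_steps:
                last_spike[cell] = s
                if n_spk < cap:
                    spk_cell[n_spk] = cell
                    spk_time[n_spk] = (s + 1) * dt
                    n_spk += 1
                else:
                    status = 2  # spike buffer overflow
                for j in range(lf_ptr[cell], lf_ptr[cell + 1]):
                    tgt = (s + lf_dstep[j]) % ring_len
                    acc[tgt, lf_kind[j], lf_comp[j]] += lf_g[j]

        # h) recording
        if s % i_stride == 0:
            r = s // i_stride
            for c in range(nc):
                imem[c] = 0.0
            for c in range(nc):
                p = parent[c]
                if p >= 0:
                    flow = g_ax[c] * (v_new[p] - v_new[c])
                    imem[c] += flow
                    imem[p] -= flow
            for ii in range(inj_comp.shape[0]):
                if inj_start[ii] <= s < inj_stop[ii]:
                    imem[inj_comp[ii]] += inj_amp[ii]
            for c in range(nc):
                i_out[r, c] = imem[c]
            t_i[r] = (s + 1) * dt
        if s % v_stride == 0:
            r = s // v_stride
            for ii in range(n_vrec):
                v_out[r, ii] = v_new[v_rec_idx[ii]]

        # commit
        for c in range(nc):
            V[c] = v_new[c]

        if s % 2000 == 0:
            for c in range(nc):
                if not np.isfinite(V[c]) or V[c] > 200.0 or V[c] < -200.0:
                    status = 1
                    break
            if status == 1:
                break

    return status, spk_cell[:n_spk], spk_time[:n_spk], v_out, i_out, t_i, V
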