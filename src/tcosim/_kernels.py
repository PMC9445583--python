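"""Compiled integration core (numba).

One call advances the whole coupled network with classical RK4 at a fixed
step.  Continuous state (membrane voltages, channel gates, calcium, drive
and cortical conductances, adaptation currents) is integrated with RK4;
discrete events (spike detection, transmitter pulses, depression drops,
quantal conductance jumps, Poisson arrivals) are processed at step
boundaries.  Receptor gating s and depression D are linear ODEs with
piecewise-constant coefficients over a step and are advanced by their exact
exponential updates; the chemical conductances they set are frozen over one
step while driving forces and the NMDA magnesium block follow the RK4
stage voltages.

Gate kinetics are evaluated from tabulated x_inf(V) and tau(V)/phi curves
(linear interpolation on a 0.05 mV grid); the calcium-dependent AHP gate is
evaluated analytically.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_SPIKE_OVERFLOW = 2

SRC_THALAMIC = 0
SRC_GC = 1
SRC_PY = 2

CQ_SRC_CORTICAL = 0
CQ_SRC_THALAMIC = 1


@njit(cache=True, fastmath=True)
def _lookup(tab, row, pos_f, n_v):
    k = int(pos_f)
    if k < 0:
        k = 0
        f = 0.0
    elif k >= n_v - 1:
        k = n_v - 2
        f = 1.0
    else:
        f = pos_f - k
    a = tab[row, k]
    return a + f * (tab[row, k + 1] - a)


@njit(cache=True, fastmath=True)
def _th_deriv(V, X, Ca, gdrive,
              dV, dX, dCa, dgd,
              gL, gKL, EL, EKL, Cm, kCa, tauCa, caRest, tau_drive, e_drive,
              ch_i0, ch_i1, ch_g, ch_E, ch_p, ch_q,
              ch_m_tab, ch_h_tab, ch_m_slot, ch_h_slot, ch_is_ca, ch_ca_lin,
              ahp_kf, ahp_beta, ahp_tau_min,
              tab_inf, tab_tau, v_min, dv_inv, n_v,
              gap_indptr, gap_idx, gap_w,
              lin_g, lin_gE, nmda_g, nmda_gE):
    n = V.shape[0]
    for i in range(n):
        v = V[i]
        # leak + K-leak + drive + aggregated chemical conductances
        i_total = gL[i] * (v - EL[i]) + gKL[i] * (v - EKL[i])
        i_total += gdrive[i] * (v - e_drive)
        i_total += lin_g[i] * v - lin_gE[i]
        if nmda_g[i] > 0.0:
            b = 1.0 / (1.0 + np.exp(-0.062 * v) * 0.2801)  # [Mg]=1 mM / 3.57
            i_total += b * (nmda_g[i] * v - nmda_gE[i])
        # gap junctions
        for k in range(gap_indptr[i], gap_indptr[i + 1]):
            i_total += gap_w[k] * (v - V[gap_idx[k]])
        dCa[i] = (caRest[i] - Ca[i]) / tauCa[i]
        dV[i] = i_total  # accumulate intrinsic below, then divide
        dgd[i] = -gdrive[i] / tau_drive

    n_ch = ch_i0.shape[0]
    for c in range(n_ch):
        g = ch_g[c]
        e_rev = ch_E[c]
        p = ch_p[c]
        q = ch_q[c]
        m_tab = ch_m_tab[c]
        h_tab = ch_h_tab[c]
        m_slot = ch_m_slot[c]
        h_slot = ch_h_slot[c]
        is_ca = ch_is_ca[c]
        for i in range(ch_i0[c], ch_i1[c]):
            v = V[i]
            pos = (v - v_min) * dv_inv
            fac = 1.0
            if m_slot >= 0:
                m = X[m_slot, i]
                if m_tab >= 0:
                    m_inf = _lookup(tab_inf, m_tab, pos, n_v)
                    m_tau = _lookup(tab_tau, m_tab, pos, n_v)
                else:  # calcium-gated (AHP); linear or quadratic Ca dependence
                    if ch_ca_lin[c] == 1:
                        a = 2.0 * Ca[i]
                        b_ = 0.01
                    else:
                        a = ahp_kf * Ca[i] * Ca[i]
                        b_ = ahp_beta
                    m_inf = a / (a + b_)
                    m_tau = 1.0 / (a + b_)
                    if m_tau < ahp_tau_min:
                        m_tau = ahp_tau_min
                dX[m_slot, i] = (m_inf - m) / m_tau
                for _ in range(p):
                    fac *= m
            if h_slot >= 0:
                h = X[h_slot, i]
                h_inf = _lookup(tab_inf, h_tab, pos, n_v)
                h_tau = _lookup(tab_tau, h_tab, pos, n_v)
                dX[h_slot, i] = (h_inf - h) / h_tau
                for _ in range(q):
                    fac *= h
            cur = g * fac * (v - e_rev)
            dV[i] += cur
            if is_ca:
                dCa[i] -= kCa[i] * cur

    for i in range(n):
        dV[i] = -dV[i] / Cm[i]


@njit(cache=True, fastmath=True)
def _cx_deriv(v_cx, w_cx, gE, gI, refr,
              dv, dw, dgE, dgI,
              cxCm, cxgL, cxEL, cxVT, cxDelta, cxa, cxtauw, cxVcut,
              eE, eI, tauE, tauI):
    n = v_cx.shape[0]
    for i in range(n):
        v = v_cx[i]
        # bound the spike upswing: cap the exponential argument and evaluate
        # the adaptation coupling at most at the cutoff voltage, so RK4
        # stages stay finite while the event handler performs the reset
        veff = v if v < cxVcut[i] else cxVcut[i]
        if refr[i] > 0.0:
            dv[i] = 0.0
        else:
            arg = (v - cxVT[i]) / cxDelta[i]
            if arg > 8.0:
                arg = 8.0
            i_exp = cxgL[i] * cxDelta[i] * np.exp(arg)
            i_syn = gE[i] * (v - eE) + gI[i] * (v - eI)
            dv[i] = (-cxgL[i] * (v - cxEL[i]) + i_exp - w_cx[i] - i_syn) / cxCm[i]
        dw[i] = (cxa[i] * (veff - cxEL[i]) - w_cx[i]) / cxtauw[i]
        dgE[i] = -gE[i] / tauE
        dgI[i] = -gI[i] / tauI


@njit(cache=True, fastmath=True)
def simulate(dt, n_steps,
             # --- thalamic state ---
             V, X, Ca, gdrive,
             gL, gKL, EL, EKL, Cm, kCa, tauCa, caRest, tau_drive, e_drive,
             # --- channels ---
             ch_i0, ch_i1, ch_g, ch_E, ch_p, ch_q,
             ch_m_tab, ch_h_tab, ch_m_slot, ch_h_slot, ch_is_ca, ch_ca_lin,
             ahp_kf, ahp_beta, ahp_tau_min,
             tab_inf, tab_tau, v_min, dv_inv,
             # --- gap junctions ---
             gap_indptr, gap_idx, gap_w,
             # --- chemical projections ---
             pr_src_kind, pr_src_g0, pr_tgt_g0, pr_nsrc, pr_ntgt,
             pr_gden, pr_E, pr_is_nmda,
             pr_exp_off, pr_exp_on, pr_sinf_on, pr_one_minus_U, pr_exp_rec,
             pr_indptr, pr_ip_off, pr_edge_src, pr_edge_off,
             pr_s, pr_D, pr_st_off,
             toff_th, toff_py,
             # --- GC spike train ---
             gc_times,
             # --- thalamic spike detection / drive events ---
             thr, lockout, last_spike_th,
             drv_t, drv_i, drv_q,
             # --- cortex ---
             v_cx, w_cx, gE, gI, refr,
             cxCm, cxgL, cxEL, cxVT, cxDelta, cxa, cxb, cxtauw, cxVr, cxRefr, cxVcut,
             eE, eI, tauE, tauI,
             # --- cortical quantal projections (CSR over sources) ---
             cq_src_kind, cq_src_g0, cq_tgt_g0, cq_nsrc, cq_q, cq_is_inh,
             cq_indptr, cq_ip_off, cq_edge_tgt, cq_edge_off,
             cxn_t, cxn_i, cxn_q,
             # --- recording ---
             rec_decim, th_pop_off, cx_pop_off, traces,
             sel_idx, v_sel,
             sp_i_th, sp_t_th, sp_i_cx, sp_t_cx):
    n_th = V.shape[0]
    n_cx = v_cx.shape[0]
    n_slots = X.shape[0]
    n_pr = pr_src_kind.shape[0]
    n_cq = cq_src_kind.shape[0]
    n_v = tab_inf.shape[1]
    n_th_pops = th_pop_off.shape[0] - 1
    n_cx_pops = cx_pop_off.shape[0] - 1

    # chemical conductance accumulators
    lin_g = np.zeros(n_th)
    lin_gE = np.zeros(n_th)
    nmda_g = np.zeros(n_th)
    nmda_gE = np.zeros(n_th)

    # RK4 work buffers
    dV1 = np.zeros(n_th); dV2 = np.zeros(n_th); dV3 = np.zeros(n_th); dV4 = np.zeros(n_th)
    dC1 = np.zeros(n_th); dC2 = np.zeros(n_th); dC3 = np.zeros(n_th); dC4 = np.zeros(n_th)
    dg1 = np.zeros(n_th); dg2 = np.zeros(n_th); dg3 = np.zeros(n_th); dg4 = np.zeros(n_th)
    dX1 = np.zeros((n_slots, n_th)); dX2 = np.zeros((n_slots, n_th))
    dX3 = np.zeros((n_slots, n_th)); dX4 = np.zeros((n_slots, n_th))
    Vt = np.zeros(n_th); Cat = np.zeros(n_th); gdt = np.zeros(n_th)
    Xt = np.zeros((n_slots, n_th))

    dv1 = np.zeros(n_cx); dv2 = np.zeros(n_cx); dv3 = np.zeros(n_cx); dv4 = np.zeros(n_cx)
    dw1 = np.zeros(n_cx); dw2 = np.zeros(n_cx); dw3 = np.zeros(n_cx); dw4 = np.zeros(n_cx)
    dE1 = np.zeros(n_cx); dE2 = np.zeros(n_cx); dE3 = np.zeros(n_cx); dE4 = np.zeros(n_cx)
    dI1 = np.zeros(n_cx); dI2 = np.zeros(n_cx); dI3 = np.zeros(n_cx); dI4 = np.zeros(n_cx)
    vt = np.zeros(n_cx); wt = np.zeros(n_cx); gEt = np.zeros(n_cx); gIt = np.zeros(n_cx)

    Vprev = np.zeros(n_th)

    n_sp_th = 0
    n_sp_cx = 0
    cap_th = sp_i_th.shape[0]
    cap_cx = sp_i_cx.shape[0]
    drv_ptr = 0
    cxn_ptr = 0
    gc_ptr = 0
    toff_gc = -1.0e30
    rec_i = 0
    n_sel = sel_idx.shape[0]
    status = STATUS_OK

    for step in range(n_steps):
        t = step * dt
        t_next = t + dt

        # -- record at step start --
        if step % rec_decim == 0 and rec_i < traces.shape[1]:
            for p in range(n_th_pops):
                acc = 0.0
                for i in range(th_pop_off[p], th_pop_off[p + 1]):
                    acc += V[i]
                cnt = th_pop_off[p + 1] - th_pop_off[p]
                traces[p, rec_i] = acc / cnt if cnt > 0 else 0.0
            for p in range(n_cx_pops):
                acc = 0.0
                for i in range(cx_pop_off[p], cx_pop_off[p + 1]):
                    acc += v_cx[i]
                cnt = cx_pop_off[p + 1] - cx_pop_off[p]
                traces[n_th_pops + p, rec_i] = acc / cnt if cnt > 0 else 0.0
            for s_ in range(n_sel):
                v_sel[s_, rec_i] = V[sel_idx[s_]]
            rec_i += 1

        # -- deliver Poisson arrivals for this step --
        while drv_ptr < drv_t.shape[0] and drv_t[drv_ptr] < t_next:
            gdrive[drv_i[drv_ptr]] += drv_q[drv_ptr]
            drv_ptr += 1
        while cxn_ptr < cxn_t.shape[0] and cxn_t[cxn_ptr] < t_next:
            gE[cxn_i[cxn_ptr]] += cxn_q[cxn_ptr]
            cxn_ptr += 1

        # -- chemical conductance aggregation (frozen over the step) --
        for i in range(n_th):
            lin_g[i] = 0.0
            lin_gE[i] = 0.0
            nmda_g[i] = 0.0
            nmda_gE[i] = 0.0
        for p in range(n_pr):
            tgt0 = pr_tgt_g0[p]
            gden = pr_gden[p]
            e_rev = pr_E[p]
            st0 = pr_st_off[p]
            ip0 = pr_ip_off[p]
            e0 = pr_edge_off[p]
            if pr_is_nmda[p] == 1:
                for tl in range(pr_ntgt[p]):
                    acc = 0.0
                    for k in range(pr_indptr[ip0 + tl], pr_indptr[ip0 + tl + 1]):
                        sl = pr_edge_src[e0 + k]
                        acc += pr_s[st0 + sl] * pr_D[st0 + sl]
                    ge = gden * acc
                    nmda_g[tgt0 + tl] += ge
                    nmda_gE[tgt0 + tl] += ge * e_rev
            else:
                for tl in range(pr_ntgt[p]):
                    acc = 0.0
                    for k in range(pr_indptr[ip0 + tl], pr_indptr[ip0 + tl + 1]):
                        sl = pr_edge_src[e0 + k]
                        acc += pr_s[st0 + sl] * pr_D[st0 + sl]
                    ge = gden * acc
                    lin_g[tgt0 + tl] += ge
                    lin_gE[tgt0 + tl] += ge * e_rev

        # -- RK4 stages --
        _th_deriv(V, X, Ca, gdrive, dV1, dX1, dC1, dg1,
                  gL, gKL, EL, EKL, Cm, kCa, tauCa, caRest, tau_drive, e_drive,
                  ch_i0, ch_i1, ch_g, ch_E, ch_p, ch_q,
                  ch_m_tab, ch_h_tab, ch_m_slot, ch_h_slot, ch_is_ca, ch_ca_lin,
                  ahp_kf, ahp_beta, ahp_tau_min,
                  tab_inf, tab_tau, v_min, dv_inv, n_v,
                  gap_indptr, gap_idx, gap_w,
                  lin_g, lin_gE, nmda_g, nmda_gE)
        _cx_deriv(v_cx, w_cx, gE, gI, refr, dv1, dw1, dE1, dI1,
                  cxCm, cxgL, cxEL, cxVT, cxDelta, cxa, cxtauw, cxVcut,
                  eE, eI, tauE, tauI)

        half = 0.5 * dt
        for i in range(n_th):
            Vt[i] = V[i] + half * dV1[i]
            Cat[i] = Ca[i] + half * dC1[i]
            gdt[i] = gdrive[i] + half * dg1[i]
        for s_ in range(n_slots):
            for i in range(n_th):
                Xt[s_, i] = X[s_, i] + half * dX1[s_, i]
        for i in range(n_cx):
            vt[i] = v_cx[i] + half * dv1[i]
            wt[i] = w_cx[i] + half * dw1[i]
            gEt[i] = gE[i] + half * dE1[i]
            gIt[i] = gI[i] + half * dI1[i]

        _th_deriv(Vt, Xt, Cat, gdt, dV2, dX2, dC2, dg2,
                  gL, gKL, EL, EKL, Cm, kCa, tauCa, caRest, tau_drive, e_drive,
                  ch_i0, ch_i1, ch_g, ch_E, ch_p, ch_q,
                  ch_m_tab, ch_h_tab, ch_m_slot, ch_h_slot, ch_is_ca, ch_ca_lin,
                  ahp_kf, ahp_beta, ahp_tau_min,
                  tab_inf, tab_tau, v_min, dv_inv, n_v,
                  gap_indptr, gap_idx, gap_w,
                  lin_g, lin_gE, nmda_g, nmda_gE)
        _cx_deriv(vt, wt, gEt, gIt, refr, dv2, dw2, dE2, dI2,
                  cxCm, cxgL, cxEL, cxVT, cxDelta, cxa, cxtauw, cxVcut,
                  eE, eI, tauE, tauI)

        for i in range(n_th):
            Vt[i] = V[i] + half * dV2[i]
            Cat[i] = Ca[i] + half * dC2[i]
            gdt[i] = gdrive[i] + half * dg2[i]
        for s_ in range(n_slots):
            for i in range(n_th):
                Xt[s_, i] = X[s_, i] + half * dX2[s_, i]
        for i in range(n_cx):
            vt[i] = v_cx[i] + half * dv2[i]
            wt[i] = w_cx[i] + half * dw2[i]
            gEt[i] = gE[i] + half * dE2[i]
            gIt[i] = gI[i] + half * dI2[i]

        _th_deriv(Vt, Xt, Cat, gdt, dV3, dX3, dC3, dg3,
                  gL, gKL, EL, EKL, Cm, kCa, tauCa, caRest, tau_drive, e_drive,
                  ch_i0, ch_i1, ch_g, ch_E, ch_p, ch_q,
                  ch_m_tab, ch_h_tab, ch_m_slot, ch_h_slot, ch_is_ca, ch_ca_lin,
                  ahp_kf, ahp_beta, ahp_tau_min,
                  tab_inf, tab_tau, v_min, dv_inv, n_v,
                  gap_indptr, gap_idx, gap_w,
                  lin_g, lin_gE, nmda_g, nmda_gE)
        _cx_deriv(vt, wt, gEt, gIt, refr, dv3, dw3, dE3, dI3,
                  cxCm, cxgL, cxEL, cxVT, cxDelta, cxa, cxtauw, cxVcut,
                  eE, eI, tauE, tauI)

        for i in range(n_th):
            Vt[i] = V[i] + dt * dV3[i]
            Cat[i] = Ca[i] + dt * dC3[i]
            gdt[i] = gdrive[i] + dt * dg3[i]
        for s_ in range(n_slots):
            for i in range(n_th):
                Xt[s_, i] = X[s_, i] + dt * dX3[s_, i]
        for i in range(n_cx):
            vt[i] = v_cx[i] + dt * dv3[i]
            wt[i] = w_cx[i] + dt * dw3[i]
            gEt[i] = gE[i] + dt * dE3[i]
            gIt[i] = gI[i] + dt * dI3[i]

        _th_deriv(Vt, Xt, Cat, gdt, dV4, dX4, dC4, dg4,
                  gL, gKL, EL, EKL, Cm, kCa, tauCa, caRest, tau_drive, e_drive,
                  ch_i0, ch_i1, ch_g, ch_E, ch_p, ch_q,
                  ch_m_tab, ch_h_tab, ch_m_slot, ch_h_slot, ch_is_ca, ch_ca_lin,
                  ahp_kf, ahp_beta, ahp_tau_min,
                  tab_inf, tab_tau, v_min, dv_inv, n_v,
                  gap_indptr, gap_idx, gap_w,
                  lin_g, lin_gE, nmda_g, nmda_gE)
        _cx_deriv(vt, wt, gEt, gIt, refr, dv4, dw4, dE4, dI4,
                  cxCm, cxgL, cxEL, cxVT, cxDelta, cxa, cxtauw, cxVcut,
                  eE, eI, tauE, tauI)

        sixth = dt / 6.0
        for i in range(n_th):
            Vprev[i] = V[i]
            V[i] += sixth * (dV1[i] + 2.0 * dV2[i] + 2.0 * dV3[i] + dV4[i])
            Ca[i] += sixth * (dC1[i] + 2.0 * dC2[i] + 2.0 * dC3[i] + dC4[i])
            if Ca[i] < 1e-12:
                Ca[i] = 1e-12
            gdrive[i] += sixth * (dg1[i] + 2.0 * dg2[i] + 2.0 * dg3[i] + dg4[i])
        for s_ in range(n_slots):
            for i in range(n_th):
                x = X[s_, i] + sixth * (dX1[s_, i] + 2.0 * dX2[s_, i]
                                        + 2.0 * dX3[s_, i] + dX4[s_, i])
                if x < 0.0:
                    x = 0.0
                elif x > 1.0:
                    x = 1.0
                X[s_, i] = x
        for i in range(n_cx):
            if refr[i] <= 0.0:
                v_cx[i] += sixth * (dv1[i] + 2.0 * dv2[i] + 2.0 * dv3[i] + dv4[i])
            w_cx[i] += sixth * (dw1[i] + 2.0 * dw2[i] + 2.0 * dw3[i] + dw4[i])
            gE[i] += sixth * (dE1[i] + 2.0 * dE2[i] + 2.0 * dE3[i] + dE4[i])
            gI[i] += sixth * (dI1[i] + 2.0 * dI2[i] + 2.0 * dI3[i] + dI4[i])
            if refr[i] > 0.0:
                refr[i] -= dt
                if refr[i] < 0.0:
                    refr[i] = 0.0
                v_cx[i] = cxVr[i]

        # -- exact updates of receptor gating and depression --
        for p in range(n_pr):
            st0 = pr_st_off[p]
            kind = pr_src_kind[p]
            src0 = pr_src_g0[p]
            for j in range(pr_nsrc[p]):
                if kind == SRC_THALAMIC:
                    on = toff_th[src0 + j] > t + 1e-12
                elif kind == SRC_GC:
                    on = toff_gc > t + 1e-12
                else:
                    on = toff_py[src0 + j] > t + 1e-12
                s_val = pr_s[st0 + j]
                if on:
                    pr_s[st0 + j] = pr_sinf_on[p] + (s_val - pr_sinf_on[p]) * pr_exp_on[p]
                else:
                    pr_s[st0 + j] = s_val * pr_exp_off[p]
                pr_D[st0 + j] = 1.0 - (1.0 - pr_D[st0 + j]) * pr_exp_rec[p]

        # -- GC spikes in (t, t_next] --
        while gc_ptr < gc_times.shape[0] and gc_times[gc_ptr] <= t_next:
            toff_gc = t_next + 0.3
            for p in range(n_pr):
                if pr_src_kind[p] == SRC_GC:
                    pr_D[pr_st_off[p]] *= pr_one_minus_U[p]
            gc_ptr += 1

        # -- thalamic spike detection --
        for i in range(n_th):
            if Vprev[i] < thr and V[i] >= thr and t_next - last_spike_th[i] >= lockout:
                last_spike_th[i] = t_next
                if n_sp_th < cap_th:
                    sp_i_th[n_sp_th] = i
                    sp_t_th[n_sp_th] = t_next
                    n_sp_th += 1
                else:
                    status = STATUS_SPIKE_OVERFLOW
                toff_th[i] = t_next + 0.3
                for p in range(n_pr):
                    if pr_src_kind[p] == SRC_THALAMIC and pr_src_g0[p] <= i < pr_src_g0[p] + pr_nsrc[p]:
                        pr_D[pr_st_off[p] + i - pr_src_g0[p]] *= pr_one_minus_U[p]
                for p in range(n_cq):
                    if cq_src_kind[p] == CQ_SRC_THALAMIC and cq_src_g0[p] <= i < cq_src_g0[p] + cq_nsrc[p]:
                        sl = i - cq_src_g0[p]
                        ip0 = cq_ip_off[p]
                        e0 = cq_edge_off[p]
                        for k in range(cq_indptr[ip0 + sl], cq_indptr[ip0 + sl + 1]):
                            tgt = cq_tgt_g0[p] + cq_edge_tgt[e0 + k]
                            if cq_is_inh[p] == 1:
                                gI[tgt] += cq_q[p]
                            else:
                                gE[tgt] += cq_q[p]

        # -- cortical spike handling --
        for i in range(n_cx):
            if refr[i] <= 0.0 and v_cx[i] >= cxVcut[i]:
                v_cx[i] = cxVr[i]
                w_cx[i] += cxb[i]
                refr[i] = cxRefr[i]
                if n_sp_cx < cap_cx:
                    sp_i_cx[n_sp_cx] = i
                    sp_t_cx[n_sp_cx] = t_next
                    n_sp_cx += 1
                else:
                    status = STATUS_SPIKE_OVERFLOW
                toff_py[i] = t_next + 0.3
                for p in range(n_pr):
                    if pr_src_kind[p] == SRC_PY and pr_src_g0[p] <= i < pr_src_g0[p] + pr_nsrc[p]:
                        pr_D[pr_st_off[p] + i - pr_src_g0[p]] *= pr_one_minus_U[p]
                for p in range(n_cq):
                    if cq_src_kind[p] == CQ_SRC_CORTICAL and cq_src_g0[p] <= i < cq_src_g0[p] + cq_nsrc[p]:
                        sl = i - cq_src_g0[p]
                        ip0 = cq_ip_off[p]
                        e0 = cq_edge_off[p]
                        for k in range(cq_indptr[ip0 + sl], cq_indptr[ip0 + sl + 1]):
                            tgt = cq_tgt_g0[p] + cq_edge_tgt[e0 + k]
                            if cq_is_inh[p] == 1:
                                gI[tgt] += cq_q[p]
                            else:
                                gE[tgt] += cq_q[p]

        # -- sanity check --
        if step % 500 == 0:
            ok = True
            for i in range(n_th):
                if not np.isfinite(V[i]):
                    ok = False
            for i in range(n_cx):
                if not np.isfinite(v_cx[i]):
                    ok = False
            if not ok:
                return n_sp_th, n_sp_cx, STATUS_NONFINITE, step

    return n_sp_th, n_sp_cx, status, n_steps
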