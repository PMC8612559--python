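"""Numba kernels: channel rate functions, gating updates and the implicit
cable integrator.

Unit conventions (used consistently in every kernel):
    voltage mV, time ms, capacitance nF, conductance uS, current nA.
With these, C*dV/dt [nF*mV/ms] = I [nA] and g*V [uS*mV] = I [nA] hold
without conversion factors.

Parameter-vector layouts (plain float64 arrays so numba can specialise):
    Na  (len 14): G_co, G_oc, G_ic, G_ci, V_co, V_ic, k_co, k_ic,
                  tau_act, tau_ina, tau_rel, cf, q10, e_rev
    K   (len 12): G_co, G_oc, V_co, V_ic, k_co, k_ic,
                  tau_act, tau_ina, tau_rel, cf, q10, e_rev
"""
import numpy as np
from numba import njit

__all__ = [
    "na_rates_kernel",
    "k_rates_kernel",
    "simulate_kernel",
    "NA_LEN",
    "K_LEN",
]

NA_LEN = 14
K_LEN = 12


@njit(cache=True, inline="always")
def _logistic(x):
    # 1/(1+exp(x)) with overflow guard
    if x > 60.0:
        return 0.0
    if x < -60.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(x))


@njit(cache=True)
def na_rates_kernel(v, p):
    """Boltzmann transition rates of the cooperative 3-state Na channel.

    Returns (alpha_A, beta_A, alpha_IC, beta_IC) in 1/ms.  alpha_A/beta_A
    govern closed<->open at the activation midpoint V_co; alpha_IC/beta_IC
    govern the inactivated fraction at the midpoint V_ic.
    """
    qa = p[12] / p[8]
    qi = p[12] / p[9]
    a_a = qa * p[0] * _logistic((p[4] - v) / p[6])
    b_a = qa * p[1] * _logistic((v - p[4]) / p[6])
    a_ic = qi * p[2] * _logistic((p[5] - v) / p[7])
    b_ic = qi * p[3] * _logistic((v - p[5]) / p[7])
    return a_a, b_a, a_ic, b_ic


@njit(cache=True)
def k_rates_kernel(v, p):
    """Opening/closing rates (1/ms) of the 2-state delayed-rectifier K channel."""
    a_k = p[10] / p[6] * p[0] * _logistic((p[2] - v) / p[4])
    b_k = p[10] / p[7] * p[1] * _logistic((v - p[3]) / p[5])
    return a_k, b_k


@njit(cache=True)
def simulate_kernel(
    dt,
    nsteps,
    theta,
    parent,      # int64[n]; parent[0] == -1, parent[i] < i
    cm_nf,       # f8[n]
    gpas_us,     # f8[n]
    e_pas,
    g_ax,        # f8[n]; coupling conductance (uS) between i and parent[i]
    gna_us,      # f8[n]; peak Na conductance per compartment (0 = absent)
    gk_us,
    napar,       # f8[NA_LEN]
    kpar,        # f8[K_LEN]
    gton_us,     # f8[n]; tonic GABA conductance per compartment
    e_tonic,
    syn_comp,    # int64[ns]
    syn_tau1,
    syn_tau2,
    syn_e,
    ev_syn,      # int64[ne]; synapse index of each event, sorted by step
    ev_step,     # int64[ne]
    ev_w,        # f8[ne]; peak conductance (uS) added per event
    ic_comp,     # int64[nc]; step-current injections
    ic_amp,      # f8[nc] (nA)
    ic_t0,       # int64[nc] (step index, inclusive)
    ic_t1,       # int64[nc] (step index, exclusive)
    pb_comp,     # int64; playback-current compartment, -1 = none
    pb_curr,     # f8[nsteps+1]; injected current (nA) per step
    v0,          # f8[n]
    ona0,
    hna0,
    ok0,
    rec_idx,     # int64[nrec]
    rec_syn,     # int64; synapse whose current to record, -1 = none
    detect_comp,  # int64; compartment for spike detection, -1 = none
    detect_level,
    detect_step0,
    detect_step1,
    stop_at_spike,
):
    n = parent.shape[0]
    ns = syn_comp.shape[0]
    nrec = rec_idx.shape[0]

    v = v0.copy()
    ona = ona0.copy()
    hna = hna0.copy()
    ok = ok0.copy()

    # Exp2 synapse states: g(t) = b - a, each decaying exponentially
    sa = np.zeros(ns)
    sb = np.zeros(ns)
    dec1 = np.empty(ns)
    dec2 = np.empty(ns)
    for j in range(ns):
        dec1[j] = np.exp(-dt / syn_tau1[j])
        dec2[j] = np.exp(-dt / syn_tau2[j])

    out_v = np.empty((nrec, nsteps + 1))
    out_isyn = np.zeros(nsteps + 1)
    for r in range(nrec):
        out_v[r, 0] = v[rec_idx[r]]
    if rec_syn >= 0:
        out_isyn[0] = 0.0

    gtot = np.empty(n)
    stot = np.empty(n)
    diag = np.empty(n)
    rhs = np.empty(n)

    inv_tau_na = 1.0 / napar[10]
    inv_tau_k = 1.0 / kpar[8]
    cf_na = napar[11]
    cf_k = kpar[9]
    e_na = napar[13]
    e_k = kpar[11]

    spike_step = -1
    clip_count = 0
    status = 0
    ev_ptr = 0
    ne = ev_step.shape[0]
    last_step = nsteps

    for step in range(1, nsteps + 1):
        # --- synaptic events scheduled at the start of this step
        while ev_ptr < ne and ev_step[ev_ptr] < step:
            ev_ptr += 1
        # decay states over dt, then add events whose onset falls in this step
        for j in range(ns):
            sa[j] *= dec1[j]
            sb[j] *= dec2[j]
        while ev_ptr < ne and ev_step[ev_ptr] == step:
            j = ev_syn[ev_ptr]
            # normalisation so that the peak of (b-a) equals the weight
            t1 = syn_tau1[j]
            t2 = syn_tau2[j]
            tp = t1 * t2 / (t2 - t1) * np.log(t2 / t1)
            factor = 1.0 / (np.exp(-tp / t2) - np.exp(-tp / t1))
            sa[j] += ev_w[ev_ptr] * factor
            sb[j] += ev_w[ev_ptr] * factor
            ev_ptr += 1

        # --- gating update (exponential integrator, rates frozen at V(t))
        for i in range(n):
            if gna_us[i] > 0.0:
                veff = v[i] + cf_na * ona[i]
                a_a, b_a, _, _ = na_rates_kernel(veff, napar)
                _, _, a_ic, b_ic = na_rates_kernel(v[i], napar)
                d_o = a_a + b_a + inv_tau_na
                oinf = a_a * (1.0 - hna[i]) / d_o
                ona[i] = oinf + (ona[i] - oinf) * np.exp(-dt * d_o)
                d_h = a_ic + b_ic + inv_tau_na
                hinf = a_ic / d_h
                hna[i] = hinf + (hna[i] - hinf) * np.exp(-dt * d_h)
                # clip to the unit simplex
                if ona[i] < 0.0:
                    if ona[i] < -1e-9:
                        clip_count += 1
                    ona[i] = 0.0
                if hna[i] < 0.0:
                    if hna[i] < -1e-9:
                        clip_count += 1
                    hna[i] = 0.0
                if hna[i] > 1.0:
                    if hna[i] > 1.0 + 1e-9:
                        clip_count += 1
                    hna[i] = 1.0
                if ona[i] + hna[i] > 1.0:
                    if ona[i] + hna[i] > 1.0 + 1e-9:
                        clip_count += 1
                    ona[i] = 1.0 - hna[i]
            if gk_us[i] > 0.0:
                veff = v[i] + cf_k * ok[i]
                a_k, b_k = k_rates_kernel(veff, kpar)
                d_k = a_k + b_k + inv_tau_k
                kinf = a_k / d_k
                ok[i] = kinf + (ok[i] - kinf) * np.exp(-dt * d_k)
                if ok[i] < 0.0:
                    if ok[i] < -1e-9:
                        clip_count += 1
                    ok[i] = 0.0
                elif ok[i] > 1.0:
                    if ok[i] > 1.0 + 1e-9:
                        clip_count += 1
                    ok[i] = 1.0

        # --- assemble conductance / source terms (frozen over the step)
        for i in range(n):
            g = gpas_us[i]
            s = gpas_us[i] * e_pas
            if gna_us[i] > 0.0:
                gna = gna_us[i] * ona[i]
                g += gna
                s += gna * e_na
            if gk_us[i] > 0.0:
                gk = gk_us[i] * ok[i]
                g += gk
                s += gk * e_k
            if gton_us[i] > 0.0:
                g += gton_us[i]
                s += gton_us[i] * e_tonic
            gtot[i] = g
            stot[i] = s
        for j in range(ns):
            gs = sb[j] - sa[j]
            if gs > 0.0:
                i = syn_comp[j]
                gtot[i] += gs
                stot[i] += gs * syn_e[j]

        # --- theta-implicit voltage update on the tree (Hines solve)
        for i in range(n):
            diag[i] = cm_nf[i] / dt + theta * gtot[i]
            rhs[i] = (cm_nf[i] / dt) * v[i] + stot[i] \
                - (1.0 - theta) * gtot[i] * v[i]
        # explicit part of axial currents + implicit diagonal contributions
        for i in range(1, n):
            p_i = parent[i]
            diag[i] += theta * g_ax[i]
            diag[p_i] += theta * g_ax[i]
            ax = g_ax[i] * (v[p_i] - v[i])
            rhs[i] += (1.0 - theta) * ax
            rhs[p_i] -= (1.0 - theta) * ax
        # injected currents
        for c in range(ic_comp.shape[0]):
            if step >= ic_t0[c] and step <= ic_t1[c]:
                rhs[ic_comp[c]] += ic_amp[c]
        if pb_comp >= 0:
            rhs[pb_comp] += pb_curr[step]
        # eliminate leaves -> root (children have larger indices)
        for i in range(n - 1, 0, -1):
            p_i = parent[i]
            off = -theta * g_ax[i]
            ratio = off / diag[i]
            diag[p_i] -= ratio * off
            rhs[p_i] -= ratio * rhs[i]
        vnew0 = rhs[0] / diag[0]
        v[0] = vnew0
        for i in range(1, n):
            p_i = parent[i]
            off = -theta * g_ax[i]
            v[i] = (rhs[i] - off * v[p_i]) / diag[i]

        # --- record
        for r in range(nrec):
            out_v[r, step] = v[rec_idx[r]]
        if rec_syn >= 0:
            gs = sb[rec_syn] - sa[rec_syn]
            out_isyn[step] = gs * (v[syn_comp[rec_syn]] - syn_e[rec_syn])

        # --- spike detection / divergence
        if detect_comp >= 0 and spike_step < 0:
            if step >= detect_step0 and step <= detect_step1 \
                    and v[detect_comp] >= detect_level:
                spike_step = step
                if stop_at_spike:
                    last_step = step
                    break
        vmax = 0.0
        for i in range(n):
            av = abs(v[i])
            if av > vmax:
                vmax = av
        if vmax > 500.0 or not np.isfinite(vmax):
            status = 1
            last_step = step
            break

    return (status, spike_step, last_step, out_v, out_isyn,
            v, ona, hna, ok, clip_count)
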