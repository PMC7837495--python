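"""Compiled simulation engine.

The public solver API lives in :mod:`golgisim.solver`; this module packs a
CellModel into flat numpy arrays and advances it with numba-compiled kernels:

* implicit (backward Euler) cable update solved in linear time with a Hines
  tree factorization (penalty method for ideal voltage clamps),
* HH gates via exponential integrators with kinetics tabulated on a voltage
  grid (exact for constant voltage within table resolution),
* Markov channels via a per-compartment backward-Euler solve of the small
  (I - dt*Q^T) system (unconditionally stable for stiff schemes),
* submembrane calcium shells (buffer + first-order pump) semi-implicitly,
* synaptic receptors (3-state binding/desensitization scheme) driven by a
  biexponential transmitter transient with event-driven release weights.

Units: mV, ms, nA, uS, nF, mM; conductance densities are converted at pack
time using compartment areas.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# voltage grid for tabulated kinetics
V_MIN, V_MAX, V_STEP = -150.0, 100.0, 0.25
NV = int(round((V_MAX - V_MIN) / V_STEP)) + 1
V_GRID = np.linspace(V_MIN, V_MAX, NV)

# recording kinds
REC_V = 0
REC_CA = 1
REC_HH_I = 2
REC_MK_I = 3
REC_SYN_I = 4
REC_CLAMP_I = 5
REC_SYN_ICA = 6
REC_CA_DOMAIN = 7


@njit(cache=True, inline="always")
def _interp(tab, v):
    x = (v - V_MIN) / V_STEP
    if x <= 0.0:
        return tab[0]
    if x >= NV - 1:
        return tab[NV - 1]
    i = int(x)
    f = x - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(cache=True)
def _hines_solve(parent, diag, offd, rhs, v_out):
    """Solve the symmetric tree system in place; offd[i] couples i to parent."""
    n = diag.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = offd[i] / diag[i]
        diag[p] -= offd[i] * f
        rhs[p] += rhs[i] * f
    v_out[0] = rhs[0] / diag[0]
    for i in range(1, n):
        p = parent[i]
        v_out[i] = (rhs[i] + offd[i] * v_out[p]) / diag[i]


@njit(cache=True)
def _step(
    # geometry / passive
    parent, g_ax, cm_nf, gl_us, el,
    # state
    v, v_new,
    # HH instances
    hh_comp, hh_g, hh_e, hh_ca, hh_gstart, hh_gcount, hh_gopen,
    # HH gates
    hg_state, hg_def, hg_kind, hg_exp, hg_minf, hg_efac, hg_kd, hg_hill, hg_efca,
    # Markov
    mk_comp, mk_g, mk_e, mk_ca, mk_scheme, mk_off, mk_p, mk_gopen,
    sc_nstates, sc_trstart, sc_trcount, sc_cwstart,
    tr_from, tr_to, tr_ca, tr_tab, cw,
    # calcium shells
    sh_ca, sh_b, sh_btot, sh_kon, sh_koff, sh_kpump, sh_carest, sh_ifac, ica_acc,
    dm_ca, dm_k, dm_ifac, ica2_acc, hh_cadest, mk_cadest, mk_casrc,
    # synapses
    syn_comp, syn_kind, syn_g, syn_e, syn_o, syn_d, syn_ta, syn_tb,
    syn_efr, syn_efd, syn_kb, syn_ku, syn_kdes, syn_kres,
    syn_mg_scale, syn_mg_slope, syn_cafrac, syn_i, syn_ica,
    # electrodes
    ic_comp, ic_wave, vc_comp, vc_wave, vc_i,
    # scratch
    gsum, gesum, diag, offd, rhs,
    dt, istep,
):
    n = v.shape[0]
    for i in range(n):
        gsum[i] = 0.0
        gesum[i] = 0.0
        ica_acc[i] = 0.0
        ica2_acc[i] = 0.0

    # --- HH gates & conductances ---
    for k in range(hh_comp.shape[0]):
        c = hh_comp[k]
        vv = v[c]
        o = 1.0
        for g in range(hh_gstart[k], hh_gstart[k] + hh_gcount[k]):
            d = hg_def[g]
            if hg_kind[d] == 0:
                minf = _interp(hg_minf[d], vv)
                ef = _interp(hg_efac[d], vv)
            else:
                ca = sh_ca[c]
                cn = ca ** hg_hill[d]
                minf = cn / (cn + hg_kd[d] ** hg_hill[d])
                ef = hg_efca[d]
            s = minf + (hg_state[g] - minf) * ef
            hg_state[g] = s
            for _ in range(hg_exp[d]):
                o *= s
        gk = hh_g[k] * o
        hh_gopen[k] = gk
        gsum[c] += gk
        gesum[c] += gk * hh_e[k]

    # --- Markov channels (backward Euler on probabilities) ---
    qmat = np.zeros((8, 8))
    amat = np.zeros((8, 8))
    bvec = np.zeros(8)
    for k in range(mk_comp.shape[0]):
        c = mk_comp[k]
        vv = v[c]
        ca = dm_ca[c] if mk_casrc[k] == 1 else sh_ca[c]
        s = mk_scheme[k]
        ns = sc_nstates[s]
        for i in range(ns):
            for j in range(ns):
                qmat[i, j] = 0.0
        for t in range(sc_trstart[s], sc_trstart[s] + sc_trcount[s]):
            r = _interp(tr_tab[t], vv)
            if tr_ca[t] == 1:
                r *= ca
            qmat[tr_from[t], tr_to[t]] += r
        for i in range(ns):
            tot = 0.0
            for j in range(ns):
                if j != i:
                    tot += qmat[i, j]
            qmat[i, i] = -tot
        # A = I - dt*Q^T ; b = p
        off = mk_off[k]
        for i in range(ns):
            for j in range(ns):
                amat[i, j] = (1.0 if i == j else 0.0) - dt * qmat[j, i]
            bvec[i] = mk_p[off + i]
        # Gaussian elimination with partial pivoting (ns <= 8)
        for col in range(ns):
            piv = col
            big = abs(amat[col, col])
            for rr in range(col + 1, ns):
                if abs(amat[rr, col]) > big:
                    big = abs(amat[rr, col])
                    piv = rr
            if piv != col:
                for cc in range(ns):
                    tmp = amat[col, cc]
                    amat[col, cc] = amat[piv, cc]
                    amat[piv, cc] = tmp
                tmp = bvec[col]
                bvec[col] = bvec[piv]
                bvec[piv] = tmp
            inv = 1.0 / amat[col, col]
            for rr in range(col + 1, ns):
                f = amat[rr, col] * inv
                if f != 0.0:
                    for cc in range(col, ns):
                        amat[rr, cc] -= f * amat[col, cc]
                    bvec[rr] -= f * bvec[col]
        for i in range(ns - 1, -1, -1):
            acc = bvec[i]
            for j in range(i + 1, ns):
                acc -= amat[i, j] * bvec[j]
            bvec[i] = acc / amat[i, i]
        tot = 0.0
        for i in range(ns):
            if bvec[i] < 0.0:
                bvec[i] = 0.0
            tot += bvec[i]
        o = 0.0
        for i in range(ns):
            pi = bvec[i] / tot
            mk_p[off + i] = pi
            o += cw[sc_cwstart[s] + i] * pi
        gk = mk_g[k] * o
        mk_gopen[k] = gk
        gsum[c] += gk
        gesum[c] += gk * mk_e[k]

    # --- synaptic receptors ---
    for k in range(syn_comp.shape[0]):
        c = syn_comp[k]
        # transmitter transient (difference of exponentials)
        syn_ta[k] *= syn_efr[syn_kind[k]]
        syn_tb[k] *= syn_efd[syn_kind[k]]
        tr = syn_tb[k] - syn_ta[k]
        if tr < 0.0:
            tr = 0.0
        kk = syn_kind[k]
        o = syn_o[k]
        dd = syn_d[k]
        cfree = 1.0 - o - dd
        do = syn_kb[kk] * tr * cfree - syn_ku[kk] * o - syn_kdes[kk] * o
        ddd = syn_kdes[kk] * o - syn_kres[kk] * dd
        o += dt * do
        dd += dt * ddd
        if o < 0.0:
            o = 0.0
        if dd < 0.0:
            dd = 0.0
        if o + dd > 1.0:
            sc = 1.0 / (o + dd)
            o *= sc
            dd *= sc
        syn_o[k] = o
        syn_d[k] = dd
        geff = syn_g[k] * o
        if kk == 1:  # NMDA: voltage-dependent Mg unblock at current V
            unb = 1.0 / (1.0 + syn_mg_scale[kk] * math.exp(-syn_mg_slope[kk] * v[c]))
            geff *= unb
        gsum[c] += geff
        gesum[c] += geff * syn_e[k]
        syn_i[k] = geff * (v[c] - syn_e[k])  # provisional; refreshed after solve

    # --- assemble and solve implicit voltage update ---
    for i in range(n):
        diag[i] = cm_nf[i] / dt + gl_us[i] + gsum[i]
        rhs[i] = cm_nf[i] / dt * v[i] + gl_us[i] * el[i] + gesum[i]
        offd[i] = 0.0
    for i in range(1, n):
        p = parent[i]
        a = g_ax[i]
        diag[i] += a
        diag[p] += a
        offd[i] = a
    for k in range(ic_comp.shape[0]):
        rhs[ic_comp[k]] += ic_wave[k, istep]
    PEN = 1e9
    for k in range(vc_comp.shape[0]):
        diag[vc_comp[k]] += PEN
        rhs[vc_comp[k]] += PEN * vc_wave[k, istep]
    _hines_solve(parent, diag, offd, rhs, v_new)
    for k in range(vc_comp.shape[0]):
        vc_i[k] = PEN * (vc_wave[k, istep] - v_new[vc_comp[k]])

    # --- calcium influx at the new voltage ---
    for k in range(hh_comp.shape[0]):
        if hh_ca[k] == 1:
            c = hh_comp[k]
            cur = hh_gopen[k] * (v_new[c] - hh_e[k])
            if hh_cadest[k] == 1:
                ica2_acc[c] += cur
            else:
                ica_acc[c] += cur
    for k in range(mk_comp.shape[0]):
        if mk_ca[k] == 1:
            c = mk_comp[k]
            cur = mk_gopen[k] * (v_new[c] - mk_e[k])
            if mk_cadest[k] == 1:
                ica2_acc[c] += cur
            else:
                ica_acc[c] += cur
    for k in range(syn_comp.shape[0]):
        c = syn_comp[k]
        kk = syn_kind[k]
        geff = syn_g[k] * syn_o[k]
        if kk == 1:
            unb = 1.0 / (1.0 + syn_mg_scale[kk] * math.exp(-syn_mg_slope[kk] * v_new[c]))
            geff *= unb
        cur = geff * (v_new[c] - syn_e[k])
        syn_i[k] = cur
        if kk == 1:
            ic = syn_cafrac[kk] * cur
            syn_ica[k] = ic
            ica_acc[c] += ic

    # --- shell update (semi-implicit) ---
    for i in range(n):
        jin = -ica_acc[i] * sh_ifac[i]
        if jin < 0.0:
            jin = 0.0  # outward unitary K/Cl currents do not deplete the shell
        ca = sh_ca[i]
        b = sh_b[i]
        free_buf = sh_btot[i] - b
        dbdt = sh_kon * ca * free_buf - sh_koff * b
        dca = jin - dbdt - sh_kpump[i] * (ca - sh_carest)
        ca += dt * dca
        if ca < 1e-9:
            ca = 1e-9
        b += dt * dbdt
        if b < 0.0:
            b = 0.0
        elif b > sh_btot[i]:
            b = sh_btot[i]
        sh_ca[i] = ca
        sh_b[i] = b
        jin2 = -ica2_acc[i] * dm_ifac[i]
        if jin2 < 0.0:
            jin2 = 0.0
        ca2 = dm_ca[i] + dt * (jin2 - dm_k[i] * (dm_ca[i] - sh_carest))
        if ca2 < 1e-9:
            ca2 = 1e-9
        dm_ca[i] = ca2

    for i in range(n):
        v[i] = v_new[i]


@njit(cache=True)
def run_kernel(
    nsteps, dt,
    parent, g_ax, cm_nf, gl_us, el, v,
    hh_comp, hh_g, hh_e, hh_ca, hh_gstart, hh_gcount,
    hg_state, hg_def, hg_kind, hg_exp, hg_minf, hg_efac, hg_kd, hg_hill, hg_efca,
    mk_comp, mk_g, mk_e, mk_ca, mk_scheme, mk_off, mk_p,
    sc_nstates, sc_trstart, sc_trcount, sc_cwstart,
    tr_from, tr_to, tr_ca, tr_tab, cw,
    sh_ca, sh_b, sh_btot, sh_kon, sh_koff, sh_kpump, sh_carest, sh_ifac,
    dm_ca, dm_k, dm_ifac, hh_cadest, mk_cadest, mk_casrc,
    syn_comp, syn_kind, syn_g, syn_e,
    syn_efr, syn_efd, syn_kb, syn_ku, syn_kdes, syn_kres,
    syn_mg_scale, syn_mg_slope, syn_cafrac,
    ev_step, ev_syn, ev_w, ev_amp,
    ic_comp, ic_wave, vc_comp, vc_wave,
    rec_every, rec_kind, rec_idx, rec_out,
):
    n = v.shape[0]
    v_new = np.empty(n)
    gsum = np.empty(n)
    gesum = np.empty(n)
    diag = np.empty(n)
    offd = np.empty(n)
    rhs = np.empty(n)
    ica_acc = np.empty(n)
    ica2_acc = np.empty(n)
    hh_gopen = np.zeros(hh_comp.shape[0])
    mk_gopen = np.zeros(mk_comp.shape[0])
    syn_o = np.zeros(syn_comp.shape[0])
    syn_d = np.zeros(syn_comp.shape[0])
    syn_ta = np.zeros(syn_comp.shape[0])
    syn_tb = np.zeros(syn_comp.shape[0])
    syn_i = np.zeros(syn_comp.shape[0])
    syn_ica = np.zeros(syn_comp.shape[0])
    vc_i = np.zeros(vc_comp.shape[0])

    ev_ptr = 0
    nrec = rec_kind.shape[0]
    irow = 0
    for istep in range(nsteps):
        # presynaptic release events land at the start of the step
        while ev_ptr < ev_step.shape[0] and ev_step[ev_ptr] == istep:
            s = ev_syn[ev_ptr]
            amp = ev_w[ev_ptr] * ev_amp[syn_kind[s]]
            syn_ta[s] += amp
            syn_tb[s] += amp
            ev_ptr += 1
        _step(parent, g_ax, cm_nf, gl_us, el, v, v_new,
              hh_comp, hh_g, hh_e, hh_ca, hh_gstart, hh_gcount, hh_gopen,
              hg_state, hg_def, hg_kind, hg_exp, hg_minf, hg_efac, hg_kd,
              hg_hill, hg_efca,
              mk_comp, mk_g, mk_e, mk_ca, mk_scheme, mk_off, mk_p, mk_gopen,
              sc_nstates, sc_trstart, sc_trcount, sc_cwstart,
              tr_from, tr_to, tr_ca, tr_tab, cw,
              sh_ca, sh_b, sh_btot, sh_kon, sh_koff, sh_kpump, sh_carest,
              sh_ifac, ica_acc,
              dm_ca, dm_k, dm_ifac, ica2_acc, hh_cadest, mk_cadest, mk_casrc,
              syn_comp, syn_kind, syn_g, syn_e, syn_o, syn_d, syn_ta, syn_tb,
              syn_efr, syn_efd, syn_kb, syn_ku, syn_kdes, syn_kres,
              syn_mg_scale, syn_mg_slope, syn_cafrac, syn_i, syn_ica,
              ic_comp, ic_wave, vc_comp, vc_wave, vc_i,
              gsum, gesum, diag, offd, rhs, dt, istep)
        if not np.isfinite(v[0]):
            return istep  # integration failure; caller raises
        if (istep + 1) % rec_every == 0:
            for r in range(nrec):
                kk = rec_kind[r]
                ii = rec_idx[r]
                if kk == 0:
                    rec_out[irow, r] = v[ii]
                elif kk == 1:
                    rec_out[irow, r] = sh_ca[ii]
                elif kk == 2:
                    rec_out[irow, r] = hh_gopen[ii] * (v[hh_comp[ii]] - hh_e[ii])
                elif kk == 3:
                    rec_out[irow, r] = mk_gopen[ii] * (v[mk_comp[ii]] - mk_e[ii])
                elif kk == 4:
                    rec_out[irow, r] = syn_i[ii]
                elif kk == 5:
                    rec_out[irow, r] = vc_i[ii]
                elif kk == 6:
                    rec_out[irow, r] = syn_ica[ii]
                elif kk == 7:
                    rec_out[irow, r] = dm_ca[ii]
            irow += 1
    return nsteps
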