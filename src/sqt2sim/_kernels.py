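"""Compiled (numba) integration kernels for cell, strand and sheet models.

The host ventricular cell model is the 2006 ten Tusscher-Panfilov (TNNP)
formulation with EPI / MIDDLE / ENDO variants; its native Hodgkin-Huxley
IKs gate is replaced by the 17-state Markov-chain IKs open probability.
Hodgkin-Huxley gates advance by Rush-Larsen steps whose voltage-dependent
factors are linearly interpolated from precomputed tables; the Markov
occupancies advance by classical RK4 with stiffness-bounded sub-stepping
and renormalisation; concentrations advance by forward Euler with the
analytic (quadratic) buffering update.  Tissue coupling is monodomain
with explicit no-flux diffusion.

State vector layout per node (``NVAR`` doubles)::

    0      V (mV)
    1-11   gates m h j d f f2 fcass r s xr1 xr2
    12-17  Cai CaSR CaSS Nai Ki Rbar
    18-34  Markov occupancy, population 0 (C1..C15 O1 O2)
    35-51  Markov occupancy, population 1 (heterozygote only)
"""

from __future__ import annotations

import numpy as np
from numba import njit

NVAR = 52
_IV = 0
_IG = 1          # first gate index
_ICAI, _ICASR, _ICASS, _INAI, _IKI, _IRBAR = 12, 13, 14, 15, 16, 17
_IMC0, _IMC1 = 18, 35
N_MC = 17

# --- physical constants and TNNP 2006 parameters ---------------------------
R_GAS = 8314.472
TEMP = 310.0
FARADAY = 96485.3415
RTF = R_GAS * TEMP / FARADAY

CM = 0.185
V_C = 0.016404
V_SR = 0.001094
V_SS = 0.00005468

KO = 5.4
NAO = 140.0
CAO = 2.0

G_NA = 14.838
G_K1 = 5.405
G_KR = 0.153
G_TO_EPI = 0.294   # also MIDDLE
G_TO_ENDO = 0.073
G_CAL = 0.0000398
G_B_NA = 0.00029
G_B_CA = 0.000592
G_P_K = 0.0146
G_P_CA = 0.1238
K_P_CA = 0.0005
P_NAK = 2.724
KM_K = 1.0
KM_NA = 40.0
K_NACA = 1000.0
KM_NAI = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA_NACA = 0.35
ALPHA_NACA = 2.5
P_KNA = 0.03

V_MAXUP = 0.006375
K_UP = 0.00025
V_REL = 0.102
V_LEAK = 0.00036
V_XFER = 0.0038
K1_PRIME = 0.15
K2_PRIME = 0.045
K3_REL = 0.060
K4_REL = 0.005
EC_SR = 1.5
MAX_SR = 2.5
MIN_SR = 1.0
BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

#: MIDDLE-cell IKs conductance relative to EPI/ENDO (host-model ratio)
GKS_MIDDLE_FRACTION = 0.098 / 0.392

# cell-type codes
ENDO, MIDDLE, EPI = 0, 1, 2

# gate-table column layout: (inf, rush-larsen factor) pairs for
# m h j d f f2 r s_epi s_endo xr1 xr2, then voltage-only current factors
# (INaCa exponentials, INaK and IpK rectification, ICaL driving exponential)
N_TAB_GATES = 11
_COL_E1 = 2 * N_TAB_GATES
_COL_E2 = _COL_E1 + 1
_COL_INAK = _COL_E1 + 2
_COL_IPK = _COL_E1 + 3
_COL_EXPV15 = _COL_E1 + 4
N_TAB_COLS = _COL_E1 + 5


def build_gate_tables(dt: float, v_min: float = -120.0, v_max: float = 90.0,
                      dv: float = 0.02):
    """Tabulate gate steady states and Rush-Larsen factors on a V grid."""
    v = np.arange(v_min, v_max + dv / 2, dv)
    tab = np.empty((len(v), N_TAB_COLS))

    def put(col, inf, tau):
        tab[:, 2 * col] = inf
        tab[:, 2 * col + 1] = np.exp(-dt / tau)

    # INa gates
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) \
        + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    put(0, m_inf, am * bm)

    h_inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    ah = np.where(v >= -40.0, 0.0, 0.057 * np.exp(-(v + 80.0) / 6.8))
    bh = np.where(
        v >= -40.0,
        0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
        2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v),
    )
    put(1, h_inf, 1.0 / (ah + bh))

    aj = np.where(
        v >= -40.0,
        0.0,
        (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
        * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
    )
    bj = np.where(
        v >= -40.0,
        0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
        0.02424 * np.exp(-0.01052 * v)
        / (1.0 + np.exp(-0.1378 * (v + 40.14))),
    )
    put(2, h_inf, 1.0 / (aj + bj))  # j_inf == h_inf

    # ICaL voltage gates
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    put(3, d_inf, ad * bd + gd)

    f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tf = 1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0) \
        + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0)) \
        + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0
    put(4, f_inf, tf)

    f2_inf = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tf2 = 562.0 * np.exp(-((v + 27.0) ** 2) / 240.0) \
        + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0)) \
        + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0))
    put(5, f2_inf, tf2)

    # Ito gates
    r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tr = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    put(6, r_inf, tr)

    s_inf_epi = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
    ts_epi = 85.0 * np.exp(-((v + 45.0) ** 2) / 320.0) \
        + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0)) + 3.0
    put(7, s_inf_epi, ts_epi)

    s_inf_endo = 1.0 / (1.0 + np.exp((v + 28.0) / 5.0))
    ts_endo = 1000.0 * np.exp(-((v + 67.0) ** 2) / 1000.0) + 8.0
    put(8, s_inf_endo, ts_endo)

    # IKr gates
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    put(9, xr1_inf, axr1 * bxr1)

    xr2_inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    put(10, xr2_inf, axr2 * bxr2)

    vf_rt = v * FARADAY / (R_GAS * TEMP)
    tab[:, _COL_E1] = np.exp(GAMMA_NACA * vf_rt)
    tab[:, _COL_E2] = np.exp((GAMMA_NACA - 1.0) * vf_rt)
    tab[:, _COL_INAK] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vf_rt)
                               + 0.0353 * np.exp(-vf_rt))
    tab[:, _COL_IPK] = 1.0 / (1.0 + np.exp((25.0 - v) / 5.98))
    dv15 = np.where(np.abs(v - 15.0) < 1e-6, 1e-6, v - 15.0)
    tab[:, _COL_EXPV15] = np.exp(2.0 * dv15 * FARADAY / (R_GAS * TEMP))
    return v_min, 1.0 / dv, tab


# IK1 rectification on a (V - EK) axis
VK_MIN, VK_MAX, DVK = -60.0, 220.0, 0.05


def build_ik1_table():
    """Tabulate the IK1 open fraction against the driving voltage V-EK."""
    vk = np.arange(VK_MIN, VK_MAX + DVK / 2, DVK)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (vk - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (vk + 100.0)) + np.exp(0.1 * (vk - 10.0))) \
        / (1.0 + np.exp(-0.5 * vk))
    return ak1 / (ak1 + bk1)


def build_mc_rate_table(coef, v_min: float = -120.0, v_max: float = 90.0,
                        dv: float = 0.02):
    """Tabulate the 8 Markov class rates of one coefficient set."""
    v = np.arange(v_min, v_max + dv / 2, dv)
    out = np.empty((len(v), 8))
    for c in range(8):
        out[:, c] = coef[c, 0] * np.exp(coef[c, 1] * v)
    return out


@njit(cache=True)
def _mc_step(y, rates, esrc, edst, ecls, emul, dt, work):
    """RK4 advance of one 17-state occupancy vector at fixed rates.

    ``work`` is a (6, N_MC + n_edges) scratch buffer owned by the
    integration driver (allocating it per call would dominate
    tissue-scale run time); row 5 holds the per-edge rates.
    """
    n_edge = esrc.shape[0]
    er = work[5]
    for e in range(n_edge):
        er[e] = emul[e] * rates[ecls[e]]
    # stiffness-bounded sub-stepping: classical RK4 is stable to
    # h * max_exit ~ 2.8 on the real axis; keep a safety margin
    exit_sum = work[4]
    for k in range(N_MC):
        exit_sum[k] = 0.0
    for e in range(n_edge):
        exit_sum[esrc[e]] += er[e]
    max_exit = 0.0
    for k in range(N_MC):
        if exit_sum[k] > max_exit:
            max_exit = exit_sum[k]
    ns = 1
    if dt * max_exit > 2.0:
        ns = int(np.ceil(dt * max_exit / 2.0))
    h = dt / ns
    k1 = work[0]
    k2 = work[1]
    k3 = work[2]
    k4 = work[3]
    tmp = work[4]
    for _ in range(ns):
        _qmul(er, y, k1, esrc, edst)
        for k in range(N_MC):
            tmp[k] = y[k] + 0.5 * h * k1[k]
        _qmul(er, tmp, k2, esrc, edst)
        for k in range(N_MC):
            tmp[k] = y[k] + 0.5 * h * k2[k]
        _qmul(er, tmp, k3, esrc, edst)
        for k in range(N_MC):
            tmp[k] = y[k] + h * k3[k]
        _qmul(er, tmp, k4, esrc, edst)
        for k in range(N_MC):
            y[k] += (h / 6.0) * (k1[k] + 2.0 * k2[k] + 2.0 * k3[k] + k4[k])
    # renormalise
    total = 0.0
    for k in range(N_MC):
        if y[k] < 0.0:
            y[k] = 0.0
        total += y[k]
    for k in range(N_MC):
        y[k] /= total


@njit(cache=True)
def _qmul(er, y, out, esrc, edst):
    for k in range(N_MC):
        out[k] = 0.0
    for e in range(esrc.shape[0]):
        flux = er[e] * y[esrc[e]]
        out[esrc[e]] -= flux
        out[edst[e]] += flux


@njit(cache=True)
def _node_step(s, ct, vmin, inv_dv, tab, ktab, rtab0, rtab1, dt,
               gks0, gks1, npop, esrc, edst, ecls, emul, istim,
               rates, work):
    """Advance one node's gates/concentrations/Markov states by dt.

    Returns the total ionic current (pA/pF, stimulus excluded) evaluated
    at the step start, to be used in the caller's membrane update.
    """
    v = s[_IV]
    cai = s[_ICAI]
    casr = s[_ICASR]
    cass = s[_ICASS]
    nai = s[_INAI]
    ki = s[_IKI]

    # table lookup (linear interpolation)
    x = (v - vmin) * inv_dv
    if x < 0.0:
        x = 0.0
    elif x > tab.shape[0] - 2.0:
        x = tab.shape[0] - 2.0
    i0 = int(x)
    w1 = x - i0
    w0 = 1.0 - w1

    # reversal potentials
    ek = RTF * np.log(KO / ki)
    ena = RTF * np.log(NAO / nai)
    eca = 0.5 * RTF * np.log(CAO / cai)
    eks = RTF * np.log((KO + P_KNA * NAO) / (ki + P_KNA * nai))

    m = s[_IG + 0]
    h = s[_IG + 1]
    j = s[_IG + 2]
    d = s[_IG + 3]
    f = s[_IG + 4]
    f2 = s[_IG + 5]
    fcass = s[_IG + 6]
    r = s[_IG + 7]
    sg = s[_IG + 8]
    xr1 = s[_IG + 9]
    xr2 = s[_IG + 10]

    # currents
    ina = G_NA * m * m * m * h * j * (v - ena)

    dv15 = v - 15.0
    if -1e-6 < dv15 < 1e-6:
        dv15 = 1e-6
    expv15 = w0 * tab[i0, _COL_EXPV15] + w1 * tab[i0 + 1, _COL_EXPV15]
    ical = G_CAL * d * f * f2 * fcass * 4.0 * dv15 \
        * FARADAY * FARADAY / (R_GAS * TEMP) \
        * (0.25 * cass * expv15 - CAO) / (expv15 - 1.0)

    gto = G_TO_ENDO if ct == ENDO else G_TO_EPI
    ito = gto * r * sg * (v - ek)

    ikr = G_KR * xr1 * xr2 * (v - ek)

    # Markov IKs: population open probabilities
    po0 = s[_IMC0 + N_MC - 2] + s[_IMC0 + N_MC - 1]
    po1 = s[_IMC1 + N_MC - 2] + s[_IMC1 + N_MC - 1]
    gks_ct = GKS_MIDDLE_FRACTION if ct == MIDDLE else 1.0
    iks = gks_ct * (gks0 * po0 + gks1 * po1) * (v - eks)

    vk = (v - ek - VK_MIN) / DVK
    if vk < 0.0:
        vk = 0.0
    elif vk > ktab.shape[0] - 2.0:
        vk = ktab.shape[0] - 2.0
    k0 = int(vk)
    wk1 = vk - k0
    xk1 = (1.0 - wk1) * ktab[k0] + wk1 * ktab[k0 + 1]
    ik1 = G_K1 * xk1 * (v - ek)

    e1 = w0 * tab[i0, _COL_E1] + w1 * tab[i0 + 1, _COL_E1]
    e2 = w0 * tab[i0, _COL_E2] + w1 * tab[i0 + 1, _COL_E2]
    inaca = K_NACA * (e1 * nai ** 3 * CAO - e2 * NAO ** 3 * cai * ALPHA_NACA) \
        / ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO) * (1.0 + K_SAT * e2))

    inak_f = w0 * tab[i0, _COL_INAK] + w1 * tab[i0 + 1, _COL_INAK]
    inak = P_NAK * KO * nai / ((KO + KM_K) * (nai + KM_NA)) * inak_f

    ipca = G_P_CA * cai / (cai + K_P_CA)
    ipk_f = w0 * tab[i0, _COL_IPK] + w1 * tab[i0 + 1, _COL_IPK]
    ipk = G_P_K * (v - ek) * ipk_f
    ibna = G_B_NA * (v - ena)
    ibca = G_B_CA * (v - eca)

    iion = ina + ical + ito + ikr + iks + ik1 + inaca + inak \
        + ipca + ipk + ibna + ibca

    # --- gate updates (Rush-Larsen via tables) -----------------------------
    for g in range(N_TAB_GATES):
        # map table column to state slot; s-gate variant chosen by cell type
        if g < 6:        # m h j d f f2
            slot = _IG + g
        elif g == 6:     # r (slot 6 is the Ca-dependent fcass gate)
            slot = _IG + 7
        elif g == 7:     # s gate, EPI/MIDDLE variant
            if ct == ENDO:
                continue
            slot = _IG + 8
        elif g == 8:     # s gate, ENDO variant
            if ct != ENDO:
                continue
            slot = _IG + 8
        else:            # xr1, xr2
            slot = _IG + g
        inf = w0 * tab[i0, 2 * g] + w1 * tab[i0 + 1, 2 * g]
        rlf = w0 * tab[i0, 2 * g + 1] + w1 * tab[i0 + 1, 2 * g + 1]
        s[slot] = inf + (s[slot] - inf) * rlf

    # fcass gate (Ca-dependent)
    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    s[_IG + 6] = fcass_inf + (fcass - fcass_inf) * np.exp(-dt / tau_fcass)

    # --- calcium subsystem -------------------------------------------------
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) ** 2)
    k1 = K1_PRIME / kcasr
    k2 = K2_PRIME * kcasr
    rbar = s[_IRBAR]
    s[_IRBAR] = rbar + dt * (-k2 * cass * rbar + K4_REL * (1.0 - rbar))
    o_rel = k1 * cass * cass * rbar / (K3_REL + k1 * cass * cass)
    irel = V_REL * o_rel * (casr - cass)
    ileak = V_LEAK * (casr - cai)
    iup = V_MAXUP / (1.0 + (K_UP / cai) ** 2)
    ixfer = V_XFER * (cass - cai)

    # CaSR (quadratic buffering)
    ca_csqn = BUF_SR * casr / (casr + K_BUF_SR)
    d_casr = dt * (iup - irel - ileak)
    b = BUF_SR - ca_csqn - d_casr - casr + K_BUF_SR
    c = K_BUF_SR * (ca_csqn + d_casr + casr)
    s[_ICASR] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

    # CaSS
    ca_ssbuf = BUF_SS * cass / (cass + K_BUF_SS)
    d_cass = dt * (-ixfer * (V_C / V_SS) + irel * (V_SR / V_SS)
                   + (-ical * CM / (2.0 * V_SS * FARADAY)))
    b = BUF_SS - ca_ssbuf - d_cass - cass + K_BUF_SS
    c = K_BUF_SS * (ca_ssbuf + d_cass + cass)
    s[_ICASS] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

    # Cai
    ca_buf = BUF_C * cai / (cai + K_BUF_C)
    d_cai = dt * (-(ibca + ipca - 2.0 * inaca) * CM / (2.0 * V_C * FARADAY)
                  - (iup - ileak) * (V_SR / V_C) + ixfer)
    b = BUF_C - ca_buf - d_cai - cai + K_BUF_C
    c = K_BUF_C * (ca_buf + d_cai + cai)
    s[_ICAI] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

    # Na+ and K+ (stimulus carried as a K+ flux, as in the host model)
    s[_INAI] = nai - dt * (ina + ibna + 3.0 * inak + 3.0 * inaca) \
        * CM / (V_C * FARADAY)
    s[_IKI] = ki - dt * (ik1 + ito + ikr + iks + ipk + istim - 2.0 * inak) \
        * CM / (V_C * FARADAY)

    # --- Markov populations ------------------------------------------------
    for c8 in range(8):
        rates[c8] = w0 * rtab0[i0, c8] + w1 * rtab0[i0 + 1, c8]
    _mc_step(s[_IMC0:_IMC0 + N_MC], rates, esrc, edst, ecls, emul, dt, work)
    if npop == 2:
        for c8 in range(8):
            rates[c8] = w0 * rtab1[i0, c8] + w1 * rtab1[i0 + 1, c8]
        _mc_step(s[_IMC1:_IMC1 + N_MC], rates, esrc, edst, ecls, emul, dt,
                 work)

    return iion


@njit(cache=True)
def run_cell(s, ct, vmin, inv_dv, tab, ktab, rtab0, rtab1, dt, n_steps,
             gks0, gks1, npop, esrc, edst, ecls, emul,
             stim_starts, stim_amp, stim_dur, rec_stride):
    """Integrate a single cell; record V and IKs every ``rec_stride`` steps.

    ``stim_starts`` lists stimulus onset times (ms).  Returns
    (V_record, IKs_record) sampled at ``rec_stride * dt`` intervals.
    """
    n_rec = n_steps // rec_stride + 1
    v_rec = np.empty(n_rec)
    iks_rec = np.empty(n_rec)
    rates = np.empty(8)
    work = np.empty((6, 44))
    k_stim = 0
    n_stim = stim_starts.shape[0]
    idx = 0
    for step in range(n_steps + 1):
        t = step * dt
        istim = 0.0
        while k_stim < n_stim and t >= stim_starts[k_stim] + stim_dur:
            k_stim += 1
        if k_stim < n_stim and stim_starts[k_stim] <= t:
            istim = stim_amp
        if step % rec_stride == 0:
            eks = RTF * np.log((KO + P_KNA * NAO)
                               / (s[_IKI] + P_KNA * s[_INAI]))
            po0 = s[_IMC0 + N_MC - 2] + s[_IMC0 + N_MC - 1]
            po1 = s[_IMC1 + N_MC - 2] + s[_IMC1 + N_MC - 1]
            gks_ct = GKS_MIDDLE_FRACTION if ct == MIDDLE else 1.0
            v_rec[idx] = s[_IV]
            iks_rec[idx] = gks_ct * (gks0 * po0 + gks1 * po1) \
                * (s[_IV] - eks)
            idx += 1
        if step == n_steps:
            break
        iion = _node_step(s, ct, vmin, inv_dv, tab, ktab, rtab0, rtab1,
                          dt, gks0, gks1, npop, esrc, edst, ecls, emul,
                          istim, rates, work)
        s[_IV] = s[_IV] - dt * (iion + istim)
    return v_rec, iks_rec


@njit(cache=True)
def run_strand(S, ct, vmin, inv_dv, tab, ktab, rtab0, rtab1, dt, n_steps,
               gks0, gks1, npop, esrc, edst, ecls, emul,
               D, dx,
               s1_starts, s1_amp, s1_dur, s1_lo, s1_hi,
               s2_start, s2_amp, s2_dur, s2_lo, s2_hi,
               rec_stride):
    """Integrate a 1D monodomain strand with no-flux boundaries.

    S1 stimuli hit nodes ``[s1_lo, s1_hi)``; an optional premature S2
    (``s2_start < 0`` disables it) hits ``[s2_lo, s2_hi)``.  Records the
    full V(x) profile every ``rec_stride`` steps.
    """
    n = S.shape[0]
    n_rec = n_steps // rec_stride + 1
    v_rec = np.empty((n_rec, n))
    lap = np.empty(n)
    iion = np.empty(n)
    rates = np.empty(8)
    work = np.empty((6, 44))
    k_stim = 0
    n_stim = s1_starts.shape[0]
    idx = 0
    r_coef = D * dt / (dx * dx)
    for step in range(n_steps + 1):
        t = step * dt
        while k_stim < n_stim and t >= s1_starts[k_stim] + s1_dur:
            k_stim += 1
        s1_on = k_stim < n_stim and s1_starts[k_stim] <= t
        s2_on = s2_start >= 0.0 and s2_start <= t < s2_start + s2_dur
        if step % rec_stride == 0:
            for i in range(n):
                v_rec[idx, i] = S[i, _IV]
            idx += 1
        if step == n_steps:
            break
        for i in range(n):
            istim = 0.0
            if s1_on and s1_lo <= i < s1_hi:
                istim = s1_amp
            if s2_on and s2_lo <= i < s2_hi:
                istim += s2_amp
            iion[i] = _node_step(S[i], ct[i], vmin, inv_dv, tab, ktab,
                                 rtab0, rtab1, dt, gks0, gks1, npop,
                                 esrc, edst, ecls, emul, istim,
                                 rates, work) + istim
        for i in range(n):
            im = i - 1 if i > 0 else 1
            ip = i + 1 if i < n - 1 else n - 2
            lap[i] = S[im, _IV] + S[ip, _IV] - 2.0 * S[i, _IV]
        for i in range(n):
            S[i, _IV] = S[i, _IV] - dt * iion[i] + r_coef * lap[i]
    return v_rec


@njit(cache=True)
def run_sheet(S, ct, nx, ny, vmin, inv_dv, tab, ktab, rtab0, rtab1, dt,
              n_steps, gks0, gks1, npop, esrc, edst, ecls, emul,
              D, dx,
              s1_start, s1_amp, s1_dur, s1_cols,
              s2_start, s2_amp, s2_dur, s2_x0, s2_x1, s2_y0, s2_y1,
              snap_stride):
    """Integrate a 2D isotropic monodomain sheet (row-major node order).

    S1 is a planar stimulus on the first ``s1_cols`` columns; S2 a
    rectangular cross-field stimulus.  Returns the whole-field mean
    potential sampled every 1 ms, per-node last upstroke-crossing times
    (-20 mV, positive-going, after S2), and V snapshots every
    ``snap_stride`` steps.
    """
    n = S.shape[0]
    steps_per_ms = int(round(1.0 / dt))
    n_sig = n_steps // steps_per_ms + 1
    mean_v = np.empty(n_sig)
    last_act = np.full(n, -1.0)
    below = np.ones(n, np.bool_)
    n_snap = n_steps // snap_stride + 1
    snaps = np.empty((n_snap, n))
    iion = np.empty(n)
    lap = np.empty(n)
    rates = np.empty(8)
    work = np.empty((6, 44))
    r_coef = D * dt / (dx * dx)
    i_sig = 0
    i_snap = 0
    for step in range(n_steps + 1):
        t = step * dt
        if step % steps_per_ms == 0:
            acc = 0.0
            for i in range(n):
                acc += S[i, _IV]
            mean_v[i_sig] = acc / n
            i_sig += 1
        if step % snap_stride == 0:
            for i in range(n):
                snaps[i_snap, i] = S[i, _IV]
            i_snap += 1
        if step == n_steps:
            break
        s1_on = s1_start <= t < s1_start + s1_dur
        s2_on = s2_start >= 0.0 and s2_start <= t < s2_start + s2_dur
        for i in range(n):
            iy = i // nx
            ix = i - iy * nx
            istim = 0.0
            if s1_on and ix < s1_cols:
                istim = s1_amp
            if s2_on and s2_x0 <= ix < s2_x1 and s2_y0 <= iy < s2_y1:
                istim += s2_amp
            iion[i] = _node_step(S[i], ct[i], vmin, inv_dv, tab, ktab,
                                 rtab0, rtab1, dt, gks0, gks1, npop,
                                 esrc, edst, ecls, emul, istim,
                                 rates, work) + istim
        for i in range(n):
            iy = i // nx
            ix = i - iy * nx
            il = i - 1 if ix > 0 else (i + 1 if nx > 1 else i)
            ir = i + 1 if ix < nx - 1 else (i - 1 if nx > 1 else i)
            iu = i - nx if iy > 0 else (i + nx if ny > 1 else i)
            idn = i + nx if iy < ny - 1 else (i - nx if ny > 1 else i)
            lap[i] = (S[il, _IV] + S[ir, _IV] + S[iu, _IV] + S[idn, _IV]
                      - 4.0 * S[i, _IV])
        for i in range(n):
            vnew = S[i, _IV] - dt * iion[i] + r_coef * lap[i]
            S[i, _IV] = vnew
            # upstroke bookkeeping
            if vnew < -20.0:
                below[i] = True
            elif below[i]:
                below[i] = False
                last_act[i] = t
    return mean_v, last_act, snaps
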