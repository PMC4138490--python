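"""Fixed-step implicit integration kernel for the full coupled system.

One backward-Euler step of the cable equation (Thomas algorithm on the
chain-ordered tridiagonal Hines matrix) with staggered gate updates:
HH gates advance by exponential Euler at the pre-step voltage, the
13-state Markov Na occupancies advance by implicit Euler (dense 13x13
Gaussian elimination; the matrix I - dt*Q is strictly diagonally
dominant, so no pivoting is required), calcium shells and the cascade
advance by exact exponential updates with currents frozen over the step.

The GHK (CaLVA) current is nonlinear in V and is treated explicitly at
the pre-step voltage; all ohmic currents are implicit in V.

Everything is scalar float64 so that the identical source compiles under
numba (preferred) or runs as plain Python (fallback).

Gate column layout (per compartment):
  0 kv_m, 1 kv_h, 2 ka_a, 3 ka_b, 4 ks_x, 5 kca_c,
  6 ch_s, 7 ch_u, 8 cl_m, 9 cl_h, 10 h_l
Mechanism rows of the conductance matrix / recorded current totals:
  0 leak, 1 trp, 2 h, 3 kv, 4 ka, 5 kslow, 6 kca, 7 cahva, 8 calva, 9 na
Rate-multiplier vector:
  0 h, 1 kv, 2 ka, 3 kslow, 4 kca, 5 cahva, 6 calva_m, 7 calva_h, 8 na
"""

import math

import numpy as np

from ._rates import (
    ghk_flux_factor,
    h_linf,
    h_ltau,
    ka_ainf,
    ka_alpha_a,
    ka_alpha_b,
    ka_beta_a,
    ka_beta_b,
    ka_binf,
    kca_alpha,
    kca_beta,
    kslow_alpha,
    kslow_beta,
    kslow_xinf,
    kv_hinf,
    kv_htau,
    kv_minf,
    kv_mtau,
    calva_hinf,
    calva_htau,
    calva_minf,
    calva_mtau,
    cahva_alpha_s,
    cahva_alpha_u,
    cahva_beta_s,
    cahva_beta_u,
    na_fill_rates,
    njit,
)

from ._rates import GHK_CURRENT_COEF as GHK_COEF  # mA/cm^2 per (cm/s * mM)

NG = 11
NMECH = 10


@njit(cache=True)
def _solve13(a, x):
    """In-place Gaussian elimination for the 13x13 implicit Na step."""
    n = 13
    for k in range(n - 1):
        akk = a[k, k]
        for i in range(k + 1, n):
            f = a[i, k] / akk
            if f != 0.0:
                for j in range(k + 1, n):
                    a[i, j] -= f * a[k, j]
                x[i] -= f * x[k]
    for i in range(n - 1, -1, -1):
        s = x[i]
        for j in range(i + 1, n):
            s -= a[i, j] * x[j]
        x[i] = s / a[i, i]


@njit(cache=True)
def _expo(x, x_inf, k):
    """Exponential-Euler gate update toward x_inf with factor k=exp(-dt/tau)."""
    return x_inf + (x - x_inf) * k


@njit(cache=True)
def integrate(
    nsteps,
    dt,
    # state (mutated in place)
    v,            # (n,) mV
    gates,        # (n, NG)
    na_s,         # (n, 13)
    ca,           # (n,) mM
    casc,         # (2,) x_star, y_star (mM)
    # geometry / passive
    cap,          # (n,) nF
    gax,          # (n,) uS coupling node i to i-1 (gax[0] = 0)
    # conductance totals, uS (row 8 = calva GHK coefficient nA/mM, row 9 = na)
    gmech,        # (NMECH, n)
    e_leak, e_trp, e_h, e_k, e_na,
    rates,        # (9,) q10 rate multipliers
    htau_prm,     # (3,) delta, gamma, amplitude of the H tau law
    na_prm,       # (17,)
    rt_mv,
    # calcium shells
    ca_mask,      # (n,) 0/1
    ca_fac,       # (n,) mM per nA*ms
    beta_ca, ca_rest, ca_bath,
    # cascade (rates 1/ms)
    alpha_t,      # (nsteps,)
    c_beta, c_dmax, c_gamma, c_xtot, c_xhalf, c_k,
    c_ytot, c_trpbase, c_hsmax, c_hsmid, c_hsslope,
    # protocol
    mode,         # 0 current clamp, 1 voltage clamp
    inj_t,        # (nsteps,) nA at soma
    vcmd_t,       # (nsteps,) mV
    g_pip,        # uS
    soma,         # index
    # recording
    rec_stride,
    v_out,        # (nrec, n)
    ca_out,       # (nrec, n)
    im_out,       # (nrec, NMECH) summed currents, nA
    casc_out,     # (nrec, 6) x_star, y_star_norm, alpha, delta, trp_factor, h_shift
    istim_out,    # (nrec,)
):
    n = v.shape[0]
    amat = np.empty((13, 13))
    occ = np.empty(13)
    q = np.empty((13, 13))
    dlo = np.empty(n)
    dup = np.empty(n)
    diag = np.empty(n)
    rhs = np.empty(n)
    eca = np.empty(n)
    half_rt = 0.5 * rt_mv
    for i in range(n):
        eca[i] = half_rt * math.log(ca_bath / ca[i])
    max_na_err = 0.0
    xs = casc[0]
    ys = casc[1]

    # record initial state at index 0
    ysn0 = ys / c_ytot
    trp_fac = c_trpbase + ysn0
    h_shift = c_hsmax / (1.0 + math.exp((c_hsmid - ysn0) / c_hsslope))
    _record(0, n, v, gates, na_s, ca, eca, gmech, e_leak, e_trp, e_h, e_k, e_na,
            trp_fac, h_shift, rt_mv, ca_mask, ca_rest, ca_bath, v_out, ca_out, im_out)
    casc_out[0, 0] = xs
    casc_out[0, 1] = ysn0
    casc_out[0, 2] = 0.0
    casc_out[0, 3] = c_dmax / (1.0 + math.exp(-(xs - c_xhalf) * c_k))
    casc_out[0, 4] = trp_fac
    casc_out[0, 5] = h_shift
    istim_out[0] = 0.0

    for step in range(nsteps):
        # ---- cascade -----------------------------------------------------
        a = alpha_t[step]
        r1 = a + c_beta
        if r1 > 0.0:
            x_inf = c_xtot * a / r1
            xs = _expo(xs, x_inf, math.exp(-r1 * dt))
        dlt = c_dmax / (1.0 + math.exp(-(xs - c_xhalf) * c_k))
        r2 = dlt + c_gamma
        if r2 > 0.0:
            y_inf = c_ytot * dlt / r2
            ys = _expo(ys, y_inf, math.exp(-r2 * dt))
        ysn = ys / c_ytot
        trp_fac = c_trpbase + ysn
        h_shift = c_hsmax / (1.0 + math.exp((c_hsmid - ysn) / c_hsslope))

        # ---- gating ------------------------------------------------------
        for i in range(n):
            vi = v[i]
            if gmech[3, i] > 0.0:  # KV
                gates[i, 0] = _expo(gates[i, 0], kv_minf(vi),
                                    math.exp(-dt * rates[1] / kv_mtau(vi)))
                gates[i, 1] = _expo(gates[i, 1], kv_hinf(vi),
                                    math.exp(-dt * rates[1] / kv_htau(vi)))
            if gmech[4, i] > 0.0:  # KA
                ra = (ka_alpha_a(vi) + ka_beta_a(vi)) * rates[2]
                rb = (ka_alpha_b(vi) + ka_beta_b(vi)) * rates[2]
                gates[i, 2] = _expo(gates[i, 2], ka_ainf(vi), math.exp(-dt * ra))
                gates[i, 3] = _expo(gates[i, 3], ka_binf(vi), math.exp(-dt * rb))
            if gmech[5, i] > 0.0:  # Kslow
                rx = (kslow_alpha(vi) + kslow_beta(vi)) * rates[3]
                gates[i, 4] = _expo(gates[i, 4], kslow_xinf(vi), math.exp(-dt * rx))
            if gmech[6, i] > 0.0:  # KCa
                ac = kca_alpha(vi, ca[i]) * rates[4]
                bc = kca_beta(vi, ca[i]) * rates[4]
                gates[i, 5] = _expo(gates[i, 5], ac / (ac + bc), math.exp(-dt * (ac + bc)))
            if gmech[7, i] > 0.0:  # CaHVA
                as_ = cahva_alpha_s(vi) * rates[5]
                bs = cahva_beta_s(vi) * rates[5]
                au = cahva_alpha_u(vi) * rates[5]
                bu = cahva_beta_u(vi) * rates[5]
                gates[i, 6] = _expo(gates[i, 6], as_ / (as_ + bs), math.exp(-dt * (as_ + bs)))
                gates[i, 7] = _expo(gates[i, 7], au / (au + bu), math.exp(-dt * (au + bu)))
            if gmech[8, i] > 0.0:  # CaLVA
                gates[i, 8] = _expo(gates[i, 8], calva_minf(vi),
                                    math.exp(-dt * rates[6] / calva_mtau(vi)))
                gates[i, 9] = _expo(gates[i, 9], calva_hinf(vi),
                                    math.exp(-dt * rates[7] / calva_htau(vi)))
            if gmech[2, i] > 0.0:  # H (cascade-shifted)
                vs = vi - h_shift
                tl = h_ltau(vs, htau_prm[0], htau_prm[1], htau_prm[2])
                gates[i, 10] = _expo(gates[i, 10], h_linf(vs),
                                     math.exp(-dt * rates[0] / tl))
            if gmech[9, i] > 0.0:  # Markov Na, implicit Euler
                na_fill_rates(vi, rates[8], na_prm, q)
                for r_ in range(13):
                    for c_ in range(13):
                        amat[r_, c_] = -dt * q[r_, c_]
                    amat[r_, r_] += 1.0
                    occ[r_] = na_s[i, r_]
                _solve13(amat, occ)
                s = 0.0
                for r_ in range(13):
                    if occ[r_] < 0.0:
                        occ[r_] = 0.0
                    s += occ[r_]
                err = abs(s - 1.0)
                if err > max_na_err:
                    max_na_err = err
                for r_ in range(13):
                    na_s[i, r_] = occ[r_] / s

        # ---- voltage (backward Euler, tridiagonal) -----------------------
        cdt = 1.0 / dt
        for i in range(n):
            gsum = gmech[0, i] + gmech[1, i] * trp_fac
            esum = gmech[0, i] * e_leak + gmech[1, i] * trp_fac * e_trp
            if gmech[2, i] > 0.0:
                gh = gmech[2, i] * gates[i, 10]
                gsum += gh
                esum += gh * e_h
            if gmech[3, i] > 0.0:
                gk = gmech[3, i] * gates[i, 0] ** 3 * gates[i, 1]
                gsum += gk
                esum += gk * e_k
            if gmech[4, i] > 0.0:
                gk = gmech[4, i] * gates[i, 2] ** 3 * gates[i, 3]
                gsum += gk
                esum += gk * e_k
            if gmech[5, i] > 0.0:
                gk = gmech[5, i] * gates[i, 4]
                gsum += gk
                esum += gk * e_k
            if gmech[6, i] > 0.0:
                gk = gmech[6, i] * gates[i, 5]
                gsum += gk
                esum += gk * e_k
            if gmech[7, i] > 0.0:
                gc = gmech[7, i] * gates[i, 6] ** 2 * gates[i, 7]
                gsum += gc
                esum += gc * eca[i]
            if gmech[9, i] > 0.0:
                gna = gmech[9, i] * na_s[i, 5]
                gsum += gna
                esum += gna * e_na
            i_ghk = 0.0
            if gmech[8, i] > 0.0:
                phi = ghk_flux_factor(v[i], ca[i] if ca_mask[i] > 0.0 else ca_rest,
                                      ca_bath, rt_mv)
                i_ghk = gmech[8, i] * gates[i, 8] ** 2 * gates[i, 9] * phi
            c_over = cap[i] * cdt
            diag[i] = c_over + gsum
            rhs[i] = c_over * v[i] + esum - i_ghk
            dlo[i] = -gax[i]
            dup[i] = -(gax[i + 1] if i + 1 < n else 0.0)
            if i > 0:
                diag[i] += gax[i]
            if i + 1 < n:
                diag[i] += gax[i + 1]
        if mode == 0:
            rhs[soma] += inj_t[step]
        else:
            diag[soma] += g_pip
            rhs[soma] += g_pip * vcmd_t[step]
        # Thomas
        for i in range(1, n):
            w = dlo[i] / diag[i - 1]
            diag[i] -= w * dup[i - 1]
            rhs[i] -= w * rhs[i - 1]
        v[n - 1] = rhs[n - 1] / diag[n - 1]
        for i in range(n - 2, -1, -1):
            v[i] = (rhs[i] - dup[i] * v[i + 1]) / diag[i]

        # ---- calcium shells ---------------------------------------------
        for i in range(n):
            if ca_mask[i] > 0.0:
                i_ch = gmech[7, i] * gates[i, 6] ** 2 * gates[i, 7] * (v[i] - eca[i])
                influx = -i_ch * ca_fac[i]
                ca_inf = ca_rest + influx / beta_ca
                ca[i] = _expo(ca[i], ca_inf, math.exp(-beta_ca * dt))
                if ca[i] < 1e-12:
                    ca[i] = 1e-12
                eca[i] = half_rt * math.log(ca_bath / ca[i])

        # ---- record ------------------------------------------------------
        if (step + 1) % rec_stride == 0:
            r = (step + 1) // rec_stride
            _record(r, n, v, gates, na_s, ca, eca, gmech, e_leak, e_trp, e_h,
                    e_k, e_na, trp_fac, h_shift, rt_mv, ca_mask, ca_rest, ca_bath,
                    v_out, ca_out, im_out)
            casc_out[r, 0] = xs
            casc_out[r, 1] = ysn
            casc_out[r, 2] = a
            casc_out[r, 3] = dlt
            casc_out[r, 4] = trp_fac
            casc_out[r, 5] = h_shift
            if mode == 0:
                istim_out[r] = inj_t[step]
            else:
                istim_out[r] = g_pip * (vcmd_t[step] - v[soma])

    casc[0] = xs
    casc[1] = ys
    return max_na_err


@njit(cache=True)
def _record(r, n, v, gates, na_s, ca, eca, gmech, e_leak, e_trp, e_h, e_k, e_na,
            trp_fac, h_shift, rt_mv, ca_mask, ca_rest, ca_bath, v_out, ca_out, im_out):
    for m in range(NMECH):
        im_out[r, m] = 0.0
    for i in range(n):
        v_out[r, i] = v[i]
        ca_out[r, i] = ca[i]
        vi = v[i]
        im_out[r, 0] += gmech[0, i] * (vi - e_leak)
        im_out[r, 1] += gmech[1, i] * trp_fac * (vi - e_trp)
        if gmech[2, i] > 0.0:
            im_out[r, 2] += gmech[2, i] * gates[i, 10] * (vi - e_h)
        if gmech[3, i] > 0.0:
            im_out[r, 3] += gmech[3, i] * gates[i, 0] ** 3 * gates[i, 1] * (vi - e_k)
        if gmech[4, i] > 0.0:
            im_out[r, 4] += gmech[4, i] * gates[i, 2] ** 3 * gates[i, 3] * (vi - e_k)
        if gmech[5, i] > 0.0:
            im_out[r, 5] += gmech[5, i] * gates[i, 4] * (vi - e_k)
        if gmech[6, i] > 0.0:
            im_out[r, 6] += gmech[6, i] * gates[i, 5] * (vi - e_k)
        if gmech[7, i] > 0.0:
            im_out[r, 7] += gmech[7, i] * gates[i, 6] ** 2 * gates[i, 7] * (vi - eca[i])
        if gmech[8, i] > 0.0:
            ci = ca[i] if ca_mask[i] > 0.0 else ca_rest
            phi = ghk_flux_factor(vi, ci, ca_bath, rt_mv)
            im_out[r, 8] += gmech[8, i] * gates[i, 8] ** 2 * gates[i, 9] * phi
        if gmech[9, i] > 0.0:
            im_out[r, 9] += gmech[9, i] * na_s[i, 5] * (vi - e_na)
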