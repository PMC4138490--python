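"""Scalar gating-rate primitives for every ionic mechanism.

All functions take membrane potential in mV and return rates in 1/ms or
time constants in ms, *without* temperature correction — Q10 factors are
applied by the caller (multiply rates, divide time constants).

These are written as plain scalar Python so the same source compiles
under numba for the integration kernel and runs un-jitted everywhere
else.  Mechanism provenance: the delayed rectifier follows the Kv3.4
formulation (piecewise time constants expressed in seconds in the
original); KA, KCa (BK), Kslow (M-type) and CaHVA (L-type) follow the
cerebellar granule-cell formulations; CaLVA is the Cav3.1 T-type with
GHK permeation; the H current is the thalamocortical HCN Boltzmann with
the UBC midpoint (-91.5 mV, slope 7.7 mV).
"""

import math

try:  # pragma: no cover - exercised implicitly by the kernel
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def q10_factor(q10: float, t_sim: float, t_exp: float) -> float:
    """Rate multiplier q10 ** ((t_sim - t_exp) / 10)."""
    return q10 ** ((t_sim - t_exp) / 10.0)


# -- delayed rectifier (Kv3.4-type), n = m^3 * h ----------------------------

@njit(cache=True)
def kv_minf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 24.0) / 15.4))


@njit(cache=True)
def kv_mtau(v: float) -> float:
    """Activation time constant, ms (source expression in seconds)."""
    if v < -35.0:
        return 1e3 * (3.4225e-5 + 0.00498 * math.exp(v / 28.29)) * 3.0
    return 1e3 * (0.00012851 + 1.0 / (math.exp((v + 100.7) / 12.9) + math.exp(-(v - 56.0) / 23.1)))


@njit(cache=True)
def kv_hinf(v: float) -> float:
    return 0.31 + 0.69 / (1.0 + math.exp((v + 5.802) / 11.2))


@njit(cache=True)
def kv_htau(v: float) -> float:
    """Inactivation time constant, ms."""
    if v > 0.0:
        return 1e3 * (0.0012 + 0.0023 * math.exp(-0.141 * v))
    return 1e3 * (1.2202e-5 + 0.012 * math.exp(-(((v + 56.3) / 49.6) ** 2)))


# -- A-type K (granule-cell KA), n = a^3 * b --------------------------------

@njit(cache=True)
def ka_alpha_a(v: float) -> float:
    return 4.88826 / (1.0 + math.exp(-(v + 9.17203) / 23.32708))


@njit(cache=True)
def ka_beta_a(v: float) -> float:
    return 0.99285 / math.exp((v + 18.27914) / 19.47175)


@njit(cache=True)
def ka_alpha_b(v: float) -> float:
    return 0.11042 / (1.0 + math.exp((v + 111.33209) / 12.8433))


@njit(cache=True)
def ka_beta_b(v: float) -> float:
    return 0.10353 / (1.0 + math.exp(-(v + 49.9537) / 8.90123))


@njit(cache=True)
def ka_ainf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 38.0) / 17.0))


@njit(cache=True)
def ka_binf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v + 78.8) / 8.4))


# -- slow M-type K (granule-cell Kslow), n = x ------------------------------

@njit(cache=True)
def kslow_alpha(v: float) -> float:
    return 0.0033 * math.exp((v + 30.0) / 40.0)


@njit(cache=True)
def kslow_beta(v: float) -> float:
    return 0.0033 * math.exp(-(v + 30.0) / 20.0)


@njit(cache=True)
def kslow_xinf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 45.0) / 6.0))


# -- Ca-dependent K (BK), n = c; rates depend on shell [Ca2+] (mM) ----------

@njit(cache=True)
def kca_alpha(v: float, ca: float) -> float:
    return 2.5 / (1.0 + 1.5e-3 * math.exp(-v / 11.765) / ca)


@njit(cache=True)
def kca_beta(v: float, ca: float) -> float:
    return 1.5 / (1.0 + ca / (1.5e-4 * math.exp(-v / 11.765)))


# -- high-voltage-activated Ca (L-type), n = s^2 * u ------------------------

@njit(cache=True)
def cahva_alpha_s(v: float) -> float:
    return 0.04944 * math.exp((v + 29.06) / 15.87301587302)


@njit(cache=True)
def cahva_beta_s(v: float) -> float:
    return 0.08298 * math.exp(-(v + 18.66) / 25.6410256410)


@njit(cache=True)
def cahva_alpha_u(v: float) -> float:
    return 0.0013 * math.exp(-(v + 48.0) / 18.183)


@njit(cache=True)
def cahva_beta_u(v: float) -> float:
    return 0.0013 * math.exp((v + 48.0) / 83.33)


# -- low-voltage-activated Ca (T-type, Cav3.1; GHK permeation), n = m^2 h ---

@njit(cache=True)
def calva_minf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 52.0) / 5.0))


@njit(cache=True)
def calva_mtau(v: float) -> float:
    return 1.0 + 1.0 / (math.exp((v + 40.0) / 9.0) + math.exp(-(v + 102.0) / 18.0))


@njit(cache=True)
def calva_hinf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v + 72.0) / 7.0))


@njit(cache=True)
def calva_htau(v: float) -> float:
    return 15.0 + math.exp(-(v + 32.0) / 7.0)


# -- H current (HCN), n = l --------------------------------------------------

H_VHALF = -91.5
H_SLOPE = 7.7

#: raw printed tau parameters: tau = exp(gamma*delta*x) / (A*(1+exp(delta*x)))
#: with x = v - vhalf, A in 1/ms
H_TAU_RAW = (0.2, 0.65, 4.5 * 0.0005)
#: recalibrated (delta, gamma, A) anchored to tau(-130) ~= 180 ms and
#: tau(-90) ~= 630 ms (see docs/methods.md)
H_TAU_CALIBRATED = (0.075, 0.65, 8.0594e-4)


@njit(cache=True)
def h_linf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v - H_VHALF) / H_SLOPE))


@njit(cache=True)
def h_ltau(v: float, delta: float, gamma: float, amp: float) -> float:
    x = v - H_VHALF
    return math.exp(gamma * delta * x) / (amp * (1.0 + math.exp(delta * x)))


# -- GHK flux ----------------------------------------------------------------

@njit(cache=True)
def ghk_flux_factor(v: float, ci: float, co: float, rt_mv: float) -> float:
    """phi = u*(ci - co*exp(-u))/(1 - exp(-u)) with u = 2 v / (RT/F), in mM.

    Current density (mA/cm^2) for a divalent ion is
    192.97 * P(cm/s) * phi; continuous through v = 0 (series expansion)."""
    u = 2.0 * v / rt_mv
    if abs(u) < 1e-4:
        return (ci - co) + 0.5 * u * (ci + co) + u * u * (ci - co) / 12.0
    eu = math.exp(-u)
    return u * (ci - co * eu) / (1.0 - eu)


#: 2 * F * 1e-6 (mol/cm^3 per mM) * 1e3 (mA/A)  ->  mA/cm^2 per (cm/s * mM)
GHK_CURRENT_COEF = 2.0 * 96485.3321 * 1e-6 * 1e3  # = 192.97...


# -- Markov resurgent Na -----------------------------------------------------
# State order: 0..4 = C1..C5, 5 = O, 6 = B (open-blocked), 7..12 = I1..I6.
# Parameter vector layout (1/ms and mV):
NA_PARAM_NAMES = (
    "Aalfa", "Valfa", "Abeta", "Vbeta", "Agamma", "Adelta",
    "Aepsilon", "Ateta", "Vteta", "Con", "Coff", "Oon", "Ooff",
    "n1", "n2", "n3", "n4",
)

NA_DEFAULT_PARAMS = (
    353.91, 13.99, 1.272, 13.99, 150.0, 40.0,
    1.75, 0.0201, 25.0, 0.005, 0.5, 0.75, 0.005,
    5.422, 3.279, 1.83, 0.738,
)


@njit(cache=True)
def na_fill_rates(v: float, scale: float, prm, q) -> None:
    """Fill the 13x13 rate matrix Q (1/ms) at voltage v.

    q[i, j] is the rate from state j to state i; columns conserve
    probability (diagonal = -sum of leaving rates).  ``scale`` is the Q10
    rate multiplier.
    """
    Aalfa, Valfa, Abeta, Vbeta = prm[0], prm[1], prm[2], prm[3]
    Agamma, Adelta, Aeps, Ateta, Vteta = prm[4], prm[5], prm[6], prm[7], prm[8]
    Con, Coff, Oon, Ooff = prm[9], prm[10], prm[11], prm[12]
    n1, n2, n3, n4 = prm[13], prm[14], prm[15], prm[16]

    alfa = scale * Aalfa * math.exp(v / Valfa)
    beta = scale * Abeta * math.exp(-v / Vbeta)
    gamma = scale * Agamma
    delta = scale * Adelta
    epsilon = scale * Aeps
    teta = scale * Ateta * math.exp(-v / Vteta)
    con = scale * Con
    coff = scale * Coff
    oon = scale * Oon
    ooff = scale * Ooff
    alfac = (Oon / Con) ** 0.25
    btfac = (Ooff / Coff) ** 0.25

    for i in range(13):
        for j in range(13):
            q[i, j] = 0.0

    fwd = (n1, n2, n3, n4)
    bwd = (n4, n3, n2, n1)
    # closed chain C1..C5 (0..4) and inactivated chain I1..I5 (7..11)
    for k in range(4):
        q[k + 1, k] = fwd[k] * alfa          # C_k -> C_k+1
        q[k, k + 1] = bwd[k] * beta          # C_k+1 -> C_k
        q[8 + k, 7 + k] = fwd[k] * alfa * alfac  # I_k -> I_k+1
        q[7 + k, 8 + k] = bwd[k] * beta * btfac  # I_k+1 -> I_k
    # C5 <-> O
    q[5, 4] = gamma
    q[4, 5] = delta
    # O <-> B
    q[6, 5] = epsilon
    q[5, 6] = teta
    # O <-> I6
    q[12, 5] = oon
    q[5, 12] = ooff
    # I5 <-> I6
    q[12, 11] = gamma
    q[11, 12] = delta
    # vertical C_i <-> I_i, i = 1..5
    for k in range(5):
        q[7 + k, k] = con * alfac**k
        q[k, 7 + k] = coff * btfac**k
    # conservation
    for j in range(13):
        s = 0.0
        for i in range(13):
            if i != j:
                s += q[i, j]
        q[j, j] = -s
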