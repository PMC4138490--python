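"""Ionic mechanism specifications and channel-level operations.

Ten mechanisms: leak, TRP (voltage-independent cationic leak, 0 mV
reversal), H (HCN), KV (delayed rectifier), KA (A-type), Kslow (M-type),
KCa (BK-type, gated by shell calcium), CaHVA (L-type, ohmic with dynamic
Ca reversal), CaLVA (T-type, GHK permeation) and a 13-state Markov
resurgent Na current.

The numerically hot scalar primitives live in :mod:`ubcsim._rates`; this
module provides the typed, inspectable surface used by configuration,
tests, and analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _rates
from ._rates import (
    GHK_CURRENT_COEF,
    H_TAU_CALIBRATED,
    H_TAU_RAW,
    NA_DEFAULT_PARAMS,
    NA_PARAM_NAMES,
    ghk_flux_factor,
    na_fill_rates,
    q10_factor,
)
from .constants import rt_over_f

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "MarkovNaSpec",
    "q10_factor",
    "gate_steady_state",
    "gate_time_constant",
    "channel_current",
    "ghk_ca_current",
    "markov_na_rates",
    "na_stationary_distribution",
    "kca_rates",
    "MECHANISMS",
]


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gate: steady state, time constant, exponent.

    ``inf`` and ``tau`` are callables of (v, ca); calcium-independent
    gates ignore the second argument.  ``tau`` is uncorrected — Q10
    scaling divides it at simulation time.
    """

    name: str
    exponent: int
    inf: Callable[[float, float], float]
    tau: Callable[[float, float], float]
    q10: float = 3.0
    calcium_dependent: bool = False

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ValueError("gate exponent must be >= 1")


@dataclass
class ChannelSpec:
    """One ionic mechanism: gates, density, reversal, current law."""

    name: str
    gates: tuple[GateSpec, ...]
    gmax_density: float  # S/cm^2, or cm/s for GHK law
    reversal: float | None  # mV; None for GHK law / dynamic Ca reversal
    law: str = "ohmic"  # ohmic | ghk
    q10: float = 3.0

    def __post_init__(self) -> None:
        if self.gmax_density < 0:
            raise ValueError("gmax_density must be >= 0")
        if self.law not in ("ohmic", "ghk"):
            raise ValueError(f"unknown current law {self.law!r}")


@dataclass
class MarkovNaSpec:
    """13-state resurgent Na scheme (5 closed, open, open-blocked, 6
    inactivated); deterministic mean-field occupancies."""

    gmax_density: float = 0.192
    reversal: float = 63.0
    q10: float = 3.0
    params: dict[str, float] = field(
        default_factory=lambda: dict(zip(NA_PARAM_NAMES, NA_DEFAULT_PARAMS))
    )

    @property
    def param_vector(self) -> np.ndarray:
        return np.array([self.params[k] for k in NA_PARAM_NAMES], dtype=float)


def _g(inf, tau):
    return (lambda v, ca=0.0: inf(v)), (lambda v, ca=0.0: tau(v))


def _from_rates(alpha, beta):
    def inf(v, ca=0.0):
        a, b = alpha(v), beta(v)
        return a / (a + b)

    def tau(v, ca=0.0):
        return 1.0 / (alpha(v) + beta(v))

    return inf, tau


def _h_tau_factory(mode: str):
    d, g, a = H_TAU_CALIBRATED if mode == "calibrated" else H_TAU_RAW

    def tau(v, ca=0.0):
        return _rates.h_ltau(v, d, g, a)

    return tau


_kv_m = GateSpec("m", 3, *_g(_rates.kv_minf, _rates.kv_mtau))
_kv_h = GateSpec("h", 1, *_g(_rates.kv_hinf, _rates.kv_htau))
_ka_a = GateSpec(
    "a", 3, (lambda v, ca=0.0: _rates.ka_ainf(v)),
    (lambda v, ca=0.0: 1.0 / (_rates.ka_alpha_a(v) + _rates.ka_beta_a(v))),
)
_ka_b = GateSpec(
    "b", 1, (lambda v, ca=0.0: _rates.ka_binf(v)),
    (lambda v, ca=0.0: 1.0 / (_rates.ka_alpha_b(v) + _rates.ka_beta_b(v))),
)
_ks_x = GateSpec(
    "x", 1, (lambda v, ca=0.0: _rates.kslow_xinf(v)),
    (lambda v, ca=0.0: 1.0 / (_rates.kslow_alpha(v) + _rates.kslow_beta(v))),
)
_kca_c = GateSpec(
    "c", 1,
    (lambda v, ca: _rates.kca_alpha(v, ca) / (_rates.kca_alpha(v, ca) + _rates.kca_beta(v, ca))),
    (lambda v, ca: 1.0 / (_rates.kca_alpha(v, ca) + _rates.kca_beta(v, ca))),
    calcium_dependent=True,
)
_ch_s = GateSpec("s", 2, *_from_rates(_rates.cahva_alpha_s, _rates.cahva_beta_s))
_ch_u = GateSpec("u", 1, *_from_rates(_rates.cahva_alpha_u, _rates.cahva_beta_u))
_cl_m = GateSpec("m", 2, *_g(_rates.calva_minf, _rates.calva_mtau), q10=5.0)
_cl_h = GateSpec("h", 1, *_g(_rates.calva_hinf, _rates.calva_htau))
_h_l = GateSpec("l", 1, (lambda v, ca=0.0: _rates.h_linf(v)), _h_tau_factory("calibrated"))

#: mechanism registry with Table-1 densities and reversals
MECHANISMS: dict[str, ChannelSpec] = {
    "leak": ChannelSpec("leak", (), 2.101e-5, -70.0),
    "trp": ChannelSpec("trp", (), 1.0e-5, 0.0),
    "h": ChannelSpec("h", (_h_l,), 5.72e-4, -30.0),
    "kv": ChannelSpec("kv", (_kv_m, _kv_h), 6.75e-4, -84.69),
    "ka": ChannelSpec("ka", (_ka_a, _ka_b), 0.007, -84.69),
    "kslow": ChannelSpec("kslow", (_ks_x,), 0.0008, -84.69),
    "kca": ChannelSpec("kca", (_kca_c,), 0.0052, -84.69),
    "cahva": ChannelSpec("cahva", (_ch_s, _ch_u), 2.15e-4, None),
    "calva": ChannelSpec("calva", (_cl_m, _cl_h), 6.3e-5, None, law="ghk"),
}


def gate_steady_state(gate: GateSpec, v: float, ca: float | None = None) -> float:
    """Steady-state open fraction of one gate at voltage v (mV)."""
    if not np.isfinite(v):
        raise ValueError("v must be finite")
    if gate.calcium_dependent:
        if ca is None or ca <= 0:
            raise ValueError("calcium-dependent gate needs ca > 0")
        return float(gate.inf(v, ca))
    return float(gate.inf(v, 0.0))


def gate_time_constant(
    gate: GateSpec,
    v: float,
    ca: float | None = None,
    t_sim: float = 30.0,
    t_exp: float = 30.0,
) -> float:
    """Q10-corrected gate time constant in ms."""
    tau = gate.tau(v, ca if ca is not None else 0.0)
    return float(tau / q10_factor(gate.q10, t_sim, t_exp))


def channel_current(
    spec: ChannelSpec,
    gates: tuple[float, ...],
    v: float,
    area_um2: float,
    e_rev: float | None = None,
) -> float:
    """Ohmic channel current in nA (outward positive).

    I = gmax * area * prod(gate^exponent) * (V - E).
    """
    if spec.law != "ohmic":
        raise ValueError("channel_current applies the ohmic law only")
    e = spec.reversal if e_rev is None else e_rev
    if e is None:
        raise ValueError(f"{spec.name}: reversal potential required")
    open_frac = 1.0
    for g_spec, g in zip(spec.gates, gates):
        if not 0.0 <= g <= 1.0:
            raise ValueError("gate fractions must lie in [0, 1]")
        open_frac *= g**g_spec.exponent
    g_total_uS = spec.gmax_density * area_um2 * 1e-8 * 1e6
    return g_total_uS * open_frac * (v - e)


def ghk_ca_current(
    permeability: float,
    v: float,
    ca_in: float,
    ca_out: float,
    temperature: float = 30.0,
) -> float:
    """GHK current density (mA/cm^2) for Ca2+; inward negative.

    Continuous through v = 0 (series expansion of the removable
    singularity).  ``permeability`` in cm/s, concentrations in mM.
    """
    if ca_in <= 0 or ca_out <= 0:
        raise ValueError("concentrations must be > 0")
    phi = ghk_flux_factor(v, ca_in, ca_out, rt_over_f(temperature))
    return GHK_CURRENT_COEF * permeability * phi


def markov_na_rates(
    v: float, spec: MarkovNaSpec | None = None, rate_scale: float = 1.0
) -> np.ndarray:
    """13x13 transition-rate matrix (1/ms) of the resurgent Na scheme.

    Columns conserve probability: Q[i, j] is the j->i rate and the
    diagonal holds minus the total leaving rate, so d(occ)/dt = Q @ occ.
    """
    if not np.isfinite(v):
        raise ValueError("v must be finite")
    spec = spec or MarkovNaSpec()
    q = np.empty((13, 13), dtype=float)
    na_fill_rates(float(v), float(rate_scale), spec.param_vector, q)
    return q


def na_stationary_distribution(
    v: float, spec: MarkovNaSpec | None = None, rate_scale: float = 1.0
) -> np.ndarray:
    """Stationary occupancies at clamped voltage (nonneg, sums to 1)."""
    q = markov_na_rates(v, spec, rate_scale)
    a = np.vstack([q, np.ones(13)])
    b = np.zeros(14)
    b[-1] = 1.0
    occ, *_ = np.linalg.lstsq(a, b, rcond=None)
    occ = np.clip(occ, 0.0, None)
    return occ / occ.sum()


def kca_rates(v: float, ca_in: float) -> tuple[float, float]:
    """BK forward/backward rates (1/ms) at voltage v and shell [Ca2+] (mM)."""
    if ca_in <= 0:
        raise ValueError("ca_in must be > 0")
    return _rates.kca_alpha(v, ca_in), _rates.kca_beta(v, ca_in)
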