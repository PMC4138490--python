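"""Second-messenger cascade coupling synaptic trains to H/TRP modulation.

A receptor pool X converts reversibly to X* at a rate alpha(t) summed
over boxcar windows opened by each synaptic pulse; X* drives, through a
sigmoidal rate delta(X*), the conversion of a messenger Y (ATP-scale
initial amount, 5 mM) to Y*.  Normalized Y* then (i) scales the TRP
maximum conductance, Gmax_TRP * (0.16 + Y*norm), and (ii) shifts the H
activation midpoint to the right by up to ``h_shift_max`` mV through a
logistic in Y*norm (midpoint 0.6, slope 0.1).

Rates here are expressed in 1/s (the engine converts to 1/ms); state
amounts in mM.  Mass is conserved exactly: X + X* = x_total and
Y + Y* = y_total at all times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._rates import H_VHALF

__all__ = [
    "CascadeParams",
    "CascadeState",
    "synaptic_drive",
    "step_x",
    "delta_rate",
    "step_y",
    "modulated_trp_gmax",
    "modulated_h_half",
    "cascade_fixed_point",
]


@dataclass(frozen=True)
class CascadeParams:
    """Rate and coupling parameters of the generic cascade.

    omega: per-pulse forward-rate weight (1/s); window: boxcar length tau
    (ms); beta: X* -> X back rate (1/s); x_total: receptor amount (mM),
    set so x_half sits at 60% of the X* range; x_half (mM) and slope_k
    (1/mM) parameterize the sigmoidal delta; delta_max (1/s) its scale;
    gamma: Y* -> Y back rate (1/s); y_total: messenger amount (mM);
    trp_baseline: resting fraction of Gmax_TRP; h_shift_max/mid/slope:
    the Y*-dependent shift of the H activation midpoint (mV, normalized
    Y*, normalized Y*).
    """

    omega: float = 3.5
    window: float = 50.0
    beta: float = 1.2
    x_total: float = 4.5
    x_half: float = 2.7
    slope_k: float = 0.75
    delta_max: float = 2.5
    gamma: float = 5.5
    y_total: float = 5.0
    trp_baseline: float = 0.16
    h_shift_max: float = 25.0
    h_shift_mid: float = 0.6
    h_shift_slope: float = 0.1
    slope_form: str = "divisive"  # how slope_k enters delta: divisive | multiplicative

    def __post_init__(self) -> None:
        for name in ("omega", "beta", "delta_max", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.y_total <= 0 or self.x_total <= 0:
            raise ValueError("pool totals must be > 0")
        if not 0 < self.trp_baseline <= 1:
            raise ValueError("trp_baseline must lie in (0, 1]")
        if self.slope_form not in ("divisive", "multiplicative"):
            raise ValueError("slope_form must be 'divisive' or 'multiplicative'")


@dataclass
class CascadeState:
    """Cascade state; x/x_star and y/y_star conserve their totals."""

    x_star: float = 0.0
    y_star: float = 0.0
    params: CascadeParams = CascadeParams()

    @property
    def x(self) -> float:
        return self.params.x_total - self.x_star

    @property
    def y(self) -> float:
        return self.params.y_total - self.y_star

    @property
    def y_star_norm(self) -> float:
        return self.y_star / self.params.y_total


def synaptic_drive(t: float, pulse_times, params: CascadeParams) -> float:
    """Forward rate alpha(t) in 1/s: omega summed over every pulse whose
    boxcar window [t_s, t_s + tau) contains t; overlapping windows add."""
    tau = params.window
    n = 0
    for ts in pulse_times:
        if ts <= t < ts + tau:
            n += 1
    return n * params.omega


def step_x(state: CascadeState, alpha: float, dt: float) -> CascadeState:
    """Advance X <-> X* by dt (ms); alpha in 1/s.  Exact exponential
    update of the linear two-state system; conservation is maintained by
    construction (X = x_total - X*)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if state.x_star < 0:
        raise ValueError("negative state")
    p = state.params
    a = alpha * 1e-3  # 1/ms
    b = p.beta * 1e-3
    rate = a + b
    if rate <= 0:
        return state
    x_inf = p.x_total * a / rate
    state.x_star = x_inf + (state.x_star - x_inf) * math.exp(-rate * dt)
    return state


def delta_rate(x_star: float, params: CascadeParams) -> float:
    """Sigmoidal forward rate delta(X*) in 1/s: delta_max / 2 at x_half,
    saturating at delta_max.

    ``slope_form`` selects how the printed slope constant enters the
    logistic: divisive (z = (X* - X*_half) / K, the default — it gives
    the near-switch behavior of the reported threshold) or
    multiplicative (z = (X* - X*_half) * K).
    """
    if params.slope_form == "divisive":
        z = (x_star - params.x_half) / params.slope_k
    else:
        z = (x_star - params.x_half) * params.slope_k
    return params.delta_max / (1.0 + math.exp(-z))


def step_y(state: CascadeState, delta: float, dt: float) -> CascadeState:
    """Advance Y <-> Y* by dt (ms); delta in 1/s."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if state.y_star < 0:
        raise ValueError("negative state")
    p = state.params
    d = delta * 1e-3
    g = p.gamma * 1e-3
    rate = d + g
    if rate <= 0:
        return state
    y_inf = p.y_total * d / rate
    state.y_star = y_inf + (state.y_star - y_inf) * math.exp(-rate * dt)
    return state


def modulated_trp_gmax(y_star_norm: float, gmax_trp: float, baseline: float = 0.16) -> float:
    """Effective TRP maximum conductance: gmax * (baseline + Y*norm)."""
    if not 0.0 <= y_star_norm <= 1.0:
        raise ValueError("y_star_norm must lie in [0, 1]")
    return gmax_trp * (baseline + y_star_norm)


def modulated_h_half(y_star_norm: float, params: CascadeParams) -> float:
    """H activation midpoint (mV) under modulation: baseline -91.5 mV
    plus a logistic shift saturating at h_shift_max."""
    if not 0.0 <= y_star_norm <= 1.0:
        raise ValueError("y_star_norm must lie in [0, 1]")
    z = (params.h_shift_mid - y_star_norm) / params.h_shift_slope
    return H_VHALF + params.h_shift_max / (1.0 + math.exp(z))


def cascade_fixed_point(params: CascadeParams) -> CascadeState:
    """Resting fixed point with no synaptic drive.

    X* -> 0 exactly; the sigmoidal delta has a small nonzero floor at
    X* = 0, so resting Y* settles at delta(0)/(delta(0)+gamma) * y_total.
    """
    d0 = delta_rate(0.0, params)
    y_rest = params.y_total * d0 / (d0 + params.gamma) if d0 + params.gamma > 0 else 0.0
    return CascadeState(x_star=0.0, y_star=y_rest, params=params)


def pulse_train_times(n_pulses: int, frequency_hz: float, onset_ms: float = 0.0) -> np.ndarray:
    """Regular pulse-train onset times in ms."""
    if n_pulses < 0 or frequency_hz <= 0:
        raise ValueError("need n_pulses >= 0 and frequency > 0")
    return onset_ms + np.arange(n_pulses) * 1000.0 / frequency_hz
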