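"""Protocol execution: current clamp, voltage clamp, synaptic trains.

The engine flattens a :class:`~ubcsim.model.UBCModel` into the dense
arrays consumed by the implicit fixed-step kernel, computes the holding
bias current that keeps the soma at the requested holding potential
(standard current-clamp practice), and returns a :class:`Trace` with
voltages, per-mechanism currents, shell calcium and cascade variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _rates
from ._kernel import GHK_COEF, NG, NMECH, integrate
from ._rates import H_TAU_CALIBRATED, H_TAU_RAW, NA_PARAM_NAMES
from .channels import na_stationary_distribution
from .constants import rt_over_f
from .model import MECH_NAMES, UBCModel
from .morphology import chain_order, coupling_matrix

__all__ = [
    "ProtocolSpec",
    "Trace",
    "build_arrays",
    "init_steady_state",
    "run",
    "apply_channel_block",
    "convergence_check",
]

CASCADE_VARS = ("x_star", "y_star_norm", "alpha", "delta", "trp_factor", "h_vhalf_shift")


@dataclass(frozen=True)
class ProtocolSpec:
    """A stimulation protocol.

    ``steps`` are (amplitude, duration ms) pairs applied sequentially
    after ``pre_time``; amplitudes are pA in current clamp and mV
    (relative to holding) in voltage clamp.  ``pulse_train`` is
    (n_pulses, frequency Hz, intensity) driving the cascade only (the
    ionotropic receptors are pharmacologically silenced in the LOR
    protocol); the train starts at the end of ``pre_time``.
    """

    mode: str = "current_clamp"  # current_clamp | voltage_clamp
    holding: float = -80.0  # mV
    bias_nA: float | None = None  # fixed holding current (nA); None = solve for it
    pre_time: float = 200.0  # ms
    steps: tuple[tuple[float, float], ...] = ()
    post_time: float = 0.0  # ms
    pulse_train: tuple[int, float, float] | None = None
    dt: float = 0.025  # ms
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if any(dur <= 0 for _, dur in self.steps):
            raise ValueError("step durations must be > 0")

    @property
    def total_time(self) -> float:
        return self.pre_time + sum(d for _, d in self.steps) + self.post_time


@dataclass
class Trace:
    """Recorded time series of one protocol run."""

    time: np.ndarray  # ms
    v: np.ndarray  # (nt, ncomp) mV
    compartments: list[str]
    ca: np.ndarray  # (nt, ncomp) mM
    currents: np.ndarray  # (nt, nmech) nA, summed over compartments
    mechanisms: tuple[str, ...]
    cascade: np.ndarray  # (nt, 6)
    stim: np.ndarray  # nA (cc) or clamp current nA (vc)
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nt = len(self.time)
        for arr in (self.v, self.ca, self.currents, self.cascade, self.stim):
            if arr.shape[0] != nt:
                raise ValueError("trace channels must share the time grid")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def voltage(self, comp: str = "soma") -> np.ndarray:
        return self.v[:, self.compartments.index(comp)]

    @property
    def soma_v(self) -> np.ndarray:
        return self.voltage("soma")

    def current(self, mech: str) -> np.ndarray:
        return self.currents[:, self.mechanisms.index(mech)]

    def cascade_var(self, name: str) -> np.ndarray:
        return self.cascade[:, CASCADE_VARS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy wide frame: time plus one column per observable."""
        cols = {"time_ms": self.time}
        for i, c in enumerate(self.compartments):
            cols[f"v_{c}"] = self.v[:, i]
        for i, c in enumerate(self.compartments):
            cols[f"ca_{c}"] = self.ca[:, i]
        for i, m in enumerate(self.mechanisms):
            cols[f"i_{m}"] = self.currents[:, i]
        for i, nm in enumerate(CASCADE_VARS):
            cols[nm] = self.cascade[:, i]
        cols["i_stim"] = self.stim
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt: float | None = None, meta: dict | None = None) -> "Trace":
        comps = [c[2:] for c in df.columns if c.startswith("v_")]
        mechs = tuple(c[2:] for c in df.columns if c.startswith("i_") and c != "i_stim")
        time = df["time_ms"].to_numpy()
        return cls(
            time=time,
            v=df[[f"v_{c}" for c in comps]].to_numpy(),
            compartments=comps,
            ca=df[[f"ca_{c}" for c in comps]].to_numpy(),
            currents=df[[f"i_{m}" for m in mechs]].to_numpy(),
            mechanisms=mechs,
            cascade=df[list(CASCADE_VARS)].to_numpy(),
            stim=df["i_stim"].to_numpy(),
            dt=dt if dt is not None else float(np.median(np.diff(time))),
            meta=meta or {},
        )


# ---------------------------------------------------------------------------
# model flattening


class ModelArrays:
    """Dense per-compartment arrays of one model, in chain order."""

    def __init__(self, model: UBCModel):
        self.model = model
        morph = model.morphology
        self.order, gax = coupling_matrix(morph)
        self.n = len(self.order)
        self.soma = self.order.index("soma")
        self.gax = gax
        comps = [morph[name] for name in self.order]
        area_cm2 = np.array([c.effective_area_um2 * 1e-8 for c in comps])
        self.area_cm2 = area_cm2
        self.cap = area_cm2 * np.array([c.specific_capacitance for c in comps]) * 1e3  # nF

        self.gmech = np.zeros((NMECH, self.n))
        for mi, mech in enumerate(MECH_NAMES):
            for ci, c in enumerate(comps):
                dens = c.channel_densities.get(mech, 0.0)
                if mech == "calva":
                    # GHK: nA per (mM flux factor)
                    self.gmech[mi, ci] = GHK_COEF * dens * area_cm2[ci] * 1e6
                else:
                    self.gmech[mi, ci] = dens * area_cm2[ci] * 1e6  # uS
        m = model.mechanisms
        t = model.temperature
        self.e_leak = m["leak"].reversal
        self.e_trp = m["trp"].reversal
        self.e_h = m["h"].reversal
        self.e_k = m["kv"].reversal
        self.e_na = m["na"].reversal
        self.rates = np.array(
            [
                m["h"].rate_multiplier(t),
                m["kv"].rate_multiplier(t),
                m["ka"].rate_multiplier(t),
                m["kslow"].rate_multiplier(t),
                m["kca"].rate_multiplier(t),
                m["cahva"].rate_multiplier(t),
                m["calva"].rate_multiplier(t),  # activation, Q10 = 5
                m["calva"].rate_multiplier(t, m["calva"].q10_inact or 3.0, m["calva"].texp_inact),
                m["na"].rate_multiplier(t),
            ]
        )
        self.htau_prm = np.array(
            H_TAU_RAW if m["h"].tau_mode == "raw" else H_TAU_CALIBRATED
        )
        spec = model.na_spec()
        self.na_prm = np.array([spec.params[k] for k in NA_PARAM_NAMES])
        self.rt_mv = rt_over_f(t)

        cal = model.calcium
        self.ca_mask = np.array(
            [1.0 if name in cal.compartments else 0.0 for name in self.order]
        )
        depth_cm = cal.shell_depth_um * 1e-4
        vol = area_cm2 * depth_cm  # shell volume, cm^3
        # charge nA*ms = 1e-12 C; /(2F) mol; /vol mol/cm^3; *1e6 mM
        self.ca_fac = 1e-6 / (2.0 * 96485.3321 * vol)
        self.beta_ca = cal.beta_ca
        self.ca_rest = cal.ca_rest
        self.ca_bath = cal.ca_out

        cas = model.cascade
        k_eff = 1.0 / cas.slope_k if cas.slope_form == "divisive" else cas.slope_k
        self.casc_scalars = (
            cas.beta * 1e-3,
            cas.delta_max * 1e-3,
            cas.gamma * 1e-3,
            cas.x_total,
            cas.x_half,
            k_eff,
            cas.y_total,
            cas.trp_baseline,
            cas.h_shift_max,
            cas.h_shift_mid,
            cas.h_shift_slope,
        )
        pip = morph.pipette
        self.g_pip = 1.0 / pip.access_resistance if pip is not None else 0.05


def build_arrays(model: UBCModel) -> ModelArrays:
    return ModelArrays(model)


@dataclass
class EngineState:
    v: np.ndarray
    gates: np.ndarray
    na_s: np.ndarray
    ca: np.ndarray
    casc: np.ndarray  # x_star, y_star

    def copy(self) -> "EngineState":
        return EngineState(
            self.v.copy(), self.gates.copy(), self.na_s.copy(), self.ca.copy(), self.casc.copy()
        )


def _fresh_state(arr: ModelArrays, v_hold: float) -> EngineState:
    """Analytic fixed point of all gates/shells/cascade at clamped v_hold."""
    n = arr.n
    v = np.full(n, float(v_hold))
    gates = np.zeros((n, NG))
    r = arr.rates
    ca = np.full(n, arr.ca_rest)
    # calcium fixed point per shell (reversal depends on ca; iterate)
    s_inf = _ab_inf(_rates.cahva_alpha_s, _rates.cahva_beta_s, v_hold)
    u_inf = _ab_inf(_rates.cahva_alpha_u, _rates.cahva_beta_u, v_hold)
    for i in range(n):
        if arr.ca_mask[i] > 0 and arr.gmech[7, i] > 0:
            c = arr.ca_rest
            for _ in range(200):
                eca = 0.5 * arr.rt_mv * math.log(arr.ca_bath / c)
                i_ch = arr.gmech[7, i] * s_inf**2 * u_inf * (v_hold - eca)
                c_new = arr.ca_rest - i_ch * arr.ca_fac[i] / arr.beta_ca
                c_new = max(c_new, 1e-12)
                if abs(c_new - c) < 1e-15:
                    c = c_new
                    break
                c = c_new
            ca[i] = c
    for i in range(n):
        gates[i, 0] = _rates.kv_minf(v_hold)
        gates[i, 1] = _rates.kv_hinf(v_hold)
        gates[i, 2] = _rates.ka_ainf(v_hold)
        gates[i, 3] = _rates.ka_binf(v_hold)
        gates[i, 4] = _rates.kslow_xinf(v_hold)
        ac = _rates.kca_alpha(v_hold, ca[i])
        bc = _rates.kca_beta(v_hold, ca[i])
        gates[i, 5] = ac / (ac + bc)
        gates[i, 6] = s_inf
        gates[i, 7] = u_inf
        gates[i, 8] = _rates.calva_minf(v_hold)
        gates[i, 9] = _rates.calva_hinf(v_hold)
        gates[i, 10] = _rates.h_linf(v_hold)  # rest shift is ~0 (logistic floor)
    na = na_stationary_distribution(v_hold, arr.model.na_spec(), rate_scale=arr.rates[8])
    na_s = np.tile(na, (n, 1))
    # cascade rest: X* = 0; Y* at the fixed point of the delta floor
    cs = arr.casc_scalars
    d0 = cs[1] / (1.0 + math.exp(cs[4] * cs[5]))
    y_rest = cs[6] * d0 / (d0 + cs[2]) if d0 + cs[2] > 0 else 0.0
    return EngineState(v, gates, na_s, ca, np.array([0.0, y_rest]))


def _ab_inf(alpha, beta, v):
    a, b = alpha(v), beta(v)
    return a / (a + b)


def membrane_current_total(arr: ModelArrays, state: EngineState) -> float:
    """Total transmembrane current (nA) summed over compartments."""
    return float(np.sum(membrane_currents(arr, state)))


def membrane_currents(arr: ModelArrays, state: EngineState) -> np.ndarray:
    """Per-compartment membrane current (nA, outward positive)."""
    g = arr.gmech
    v = state.v
    gt = state.gates
    cs = arr.casc_scalars
    ysn = state.casc[1] / cs[6]
    trp_fac = cs[7] + ysn
    out = np.zeros(arr.n)
    for i in range(arr.n):
        vi = v[i]
        eca = 0.5 * arr.rt_mv * math.log(arr.ca_bath / state.ca[i])
        cur = g[0, i] * (vi - arr.e_leak)
        cur += g[1, i] * trp_fac * (vi - arr.e_trp)
        cur += g[2, i] * gt[i, 10] * (vi - arr.e_h)
        cur += g[3, i] * gt[i, 0] ** 3 * gt[i, 1] * (vi - arr.e_k)
        cur += g[4, i] * gt[i, 2] ** 3 * gt[i, 3] * (vi - arr.e_k)
        cur += g[5, i] * gt[i, 4] * (vi - arr.e_k)
        cur += g[6, i] * gt[i, 5] * (vi - arr.e_k)
        cur += g[7, i] * gt[i, 6] ** 2 * gt[i, 7] * (vi - eca)
        ci = state.ca[i] if arr.ca_mask[i] > 0 else arr.ca_rest
        cur += g[8, i] * gt[i, 8] ** 2 * gt[i, 9] * _rates.ghk_flux_factor(
            vi, ci, arr.ca_bath, arr.rt_mv
        )
        cur += g[9, i] * state.na_s[i, 5] * (vi - arr.e_na)
        out[i] = cur
    return out


def kirchhoff_residuals(arr: ModelArrays, state: EngineState, inj_soma: float) -> np.ndarray:
    """Nodal current residuals (nA): membrane + axial - injection."""
    res = membrane_currents(arr, state)
    v = state.v
    for i in range(1, arr.n):
        flow = arr.gax[i] * (v[i] - v[i - 1])
        res[i] += flow
        res[i - 1] -= flow
    res[arr.soma] -= inj_soma
    return res


def _run_kernel(
    arr: ModelArrays,
    state: EngineState,
    nsteps: int,
    dt: float,
    alpha_t: np.ndarray,
    mode: int,
    inj_t: np.ndarray,
    vcmd_t: np.ndarray,
    stride: int,
):
    nrec = nsteps // stride + 1
    v_out = np.empty((nrec, arr.n))
    ca_out = np.empty((nrec, arr.n))
    im_out = np.empty((nrec, NMECH))
    casc_out = np.empty((nrec, 6))
    istim_out = np.empty(nrec)
    cs = arr.casc_scalars
    err = integrate(
        nsteps, dt,
        state.v, state.gates, state.na_s, state.ca, state.casc,
        arr.cap, arr.gax, arr.gmech,
        arr.e_leak, arr.e_trp, arr.e_h, arr.e_k, arr.e_na,
        arr.rates, arr.htau_prm, arr.na_prm, arr.rt_mv,
        arr.ca_mask, arr.ca_fac, arr.beta_ca, arr.ca_rest, arr.ca_bath,
        alpha_t, *cs,
        mode, inj_t, vcmd_t, arr.g_pip, arr.soma,
        stride, v_out, ca_out, im_out, casc_out, istim_out,
    )
    return v_out, ca_out, im_out, casc_out, istim_out, err


_INIT_CACHE: dict[tuple, tuple[EngineState, float]] = {}

#: default relaxation time used when computing holding states, ms
DEFAULT_SETTLE_MS = 3000.0


def init_steady_state(
    model: UBCModel | ModelArrays,
    v_hold: float,
    dt: float = 0.025,
    settle_ms: float | None = None,
    tol_mv: float = 0.1,
    max_iter: int = 6,
    use_cache: bool = True,
) -> tuple[EngineState, float]:
    """Relax the full model to steady state at ``v_hold``.

    Returns the settled state and the constant bias current (nA) that
    holds the soma at ``v_hold`` in current clamp, found by secant
    iteration on the settled somatic voltage.  Raises if the iteration
    does not bring the soma within ``tol_mv`` of the target.
    """
    if settle_ms is None:
        settle_ms = DEFAULT_SETTLE_MS
    if not -120.0 <= v_hold <= -40.0:
        raise ValueError("v_hold outside the supported range [-120, -40] mV")
    arr = model if isinstance(model, ModelArrays) else build_arrays(model)
    key = (arr.model.config_hash(), round(v_hold, 6), dt)
    if use_cache and key in _INIT_CACHE:
        st, bias = _INIT_CACHE[key]
        return st.copy(), bias

    nsteps = int(round(settle_ms / dt))
    alpha0 = np.zeros(nsteps)
    vcmd0 = np.zeros(nsteps)

    def settle(bias: float) -> tuple[EngineState, float]:
        st = _fresh_state(arr, v_hold)
        inj = np.full(nsteps, bias)
        _run_kernel(arr, st, nsteps, dt, alpha0, 0, inj, vcmd0, nsteps)
        return st, st.v[arr.soma]

    b0 = membrane_current_total(arr, _fresh_state(arr, v_hold))
    st0, v0 = settle(b0)
    f0 = v0 - v_hold
    if abs(f0) <= tol_mv:
        _INIT_CACHE[key] = (st0.copy(), b0)
        return st0, b0
    b1 = b0 - f0 * 1e-3  # first guess: ~1 GOhm input resistance
    st1, v1 = settle(b1)
    f1 = v1 - v_hold
    for _ in range(max_iter):
        if abs(f1) <= tol_mv:
            _INIT_CACHE[key] = (st1.copy(), b1)
            return st1, b1
        if f1 == f0:
            break
        b2 = b1 - f1 * (b1 - b0) / (f1 - f0)
        b0, f0 = b1, f1
        b1 = b2
        st1, v1 = settle(b1)
        f1 = v1 - v_hold
    raise RuntimeError(
        f"holding-current search did not converge: soma at {v1:.2f} mV "
        f"for target {v_hold:.2f} mV (bias {b1 * 1e3:.3f} pA)"
    )


def run(model: UBCModel, protocol: ProtocolSpec) -> Trace:
    """Integrate the full coupled system under ``protocol``."""
    arr = build_arrays(model)
    dt = protocol.dt
    nsteps = int(round(protocol.total_time / dt))
    t_edges = np.arange(nsteps) * dt  # time at the START of each step

    if protocol.mode == "current_clamp":
        if protocol.bias_nA is not None:
            # imposed bias (e.g. the pre-drug holding current): relax the
            # model under it without re-solving for the holding potential
            state = _settle_with_bias(arr, protocol.holding, protocol.bias_nA, dt)
            bias = protocol.bias_nA
        else:
            state, bias = init_steady_state(arr, protocol.holding, dt=dt)
        mode = 0
        inj_t = np.full(nsteps, bias)
        t0 = protocol.pre_time
        for amp_pa, dur in protocol.steps:
            sel = (t_edges >= t0) & (t_edges < t0 + dur)
            inj_t[sel] += amp_pa * 1e-3
            t0 += dur
        vcmd_t = np.zeros(nsteps)
    else:
        state, bias = _init_voltage_clamp(arr, protocol.holding, dt)
        mode = 1
        vcmd_t = np.full(nsteps, protocol.holding)
        t0 = protocol.pre_time
        for amp_mv, dur in protocol.steps:
            sel = (t_edges >= t0) & (t_edges < t0 + dur)
            vcmd_t[sel] = protocol.holding + amp_mv
            t0 += dur
        inj_t = np.zeros(nsteps)

    alpha_t = np.zeros(nsteps)
    pulse_times = None
    if protocol.pulse_train is not None:
        n_p, freq, intensity = protocol.pulse_train
        pulse_times = protocol.pre_time + np.arange(n_p) * 1000.0 / freq
        omega_ms = model.cascade.omega * intensity * 1e-3
        for ts in pulse_times:
            sel = (t_edges >= ts) & (t_edges < ts + model.cascade.window)
            alpha_t[sel] += omega_ms

    stride = protocol.record_stride
    v_out, ca_out, im_out, casc_out, istim_out, err = _run_kernel(
        arr, state, nsteps, dt, alpha_t, mode, inj_t, vcmd_t, stride
    )
    if not np.all(np.isfinite(v_out)):
        bad = np.argwhere(~np.isfinite(v_out))[0]
        raise FloatingPointError(
            f"voltage diverged at t={bad[0] * dt * stride:.3f} ms in "
            f"compartment {arr.order[bad[1]]!r}"
        )
    time = np.arange(v_out.shape[0]) * dt * stride
    meta = {
        "config_hash": arr.model.config_hash(),
        "dt": dt,
        "record_stride": stride,
        "mode": protocol.mode,
        "holding": protocol.holding,
        "holding_current_nA": bias,
        "stim_onset": protocol.pre_time,
        "max_na_occupancy_error": float(err),
        "pulse_times": None if pulse_times is None else list(pulse_times),
    }
    return Trace(
        time=time,
        v=v_out,
        compartments=list(arr.order),
        ca=ca_out,
        currents=im_out,
        mechanisms=MECH_NAMES,
        cascade=casc_out,
        stim=istim_out,
        dt=dt * stride,
        meta=meta,
    )


def _settle_with_bias(arr: ModelArrays, v_start: float, bias: float, dt: float) -> EngineState:
    key = (arr.model.config_hash(), round(v_start, 6), round(bias, 9), "bias")
    if key in _INIT_CACHE:
        return _INIT_CACHE[key][0].copy()
    st = _fresh_state(arr, v_start)
    settle_dt = 0.025
    nsteps = int(round(DEFAULT_SETTLE_MS / settle_dt))
    zeros = np.zeros(nsteps)
    _run_kernel(arr, st, nsteps, settle_dt, zeros, 0, np.full(nsteps, bias), zeros, nsteps)
    _INIT_CACHE[key] = (st.copy(), bias)
    return st


def _init_voltage_clamp(arr: ModelArrays, v_hold: float, dt: float) -> tuple[EngineState, float]:
    # the settled state does not depend on the protocol dt; relax on the
    # default grid and cache per holding potential
    key = (arr.model.config_hash(), round(v_hold, 6), "vc")
    if key in _INIT_CACHE:
        st, bias = _INIT_CACHE[key]
        return st.copy(), bias
    st = _fresh_state(arr, v_hold)
    settle_dt = 0.025
    nsteps = int(round(2000.0 / settle_dt))
    zeros = np.zeros(nsteps)
    vcmd = np.full(nsteps, v_hold)
    _run_kernel(arr, st, nsteps, settle_dt, zeros, 1, zeros, vcmd, nsteps)
    _INIT_CACHE[key] = (st.copy(), 0.0)
    return st, 0.0


def apply_channel_block(model: UBCModel, mechanisms) -> UBCModel:
    """Copy of ``model`` with the listed mechanisms switched off."""
    return model.with_block(set(mechanisms))


def convergence_check(
    model: UBCModel, protocol: ProtocolSpec, dt_list
) -> pd.DataFrame:
    """Re-run ``protocol`` at each dt and report successive differences.

    Returns one row per refinement pair with the maximum somatic voltage
    difference (on the coarser grid) and the first-spike-time shift.
    """
    from .analysis import detect_spikes

    dts = list(dt_list)
    if len(dts) < 2:
        raise ValueError("need at least two dt values")
    traces = [run(model, replace(protocol, dt=d, record_stride=1)) for d in dts]
    rows = []
    for a, b in zip(traces, traces[1:]):
        va = a.soma_v
        tb = b.time
        vb = np.interp(a.time, tb, b.soma_v)
        sa = detect_spikes(a)
        sb = detect_spikes(b)
        shift = np.nan
        if len(sa.times) and len(sb.times):
            shift = abs(sa.times[0] - sb.times[0])
        rows.append(
            {
                "dt_coarse": a.dt,
                "dt_fine": b.dt,
                "max_dv": float(np.max(np.abs(va - vb))),
                "spike_count_coarse": len(sa.times),
                "spike_count_fine": len(sb.times),
                "first_spike_shift": shift,
            }
        )
    return pd.DataFrame(rows)
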