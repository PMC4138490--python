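"""Measurement pipeline applied identically to simulated (or synthetic)
voltage traces: spike detection at the 5 mV/ms depolarization-rate
criterion, step-response metrics (delay, overshoot, instantaneous and
steady-state frequency, frequency ratio = ISI1/ISI4), sag amplitude,
tri-exponential fits of voltage-clamp transients, late-onset-response
(LOR) metrics, the conductance robustness sweep, and the LOR
stimulus-response space.

All analysis functions are simulator-independent: they accept any
:class:`~ubcsim.engine.Trace` (or plain time/voltage arrays), so
synthetic fixtures with known ground truth exercise them directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .engine import ProtocolSpec, Trace, run

__all__ = [
    "SpikeDetection",
    "SpikeMetrics",
    "LORMetrics",
    "PassiveFit",
    "detect_spikes",
    "spike_metrics",
    "sag_amplitude",
    "fit_triexponential",
    "lor_metrics",
    "robustness_sweep",
    "response_space",
    "step_response",
    "lor_response",
    "passive_transient",
    "STEP_WINDOWS",
    "LOR_WINDOWS",
]

#: experimental acceptance windows for the +16 pA step protocol
STEP_WINDOWS = {
    "delay": (31.1, 93.4),  # ms
    "overshoot": (15.0, 45.1),  # mV
    "instantaneous_frequency": (95.9, 202.7),  # Hz
    "steady_state_frequency": (41.2, 141.8),  # Hz
    "frequency_ratio": (0.61, 1.3),
}

#: experimental acceptance windows for the LOR (10-pulse 100 Hz train)
LOR_WINDOWS = {
    "delay": (98.0, 1000.0),  # ms
    "duration": (100.0, 2500.0),  # ms
    "instantaneous_frequency": (92.0, 209.0),  # Hz
}


@dataclass
class SpikeDetection:
    """Per-spike threshold crossings, thresholds and peaks."""

    times: np.ndarray  # threshold-crossing times, ms
    thresholds: np.ndarray  # mV at crossing
    peaks: np.ndarray  # overshoot values, mV
    peak_times: np.ndarray  # ms


@dataclass
class SpikeMetrics:
    first_spike_delay: float  # ms; NaN if no spike
    overshoots: np.ndarray
    isi: np.ndarray  # ms
    instantaneous_frequency: float  # Hz = 1000/ISI1
    steady_state_frequency: float  # Hz = 1000/ISI4
    frequency_ratio: float  # ISI1/ISI4 (== ss/inst); needs >= 5 spikes
    spike_count: int


@dataclass
class LORMetrics:
    delay: float  # ms, train onset -> first spike threshold
    ramp_slope: float  # mV/s over the post-train ramp
    duration: float  # ms, first -> last spike
    instantaneous_frequency: float  # Hz
    spike_count: int
    no_lor: bool = False


@dataclass
class PassiveFit:
    amplitudes: np.ndarray  # nA, sorted by tau
    taus: np.ndarray  # ms, tau1 < tau2 < tau3
    offset: float  # nA
    r_in: float  # GOhm
    c_in: float  # pF (charge integral)
    c_in_fit: float  # pF (sum A_i tau_i / dV)
    r_s: float  # MOhm = tau1 / c_in
    residual_rms: float = 0.0


def _tv(trace, comp="soma"):
    if isinstance(trace, Trace):
        return trace.time, trace.voltage(comp)
    t, v = trace
    return np.asarray(t, float), np.asarray(v, float)


def detect_spikes(trace, rate_threshold: float = 5.0, refractory: float = 1.5) -> SpikeDetection:
    """Detect spikes where the depolarization rate first reaches
    ``rate_threshold`` (mV/ms); one detection per spike (refractory
    grouping), with per-spike threshold and overshoot peak."""
    t, v = _tv(trace)
    if len(t) < 3:
        return SpikeDetection(*(np.empty(0),) * 4)
    dt = np.diff(t)
    if np.max(dt) > 0.1 + 1e-9:
        raise ValueError("spike detection needs sampling at dt <= 0.1 ms")
    dvdt = np.gradient(v, t)
    # hysteretic threshold with refractory grouping: one event per spike,
    # and no retriggering while the rate hovers at the criterion
    rearm = rate_threshold - max(0.1 * rate_threshold, 0.5)
    crossings = []
    armed = True
    last = -np.inf
    for j in range(len(v)):
        if armed and dvdt[j] >= rate_threshold:
            if t[j] - last >= refractory:
                crossings.append(j)
                last = t[j]
            armed = False
        elif not armed and dvdt[j] < rearm:
            armed = True
    times, thrs, peaks, ptimes = [], [], [], []
    for k, idx in enumerate(crossings):
        # overshoot: maximum V between this crossing and the next one
        # (bounded at 30 ms for the last / a monotone ramp)
        stop_t = t[crossings[k + 1]] if k + 1 < len(crossings) else t[idx] + 30.0
        j_stop = int(np.searchsorted(t, min(stop_t, t[idx] + 30.0)))
        seg = v[idx: max(j_stop, idx + 1)]
        peak_j = idx + int(np.argmax(seg))
        times.append(t[idx])
        thrs.append(v[idx])
        peaks.append(v[peak_j])
        ptimes.append(t[peak_j])
    return SpikeDetection(
        np.array(times), np.array(thrs), np.array(peaks), np.array(ptimes)
    )


def spike_metrics(spikes: SpikeDetection, stim_onset: float = 0.0) -> SpikeMetrics:
    """Step-protocol spike metrics; frequencies need >= 2 (ISI1) and >= 5
    (ISI4, ratio) spikes and are NaN otherwise."""
    n = len(spikes.times)
    isi = np.diff(spikes.times)
    delay = spikes.times[0] - stim_onset if n else math.nan
    inst = 1000.0 / isi[0] if n >= 2 else math.nan
    ss = 1000.0 / isi[3] if n >= 5 else math.nan
    ratio = isi[0] / isi[3] if n >= 5 else math.nan
    return SpikeMetrics(
        first_spike_delay=delay,
        overshoots=spikes.peaks.copy(),
        isi=isi,
        instantaneous_frequency=inst,
        steady_state_frequency=ss,
        frequency_ratio=ratio,
        spike_count=n,
    )


def sag_amplitude(trace, step_window: tuple[float, float]) -> float:
    """Sag: minimum V during the hyperpolarizing step minus the mean V
    over the final 10% of the step (negative = sag below steady state)."""
    t, v = _tv(trace)
    t0, t1 = step_window
    sel = (t >= t0) & (t < t1)
    if not np.any(sel):
        raise ValueError("step window outside trace")
    vmin = float(np.min(v[sel]))
    tail = (t >= t1 - 0.1 * (t1 - t0)) & (t < t1)
    vss = float(np.mean(v[tail]))
    return vmin - vss


def _triexp(t, a1, a2, a3, t1, t2, t3, c):
    return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + a3 * np.exp(-t / t3) + c


def _triexp_drift(t, a1, a2, a3, t1, t2, t3, c, d):
    return _triexp(t, a1, a2, a3, t1, t2, t3, c) + d * t


def fit_triexponential(
    trace,
    step_onset: float,
    step_duration: float,
    delta_v: float,
    access_resistance: float | None = None,
    fit_window: float | None = None,
    drift: bool = True,
) -> PassiveFit:
    """Tri-exponential fit of a voltage-clamp current transient.

    ``trace`` must carry the clamp current (a :class:`Trace` in
    voltage-clamp mode, or a (time, current) pair in ms/nA).  Derives
    C_in from the displaced charge (integral of I - I_ss over the fit
    window, divided by the step size — robust to fit degeneracy), R_in
    from the steady-state current, and R_s = tau1 / C_in.

    The fit is restricted to ``fit_window`` ms after the step (default
    min(step_duration, 50 ms)); with ``drift`` (default) an auxiliary
    linear term absorbs slow active relaxation (the H current develops
    over hundreds of ms) so it does not contaminate the capacitive
    components.  Samples within 0.03 ms of the edge are excluded
    (sub-sample clamp artifact).
    """
    if delta_v == 0:
        raise ValueError("zero-amplitude step has no transient")
    if isinstance(trace, Trace):
        t, i = trace.time, trace.stim
    else:
        t, i = (np.asarray(a, float) for a in trace)
    if fit_window is None:
        fit_window = min(step_duration, 50.0)
    pre = (t >= step_onset - 0.2 * step_duration) & (t < step_onset)
    i_base = float(np.mean(i[pre])) if np.any(pre) else 0.0
    sel = (t > step_onset + 0.03) & (t < step_onset + fit_window)
    ts = t[sel] - step_onset
    y = i[sel] - i_base
    if len(y) == 0:
        raise ValueError("no samples inside the step")
    tail = ts > 0.8 * fit_window
    i_ss = float(np.mean(y[tail]))
    resid = y - i_ss
    k0 = int(np.argmax(np.abs(resid[: max(1, len(resid) // 10)])))
    amp0 = resid[k0]
    if abs(amp0) < 1e-9:
        raise ValueError("no transient to fit")
    lo = [-np.inf] * 3 + [0.05, 1e-3, 1e-2, -np.inf]
    hi = [np.inf] * 3 + [0.2 * fit_window, 0.5 * fit_window, 0.9 * fit_window, np.inf]
    p0 = [0.7 * amp0, 0.2 * amp0, 0.1 * amp0, 0.3, 3.0, 0.3 * fit_window, i_ss]
    if drift:
        p0.append(0.0)
        lo.append(-np.inf)
        hi.append(np.inf)
        popt, _ = curve_fit(_triexp_drift, ts, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        d_slope = float(popt[7])
    else:
        popt, _ = curve_fit(_triexp, ts, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        d_slope = 0.0
    a = np.array(popt[:3])
    tau = np.array(popt[3:6])
    order = np.argsort(tau)
    a, tau = a[order], tau[order]
    c = float(popt[6])
    fit = _triexp(ts, *popt[:7]) + d_slope * ts
    rms = float(np.sqrt(np.mean((y - fit) ** 2)))
    if rms > 0.25 * abs(amp0):
        raise RuntimeError(f"tri-exponential fit did not converge (rms {rms:.3g} nA)")
    i_ss = c
    # charge displaced by the capacitive transient, pC (nA * ms); the
    # linear drift term (slow conductance relaxation) is excluded, and
    # the censored initial interval [0, ts0) is filled in analytically
    # from the fitted exponentials
    q = float(np.trapezoid(y - i_ss - d_slope * ts, ts))
    q += float(np.sum(a * tau * (1.0 - np.exp(-ts[0] / tau))))
    c_in = abs(q / delta_v) * 1e3  # pF (pC/mV = nF)
    c_in_fit = abs(float(np.sum(a * tau)) / delta_v) * 1e3
    r_total = abs(delta_v / i_ss) * 1e-3  # GOhm, includes series resistance
    # tau_VC: the dominant (largest-amplitude) fast component
    tau_vc = float(tau[int(np.argmax(np.abs(a)))])
    r_s = tau_vc / c_in * 1e3  # MOhm (tau ms / C pF = GOhm)
    r_s_sub = access_resistance if access_resistance is not None else r_s
    r_in = r_total - r_s_sub * 1e-3
    return PassiveFit(
        amplitudes=a, taus=tau, offset=c + i_base, r_in=r_in,
        c_in=c_in, c_in_fit=c_in_fit, r_s=r_s, residual_rms=rms,
    )


def lor_metrics(
    trace,
    train_onset: float,
    train_end: float | None = None,
    rate_threshold: float = 5.0,
) -> LORMetrics:
    """LOR metrics: delay from train onset to the first spike, linear
    ramp slope between train end and the first spike threshold (or trace
    end when no spike fires), burst duration first-to-last spike, and the
    instantaneous frequency of the late burst."""
    t, v = _tv(trace)
    if train_end is None:
        train_end = train_onset
    spikes = detect_spikes((t, v), rate_threshold=rate_threshold)
    keep = spikes.times >= train_onset
    st = spikes.times[keep]
    n = len(st)
    if n:
        delay = st[0] - train_onset
        duration = st[-1] - st[0]
        inst = 1000.0 / (st[1] - st[0]) if n >= 2 else math.nan
        ramp_hi = st[0]
    else:
        delay = math.nan
        duration = math.nan
        inst = math.nan
        # no spike: fit the ramp up to its crest (the subthreshold
        # depolarization maximum after the train)
        post = t >= train_end
        ramp_hi = t[post][int(np.argmax(v[post]))] if np.any(post) else t[-1]
        if ramp_hi <= train_end:
            ramp_hi = t[-1]
    sel = (t >= train_end) & (t <= ramp_hi)
    if np.sum(sel) >= 2:
        slope = float(np.polyfit(t[sel], v[sel], 1)[0]) * 1e3  # mV/s
    else:
        slope = math.nan
    return LORMetrics(
        delay=delay,
        ramp_slope=slope,
        duration=duration,
        instantaneous_frequency=inst,
        spike_count=n,
        no_lor=(n == 0),
    )


# ---------------------------------------------------------------------------
# canonical protocols


def step_response(
    model,
    amplitude_pa: float,
    duration: float = 800.0,
    holding: float = -80.0,
    pre_time: float = 200.0,
    post_time: float = 200.0,
    dt: float = 0.025,
) -> Trace:
    """Current-clamp step from a holding potential (amplitude in pA)."""
    return run(
        model,
        ProtocolSpec(
            mode="current_clamp",
            holding=holding,
            pre_time=pre_time,
            steps=((amplitude_pa, duration),),
            post_time=post_time,
            dt=dt,
        ),
    )


def lor_response(
    model,
    n_pulses: int = 10,
    frequency: float = 100.0,
    intensity: float = 1.0,
    holding: float = -80.0,
    pre_time: float = 200.0,
    post_time: float = 3500.0,
    dt: float = 0.025,
    bias_nA: float | None = None,
) -> Trace:
    """Synaptic-train protocol driving the cascade (no direct electrical
    pulse effect); records >= 3 s after train onset.

    ``bias_nA`` imposes a fixed holding current instead of solving for
    one — used for in-silico pharmacology, where the pre-drug holding
    current is kept and the blocked cell settles away from the holding
    potential, as in the experiments.
    """
    return run(
        model,
        ProtocolSpec(
            mode="current_clamp",
            holding=holding,
            bias_nA=bias_nA,
            pre_time=pre_time,
            post_time=post_time,
            pulse_train=(n_pulses, frequency, intensity),
            dt=dt,
        ),
    )


def passive_transient(
    model,
    delta_v: float = -10.0,
    holding: float = -70.0,
    duration: float = 250.0,
    pre_time: float = 50.0,
    dt: float = 0.005,
) -> Trace:
    """Voltage-clamp step through the pipette (transient protocol)."""
    return run(
        model,
        ProtocolSpec(
            mode="voltage_clamp",
            holding=holding,
            pre_time=pre_time,
            steps=((delta_v, duration),),
            post_time=50.0,
            dt=dt,
        ),
    )


def step_metrics(trace: Trace) -> SpikeMetrics:
    """Spike metrics of a step trace, restricted to the step window."""
    onset = trace.meta["stim_onset"]
    spikes = detect_spikes(trace)
    keep = spikes.times >= onset
    sub = SpikeDetection(
        spikes.times[keep], spikes.thresholds[keep], spikes.peaks[keep], spikes.peak_times[keep]
    )
    return spike_metrics(sub, stim_onset=onset)


# ---------------------------------------------------------------------------
# sweeps


def robustness_sweep(
    model,
    conductance_ranges: dict[str, tuple[float, ...]],
    acceptance_windows: dict[str, dict[str, tuple[float, float]]] | None = None,
    step_amplitude_pa: float = 16.0,
    include_lor: bool = True,
    dt: float = 0.025,
) -> pd.DataFrame:
    """Scale each mechanism's maximum density over a grid, re-run the
    step (and optionally LOR) protocols, and flag which scalings keep
    every metric inside the acceptance windows.

    Returns a tidy frame (one row per mechanism x scale) with metrics,
    the pass flag, and per-mechanism admissible min/max scaling derivable
    by grouping on ``ok``.
    """
    if acceptance_windows is None:
        acceptance_windows = {"step": STEP_WINDOWS, "lor": LOR_WINDOWS}
    rows = []
    for mech, scales in conductance_ranges.items():
        for s in scales:
            m = model.with_scaled(mech, s)
            rec: dict = {"mechanism": mech, "scale": s}
            ok = True
            try:
                tr = step_response(m, step_amplitude_pa, dt=dt)
                sm = step_metrics(tr)
                rec.update(
                    step_delay=sm.first_spike_delay,
                    step_overshoot=float(sm.overshoots[0]) if sm.spike_count else math.nan,
                    step_inst=sm.instantaneous_frequency,
                    step_ss=sm.steady_state_frequency,
                    step_ratio=sm.frequency_ratio,
                    step_count=sm.spike_count,
                )
                win = acceptance_windows.get("step", {})
                vals = {
                    "delay": rec["step_delay"],
                    "overshoot": rec["step_overshoot"],
                    "instantaneous_frequency": rec["step_inst"],
                    "steady_state_frequency": rec["step_ss"],
                    "frequency_ratio": rec["step_ratio"],
                }
                ok &= _inside(vals, win)
            except (RuntimeError, FloatingPointError):
                ok = False
            if include_lor and ok:
                try:
                    tr = lor_response(m, dt=dt)
                    onset = tr.meta["stim_onset"]
                    train_end = tr.meta["pulse_times"][-1] + 10.0
                    lm = lor_metrics(tr, onset, train_end)
                    rec.update(
                        lor_delay=lm.delay,
                        lor_duration=lm.duration,
                        lor_inst=lm.instantaneous_frequency,
                        lor_count=lm.spike_count,
                    )
                    win = acceptance_windows.get("lor", {})
                    vals = {
                        "delay": lm.delay,
                        "duration": lm.duration,
                        "instantaneous_frequency": lm.instantaneous_frequency,
                    }
                    ok &= _inside(vals, win)
                except (RuntimeError, FloatingPointError):
                    ok = False
            rec["ok"] = bool(ok)
            rows.append(rec)
    return pd.DataFrame(rows)


def _inside(values: dict[str, float], windows: dict[str, tuple[float, float]]) -> bool:
    for key, (lo, hi) in windows.items():
        x = values.get(key, math.nan)
        if math.isnan(x) or not lo <= x <= hi:
            return False
    return True


def admissible_envelope(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per-mechanism min/max admissible scaling from a robustness sweep."""
    ok = sweep[sweep["ok"]]
    return ok.groupby("mechanism")["scale"].agg(["min", "max"]).reset_index()


def response_space(
    model,
    n_pulses_grid,
    intensity_grid,
    frequency: float = 100.0,
    dt: float = 0.025,
) -> pd.DataFrame:
    """LOR delay/duration/frequency surfaces over (n_pulses, intensity),
    plus peak Y* per run for the parameter-vs-Y* relations."""
    n_list = list(n_pulses_grid)
    i_list = list(intensity_grid)
    if not n_list or not i_list:
        raise ValueError("grids must be non-empty")
    rows = []
    for n_p in n_list:
        for inten in i_list:
            tr = lor_response(model, n_pulses=int(n_p), frequency=frequency, intensity=float(inten), dt=dt)
            onset = tr.meta["stim_onset"]
            train_end = tr.meta["pulse_times"][-1] + 10.0 if tr.meta["pulse_times"] else onset
            lm = lor_metrics(tr, onset, train_end)
            rows.append(
                {
                    "n_pulses": int(n_p),
                    "intensity": float(inten),
                    "delay": lm.delay,
                    "duration": lm.duration,
                    "instantaneous_frequency": lm.instantaneous_frequency,
                    "spike_count": lm.spike_count,
                    "peak_y_star": float(np.max(tr.cascade_var("y_star_norm"))),
                }
            )
    return pd.DataFrame(rows)
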