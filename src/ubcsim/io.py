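"""Trace and configuration I/O plus the synthetic fixture generator.

Traces round-trip bit-exactly: CSV uses 17-significant-digit decimal
(shortest exact float representation), HDF5 stores native float64.
Every output carries a JSON sidecar with the model config hash, dt and
package version, so identical configurations are verifiable offline.

The fixture generator produces seeded synthetic traces with ground-truth
metadata (spike times, exponential amplitudes/time constants, sag size,
LOR-like ramp/burst timing) for testing the analysis pipeline
independently of the simulator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .engine import CASCADE_VARS, Trace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_hdf5",
    "read_trace_hdf5",
    "generate_fixtures",
    "FIXTURE_KINDS",
]


def _sidecar(trace: Trace) -> dict:
    return {
        "ubcsim_version": _pkg_version,
        "dt": trace.dt,
        "meta": {
            k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
            for k, v in trace.meta.items()
        },
    }


def write_trace_csv(trace: Trace, path) -> Path:
    """Write a tidy CSV (one column per observable) plus a JSON sidecar."""
    path = Path(path)
    trace.to_frame().to_csv(path, index=False, float_format="%.17g")
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(_sidecar(trace), indent=1)
    )
    return path


def read_trace_csv(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    dt = None
    meta = {}
    if meta_path.exists():
        side = json.loads(meta_path.read_text())
        dt = side.get("dt")
        meta = side.get("meta", {})
    return Trace.from_frame(df, dt=dt, meta=meta)


def write_trace_hdf5(trace: Trace, path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=trace.time)
        fh.create_dataset("v", data=trace.v)
        fh.create_dataset("ca", data=trace.ca)
        fh.create_dataset("currents", data=trace.currents)
        fh.create_dataset("cascade", data=trace.cascade)
        fh.create_dataset("stim", data=trace.stim)
        fh.attrs["compartments"] = json.dumps(trace.compartments)
        fh.attrs["mechanisms"] = json.dumps(list(trace.mechanisms))
        fh.attrs["dt"] = trace.dt
        fh.attrs["sidecar"] = json.dumps(_sidecar(trace))
    return path


def read_trace_hdf5(path) -> Trace:
    import h5py

    with h5py.File(path, "r") as fh:
        side = json.loads(fh.attrs["sidecar"])
        return Trace(
            time=fh["time"][:],
            v=fh["v"][:],
            compartments=json.loads(fh.attrs["compartments"]),
            ca=fh["ca"][:],
            currents=fh["currents"][:],
            mechanisms=tuple(json.loads(fh.attrs["mechanisms"])),
            cascade=fh["cascade"][:],
            stim=fh["stim"][:],
            dt=float(fh.attrs["dt"]),
            meta=side.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# synthetic fixtures

FIXTURE_KINDS = ("spiketrain", "exponential_transient", "sag_trace", "lor_like")


def synthetic_trace(time: np.ndarray, v_soma: np.ndarray, stim: np.ndarray | None = None,
                    meta: dict | None = None) -> Trace:
    """Wrap a bare somatic voltage (or clamp-current) series as a Trace."""
    nt = len(time)
    z = np.zeros((nt, 1))
    return Trace(
        time=np.asarray(time, float),
        v=np.asarray(v_soma, float).reshape(-1, 1),
        compartments=["soma"],
        ca=z.copy(),
        currents=np.zeros((nt, 1)),
        mechanisms=("none",),
        cascade=np.zeros((nt, len(CASCADE_VARS))),
        stim=np.zeros(nt) if stim is None else np.asarray(stim, float),
        dt=float(time[1] - time[0]),
        meta=meta or {"synthetic": True},
    )


def _spike_waveform(t_rel: np.ndarray, rise: float = 0.4, fall: float = 1.2,
                    amp: float = 100.0) -> np.ndarray:
    """Stereotyped spike: double-exponential, zero before onset."""
    w = np.where(
        t_rel >= 0.0,
        (1.0 - np.exp(-np.maximum(t_rel, 0.0) / rise)) * np.exp(-np.maximum(t_rel, 0.0) / fall),
        0.0,
    )
    return amp * w / np.max(
        (1.0 - np.exp(-np.linspace(0, 10, 2001) / rise)) * np.exp(-np.linspace(0, 10, 2001) / fall)
    )


def generate_fixtures(kind: str, seed: int, out_dir=None) -> tuple[Trace, dict]:
    """Deterministic synthetic trace + ground-truth dict; optionally
    written to ``out_dir`` as CSV + JSON (same seed -> identical files)."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    dt = 0.025
    if kind == "spiketrain":
        t = np.arange(0.0, 1000.0, dt)
        v = np.full_like(t, -80.0)
        n = int(rng.integers(4, 9))
        onsets = np.sort(rng.uniform(100.0, 900.0, n))
        # enforce >= 20 ms separation
        while np.any(np.diff(onsets) < 20.0):
            onsets = np.sort(rng.uniform(100.0, 900.0, n))
        for on in onsets:
            v += _spike_waveform(t - on)
        # band-limited measurement noise (gaussian-smoothed, ~0.05 mV rms)
        kernel = np.exp(-0.5 * (np.arange(-80, 81) * dt / 1.0) ** 2)
        noise = np.convolve(rng.standard_normal(t.size), kernel / kernel.sum(), mode="same")
        v += 0.05 * noise / max(noise.std(), 1e-12)
        truth = {"spike_onsets": onsets.tolist(), "n_spikes": n,
                 "peak_amplitude": 20.0}
        tr = synthetic_trace(t, v, meta={"synthetic": True, "kind": kind, "seed": seed})
    elif kind == "exponential_transient":
        t = np.arange(0.0, 300.0, dt)
        onset = 50.0
        taus = np.sort(rng.uniform((0.2, 2.0, 8.0), (0.8, 5.0, 20.0)))
        amps = -np.sort(-rng.uniform((0.2, 0.04, 0.01), (0.5, 0.1, 0.03)))
        offset = -0.01
        i = np.zeros_like(t)
        rel = t - onset
        inside = rel >= 0
        for a, tau in zip(amps, taus):
            i[inside] += -a * np.exp(-rel[inside] / tau)
        i[inside] += offset
        truth = {"amplitudes": (-amps).tolist(), "taus": taus.tolist(),
                 "offset": offset, "onset": onset, "delta_v": -10.0,
                 "c_in_pF": float(np.sum(amps * taus) / 10.0 * 1e3)}
        tr = synthetic_trace(t, np.full_like(t, -70.0), stim=i,
                             meta={"synthetic": True, "kind": kind, "seed": seed})
    elif kind == "sag_trace":
        t = np.arange(0.0, 1200.0, dt)
        on, off = 200.0, 1000.0
        v_hold, v_min, v_ss = -80.0, -80.0 - rng.uniform(15, 30), -80.0 - rng.uniform(8, 12)
        tau_in, tau_sag = 15.0, 120.0
        v = np.full_like(t, v_hold)
        inside = (t >= on) & (t < off)
        rel = t[inside] - on
        drop = v_min - v_hold
        relax = v_ss - v_min
        v[inside] = v_hold + drop * (1 - np.exp(-rel / tau_in)) + relax * (
            1 - np.exp(-np.maximum(rel - 40.0, 0.0) / tau_sag)
        )
        after = t >= off
        v[after] = v_hold + (v[inside][-1] - v_hold) * np.exp(-(t[after] - off) / tau_in)
        truth = {"window": [on, off], "v_min": float(np.min(v[inside])),
                 "v_steady": float(np.mean(v[(t >= off - 0.1 * (off - on)) & (t < off)]))}
        truth["sag"] = truth["v_min"] - truth["v_steady"]
        tr = synthetic_trace(t, v, meta={"synthetic": True, "kind": kind, "seed": seed})
    else:  # lor_like
        t = np.arange(0.0, 3000.0, dt)
        onset = 200.0
        delay = float(rng.uniform(250, 600))
        n_spk = int(rng.integers(5, 10))
        isi0 = float(rng.uniform(6, 10))
        v = np.full_like(t, -80.0)
        ramp = (t >= onset) & (t < onset + delay)
        slope = 18.0 / delay  # mV per ms up to threshold region
        v[ramp] += slope * (t[ramp] - onset)
        spikes = onset + delay + np.cumsum([0] + [isi0 * (1 + 0.15 * k) for k in range(n_spk - 1)])
        for on in spikes:
            v += _spike_waveform(t - on)
        v[t >= onset + delay] = np.maximum(v[t >= onset + delay], -62.0)
        decay = t >= spikes[-1] + 20.0
        v[decay] = -80.0 + (v[decay] - (-80.0)) * np.exp(-(t[decay] - (spikes[-1] + 20.0)) / 150.0)
        truth = {"train_onset": onset, "delay": delay, "spike_times": list(spikes),
                 "duration": float(spikes[-1] - spikes[0]), "ramp_slope_mV_per_s": slope * 1e3}
        tr = synthetic_trace(t, v, meta={"synthetic": True, "kind": kind, "seed": seed})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trace_csv(tr, out_dir / f"{kind}_seed{seed}.csv")
        (out_dir / f"{kind}_seed{seed}.truth.json").write_text(json.dumps(truth, indent=1))
    return tr, truth
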