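"""Analysis pipeline on synthetic fixtures with exact ground truth —
simulator-independent by construction."""

import math

import numpy as np
import pytest

from ubcsim import analysis
from ubcsim.analysis import (
    SpikeDetection,
    detect_spikes,
    fit_triexponential,
    lor_metrics,
    sag_amplitude,
    spike_metrics,
)
from ubcsim.io import generate_fixtures, synthetic_trace


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 500, 0.025)
        tr = synthetic_trace(t, np.full_like(t, -80.0))
        assert len(detect_spikes(tr).times) == 0

    def test_synthetic_train_recovered_exactly(self):
        tr, truth = generate_fixtures("spiketrain", seed=3)
        det = detect_spikes(tr)
        assert len(det.times) == truth["n_spikes"]
        onsets = np.asarray(truth["spike_onsets"])
        # detection at the 5 mV/ms crossing occurs within 1 ms of onset
        assert np.all(np.abs(det.times - onsets) < 1.0)
        assert np.all(det.peaks > 0.0)  # overshoots above 0 mV

    def test_exact_threshold_ramp_triggers_at_most_once(self):
        t = np.arange(0, 100, 0.025)
        v = -80.0 + 5.0 * t  # exactly 5 mV/ms, no downturn
        tr = synthetic_trace(t, v)
        det = detect_spikes(tr)
        assert len(det.times) <= 1

    def test_coarse_sampling_rejected(self):
        t = np.arange(0, 100, 0.5)
        with pytest.raises(ValueError):
            detect_spikes(synthetic_trace(t, np.zeros_like(t)))


class TestSpikeMetrics:
    def test_printed_frequency_pair(self):
        """ISIs starting 5.68 ms and with ISI4 = 7.94 ms reproduce the
        reported instantaneous/steady-state frequencies and their ratio."""
        times = np.cumsum([100.0, 5.68, 6.0, 7.0, 7.94, 8.0])
        det = SpikeDetection(times, np.full(6, -45.0), np.full(6, 30.0), times + 0.5)
        m = spike_metrics(det, stim_onset=50.0)
        assert m.first_spike_delay == pytest.approx(50.0)
        assert m.instantaneous_frequency == pytest.approx(176.0, abs=0.1)
        assert m.steady_state_frequency == pytest.approx(125.9, abs=0.1)
        assert m.frequency_ratio == pytest.approx(0.715, abs=0.001)
        # identity: ratio == ss/inst
        assert m.frequency_ratio == pytest.approx(
            m.steady_state_frequency / m.instantaneous_frequency, rel=0.005
        )

    def test_single_spike_frequencies_undefined(self):
        det = SpikeDetection(np.array([120.0]), np.array([-45.0]), np.array([20.0]), np.array([120.5]))
        m = spike_metrics(det, stim_onset=100.0)
        assert m.first_spike_delay == pytest.approx(20.0)
        assert math.isnan(m.instantaneous_frequency)
        assert math.isnan(m.frequency_ratio)

    def test_uniform_isis_give_unit_ratio(self):
        times = 100.0 + 8.0 * np.arange(6)
        det = SpikeDetection(times, np.full(6, -45.0), np.full(6, 30.0), times)
        assert spike_metrics(det).frequency_ratio == pytest.approx(1.0)


class TestSag:
    def test_monotone_rc_response_has_no_sag(self):
        t = np.arange(0, 1000, 0.025)
        v = -80.0 - 20.0 * (1 - np.exp(-np.maximum(t - 200, 0) / 30.0))
        v[t >= 900] = v[np.searchsorted(t, 900.0)]
        tr = synthetic_trace(t, v)
        assert abs(sag_amplitude(tr, (200.0, 900.0))) < 0.05

    def test_synthetic_sag_recovered(self):
        tr, truth = generate_fixtures("sag_trace", seed=7)
        s = sag_amplitude(tr, tuple(truth["window"]))
        assert s == pytest.approx(truth["sag"], abs=0.05)
        assert s < -1.0  # genuinely sagging

    def test_window_outside_trace_rejected(self):
        t = np.arange(0, 100, 0.025)
        tr = synthetic_trace(t, np.zeros_like(t))
        with pytest.raises(ValueError):
            sag_amplitude(tr, (500.0, 900.0))


class TestTriexponentialFit:
    def test_known_triple_recovered(self):
        tr, truth = generate_fixtures("exponential_transient", seed=11)
        fit = fit_triexponential(
            (tr.time, tr.stim), step_onset=truth["onset"], step_duration=200.0,
            delta_v=truth["delta_v"], fit_window=120.0,
        )
        assert np.all(np.diff(fit.taus) > 0)
        # slowest/fastest taus recovered within 15%
        assert fit.taus[0] == pytest.approx(truth["taus"][0], rel=0.15)
        assert fit.taus[2] == pytest.approx(truth["taus"][2], rel=0.15)
        assert fit.c_in_fit == pytest.approx(truth["c_in_pF"], rel=0.05)

    def test_scale_equivariance(self):
        """Doubling the step amplitude doubles the amplitudes and leaves
        the time constants unchanged."""
        tr, truth = generate_fixtures("exponential_transient", seed=5)
        i2 = tr.stim * 2.0
        f1 = fit_triexponential((tr.time, tr.stim), truth["onset"], 200.0, -10.0, fit_window=120.0)
        f2 = fit_triexponential((tr.time, i2), truth["onset"], 200.0, -20.0, fit_window=120.0)
        assert np.allclose(f2.taus, f1.taus, rtol=1e-3)
        assert np.allclose(f2.amplitudes, 2.0 * f1.amplitudes, rtol=1e-3)
        assert f2.c_in == pytest.approx(f1.c_in, rel=1e-3)

    def test_zero_amplitude_step_rejected(self):
        tr, truth = generate_fixtures("exponential_transient", seed=5)
        with pytest.raises(ValueError):
            fit_triexponential((tr.time, tr.stim), truth["onset"], 200.0, 0.0)


class TestLORMetrics:
    def test_synthetic_lor_recovered(self):
        tr, truth = generate_fixtures("lor_like", seed=13)
        m = lor_metrics(tr, truth["train_onset"], truth["train_onset"] + 90.0)
        assert not m.no_lor
        assert m.delay == pytest.approx(truth["delay"], abs=15.0)
        assert m.duration == pytest.approx(truth["duration"], rel=0.05)
        assert m.spike_count == len(truth["spike_times"])
        assert m.ramp_slope == pytest.approx(truth["ramp_slope_mV_per_s"], rel=0.25)

    def test_no_spikes_flags_no_lor_but_reports_slope(self):
        t = np.arange(0, 3000, 0.025)
        v = -80.0 + np.where(t > 300, 3e-3 * (t - 300), 0.0)  # slow subthreshold ramp
        m = lor_metrics(synthetic_trace(t, v), 200.0, 290.0)
        assert m.no_lor
        assert math.isnan(m.delay)
        assert m.ramp_slope == pytest.approx(3.0, rel=0.05)  # mV/s
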