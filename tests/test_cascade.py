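"""Second-messenger cascade: drive windows, two-state kinetics,
conservation, and the TRP/H modulation laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ubcsim._rates import H_VHALF
from ubcsim.cascade import (
    CascadeParams,
    CascadeState,
    cascade_fixed_point,
    delta_rate,
    modulated_h_half,
    modulated_trp_gmax,
    pulse_train_times,
    step_x,
    step_y,
    synaptic_drive,
)

P = CascadeParams()


class TestSynapticDrive:
    def test_no_pulses(self):
        assert synaptic_drive(100.0, [], P) == 0.0

    def test_single_open_window(self):
        p = CascadeParams(window=50.0)
        assert synaptic_drive(30.0, [10.0], p) == p.omega

    def test_hundred_hertz_train_overlap(self):
        """10 pulses at 100 Hz with a 50 ms window: at t = 45 ms the
        windows opened at 0, 10, 20, 30, 40 ms are all active -> 5 omega."""
        p = CascadeParams(window=50.0)
        pulses = pulse_train_times(10, 100.0)
        assert synaptic_drive(45.0, pulses, p) == pytest.approx(5 * p.omega)

    @given(
        t=st.floats(0.0, 200.0),
        onsets=st.lists(st.floats(0.0, 150.0), min_size=0, max_size=12),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_brute_force_window_count(self, t, onsets):
        onsets = sorted(onsets)
        expected = sum(1 for ts in onsets if ts <= t < ts + P.window) * P.omega
        assert synaptic_drive(t, onsets, P) == pytest.approx(expected)


class TestTwoStateKinetics:
    def test_rest_fixed_point(self):
        s = CascadeState(params=P)
        step_x(s, 0.0, 1.0)
        assert s.x_star == 0.0

    def test_x_star_exponential_decay(self):
        s = CascadeState(x_star=1.0, params=P)
        t_ms = 500.0
        for _ in range(500):
            step_x(s, 0.0, 1.0)
        assert s.x_star == pytest.approx(math.exp(-P.beta * 1e-3 * t_ms), rel=1e-9)

    def test_x_star_equilibrium_under_constant_drive(self):
        alpha = 10.0  # 1/s
        s = CascadeState(params=P)
        for _ in range(20000):
            step_x(s, alpha, 1.0)
        assert s.x_star == pytest.approx(P.x_total * alpha / (alpha + P.beta), rel=1e-6)

    def test_y_star_decay_and_equilibrium(self):
        s = CascadeState(y_star=1.0, params=P)
        for _ in range(1000):
            step_y(s, 0.0, 1.0)
        assert s.y_star == pytest.approx(math.exp(-P.gamma * 1e-3 * 1000.0), rel=1e-9)
        # sustained delta = gamma -> half conversion
        s = CascadeState(params=P)
        for _ in range(30000):
            step_y(s, P.gamma, 1.0)
        assert s.y_star == pytest.approx(P.y_total / 2.0, rel=1e-5)

    def test_negative_state_rejected(self):
        s = CascadeState(x_star=-0.1, params=P)
        with pytest.raises(ValueError):
            step_x(s, 0.0, 1.0)

    @given(
        drives=st.lists(st.floats(0.0, 50.0), min_size=1, max_size=50),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_mass_conservation_under_arbitrary_drive(self, drives):
        s = CascadeState(params=P)
        for a in drives:
            step_x(s, a, 0.5)
            step_y(s, delta_rate(s.x_star, P), 0.5)
            assert s.x + s.x_star == pytest.approx(P.x_total, abs=1e-12)
            assert s.y + s.y_star == pytest.approx(P.y_total, abs=1e-12)
            assert s.x_star >= 0.0 and s.y_star >= 0.0


class TestDeltaRate:
    def test_midpoint(self):
        assert delta_rate(P.x_half, P) == pytest.approx(P.delta_max / 2.0)

    def test_floor(self):
        assert delta_rate(-50.0, P) < 1e-10 * P.delta_max

    def test_near_saturation_four_widths_above_half(self):
        x = P.x_half + 4.0 * P.slope_k  # divisive form: width K
        assert delta_rate(x, P) == pytest.approx(0.982 * P.delta_max, rel=2e-3)

    def test_multiplicative_form_selectable(self):
        import dataclasses

        pm = dataclasses.replace(P, slope_form="multiplicative")
        x = pm.x_half + 4.0 / pm.slope_k
        assert delta_rate(x, pm) == pytest.approx(0.982 * pm.delta_max, rel=2e-3)

    def test_threshold_sits_at_sixty_percent_of_range(self):
        # delta reaches half-max exactly when X* = 60% of x_total
        assert P.x_half / P.x_total == pytest.approx(0.6)


class TestModulation:
    def test_trp_baseline(self):
        assert modulated_trp_gmax(0.0, 1.0) == pytest.approx(0.16)

    def test_trp_unity_at_084(self):
        assert modulated_trp_gmax(0.84, 2.0) == pytest.approx(2.0)

    def test_trp_block(self):
        assert modulated_trp_gmax(0.5, 0.0) == 0.0

    def test_trp_range_enforced(self):
        with pytest.raises(ValueError):
            modulated_trp_gmax(1.5, 1.0)

    def test_h_shift_floor(self):
        v = modulated_h_half(0.0, P)
        assert abs(v - H_VHALF) < 0.0025 * P.h_shift_max

    def test_h_shift_midpoint(self):
        assert modulated_h_half(P.h_shift_mid, P) == pytest.approx(
            H_VHALF + P.h_shift_max / 2.0
        )

    def test_h_shift_saturates_at_minus_66_5(self):
        # logistic reaches ~98% of the 25 mV span at Y*norm = 1
        assert modulated_h_half(1.0, P) == pytest.approx(-66.5, abs=0.5)


class TestFixedPoint:
    def test_rest_has_zero_x_star_and_small_y_star(self):
        s = cascade_fixed_point(P)
        assert s.x_star == 0.0
        assert 0.0 < s.y_star_norm < 0.12  # small delta floor

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CascadeParams(trp_baseline=0.0)
        with pytest.raises(ValueError):
            CascadeParams(gamma=-1.0)
        with pytest.raises(ValueError):
            pulse_train_times(5, 0.0)
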