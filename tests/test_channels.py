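"""Channel-kinetics contracts: gate curves, Q10 scaling, current laws,
GHK permeation, BK calcium dependence and the Markov resurgent Na scheme."""

import math

import numpy as np
import pytest

from ubcsim import _rates
from ubcsim.channels import (
    MECHANISMS,
    MarkovNaSpec,
    channel_current,
    gate_steady_state,
    gate_time_constant,
    ghk_ca_current,
    kca_rates,
    markov_na_rates,
    na_stationary_distribution,
    q10_factor,
)


class TestQ10:
    @pytest.mark.parametrize(
        "q10, tsim, texp, expected",
        [(3.0, 30.0, 30.0, 1.0), (3.0, 40.0, 30.0, 3.0), (5.0, 20.0, 30.0, 0.2)],
    )
    def test_definition(self, q10, tsim, texp, expected):
        assert q10_factor(q10, tsim, texp) == pytest.approx(expected)

    def test_scaling_leaves_steady_state_and_divides_tau(self):
        gate = MECHANISMS["kv"].gates[0]
        v = -40.0
        assert gate_steady_state(gate, v) == gate_steady_state(gate, v)
        tau_30 = gate_time_constant(gate, v, t_sim=30.0, t_exp=30.0)
        tau_40 = gate_time_constant(gate, v, t_sim=40.0, t_exp=30.0)
        assert tau_40 == pytest.approx(tau_30 / 3.0)


class TestSteadyStates:
    def test_h_half_activation(self):
        gate = MECHANISMS["h"].gates[0]
        assert gate_steady_state(gate, -91.5) == pytest.approx(0.5)

    def test_h_one_slope_above_midpoint(self):
        gate = MECHANISMS["h"].gates[0]
        assert gate_steady_state(gate, -91.5 + 7.7) == pytest.approx(1 / (1 + math.e), rel=1e-6)

    def test_kv_activation_midpoint(self):
        gate = MECHANISMS["kv"].gates[0]
        assert gate_steady_state(gate, -24.0) == pytest.approx(0.5)

    def test_infinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            gate_steady_state(MECHANISMS["h"].gates[0], math.inf)

    @pytest.mark.parametrize("mech, gate_idx, direction", [
        ("kv", 0, +1), ("kv", 1, -1),
        ("ka", 0, +1), ("ka", 1, -1),
        ("kslow", 0, +1),
        ("cahva", 0, +1), ("cahva", 1, -1),
        ("calva", 0, +1), ("calva", 1, -1),
        ("h", 0, -1),
    ])
    def test_monotone_over_physiological_range(self, mech, gate_idx, direction):
        """Every gate's steady state is monotone in V on [-120, +60] mV —
        non-monotonicity would flag a transcription error."""
        gate = MECHANISMS[mech].gates[gate_idx]
        v = np.linspace(-120.0, 60.0, 361)
        x = np.array([gate_steady_state(gate, vi, ca=1e-4) for vi in v])
        dx = np.diff(x) * direction
        assert np.all(dx >= -1e-12)
        assert np.all((x >= 0.0) & (x <= 1.0))

    @pytest.mark.parametrize("mech, gate_idx", [
        ("kv", 0), ("kv", 1), ("ka", 0), ("ka", 1), ("kslow", 0),
        ("cahva", 0), ("cahva", 1), ("calva", 0), ("calva", 1), ("h", 0),
    ])
    def test_time_constants_positive(self, mech, gate_idx):
        gate = MECHANISMS[mech].gates[gate_idx]
        for v in np.linspace(-120.0, 60.0, 91):
            assert gate.tau(v, 1e-4) > 0.0


class TestChannelCurrent:
    def test_zero_driving_force(self):
        spec = MECHANISMS["kv"]
        assert channel_current(spec, (0.5, 0.5), spec.reversal, 200.0) == 0.0

    def test_closed_channel(self):
        spec = MECHANISMS["kv"]
        assert channel_current(spec, (0.0, 1.0), 0.0, 200.0) == 0.0

    def test_leak_outward_positive_above_reversal(self):
        spec = MECHANISMS["leak"]
        i = channel_current(spec, (), -60.0, 201.06)
        assert i > 0.0  # outward positive at V > E_leak = -70

    def test_gate_range_enforced(self):
        with pytest.raises(ValueError):
            channel_current(MECHANISMS["kv"], (1.5, 0.2), 0.0, 100.0)


class TestGHK:
    def test_equilibrium_zero(self):
        assert ghk_ca_current(6.3e-5, 0.0, 2.0, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_large_negative_voltage_inward_proportional_to_outside(self):
        i1 = ghk_ca_current(6.3e-5, -150.0, 1e-4, 1.0)
        i2 = ghk_ca_current(6.3e-5, -150.0, 1e-4, 2.0)
        assert i1 < 0.0
        assert i2 / i1 == pytest.approx(2.0, rel=1e-3)

    def test_continuity_through_zero(self):
        lo = ghk_ca_current(6.3e-5, -1e-9, 1e-4, 2.0)
        hi = ghk_ca_current(6.3e-5, +1e-9, 1e-4, 2.0)
        mid = ghk_ca_current(6.3e-5, 0.0, 1e-4, 2.0)
        scale = abs(ghk_ca_current(6.3e-5, -10.0, 1e-4, 2.0))
        assert abs(hi - lo) < 1e-9 * scale
        assert min(lo, hi) <= mid <= max(lo, hi) or abs(mid - lo) < 1e-9 * scale

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            ghk_ca_current(6.3e-5, -50.0, 0.0, 2.0)


class TestKCa:
    def test_alpha_saturates_at_printed_rate(self):
        a, _ = kca_rates(0.0, 1e6)
        assert a == pytest.approx(2.5, rel=1e-3)

    def test_alpha_vanishes_without_calcium(self):
        a, _ = kca_rates(0.0, 1e-12)
        assert a < 1e-6

    def test_midpoint_value(self):
        # at v = 0 the exponential term is 1: alpha = 2.5 / (1 + 1.5e-3/ca)
        a, _ = kca_rates(0.0, 1.5e-3)
        assert a == pytest.approx(1.25)

    def test_alpha_increases_beta_decreases_with_calcium(self):
        a1, b1 = kca_rates(-20.0, 1e-4)
        a2, b2 = kca_rates(-20.0, 1e-3)
        assert a2 > a1 > 0.0
        assert 0.0 < b2 < b1

    def test_nonpositive_calcium_rejected(self):
        with pytest.raises(ValueError):
            kca_rates(0.0, 0.0)


class TestMarkovNa:
    def test_off_diagonal_rates_nonnegative(self):
        for v in (-100.0, -50.0, 0.0, 40.0):
            q = markov_na_rates(v)
            off = q - np.diag(np.diag(q))
            assert np.all(off >= 0.0)

    def test_columns_conserve_probability(self):
        q = markov_na_rates(-60.0)
        assert np.allclose(q.sum(axis=0), 0.0, atol=1e-12)

    def test_stationary_distribution_sums_to_one(self):
        occ = na_stationary_distribution(-80.0)
        assert occ.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(occ >= 0.0)

    def test_resurgent_component_on_repolarization(self):
        """Depolarize to +30 mV (drive O -> blocked), then step to -40:
        the open state transiently re-peaks above its level at the end of
        the depolarization — the resurgent pathway through the blocked
        state."""
        spec = MarkovNaSpec()
        occ = na_stationary_distribution(-80.0, spec)
        dt = 0.01
        for v, dur in ((30.0, 20.0), (-40.0, 0.0)):
            q = markov_na_rates(v, spec)
            a = np.eye(13) - dt * q
            for _ in range(int(dur / dt)):
                occ = np.linalg.solve(a, occ)
                occ = np.clip(occ, 0.0, None)
                occ /= occ.sum()
        o_end_depol = occ[5]
        blocked_end_depol = occ[6]
        assert blocked_end_depol > 0.05  # open-channel block populated
        q = markov_na_rates(-40.0, spec)
        a = np.eye(13) - dt * q
        o_trace = []
        for _ in range(int(15.0 / dt)):
            occ = np.linalg.solve(a, occ)
            occ = np.clip(occ, 0.0, None)
            occ /= occ.sum()
            o_trace.append(occ[5])
        assert max(o_trace) > 1.5 * o_end_depol  # transient reopening

    def test_occupancy_conservation_under_protocol(self):
        spec = MarkovNaSpec()
        occ = na_stationary_distribution(-70.0, spec)
        dt = 0.025
        rng = np.random.default_rng(0)
        vs = rng.uniform(-100, 40, 400)
        for v in vs:
            q = markov_na_rates(float(v), spec)
            occ = np.linalg.solve(np.eye(13) - dt * q, occ)
        assert abs(occ.sum() - 1.0) < 1e-8


def test_table_densities_round_trip_bit_exact(tmp_path):
    """The canonical config carries the published maximum densities and
    reversals verbatim, and they survive YAML serialization bit-exactly."""
    import ubcsim

    model = ubcsim.load_canonical()
    expected = {
        "na": 0.192,
        "kv": 6.75e-4,
        "ka": 0.007,
        "kca": 0.0052,
        "kslow": 0.0008,
        "cahva": 2.15e-4,
        "calva": 6.3e-5,
        "h": 5.72e-4,
    }
    for mech, gmax in expected.items():
        assert model.mechanisms[mech].gmax == gmax
    assert model.mechanisms["na"].reversal == 63.0
    assert model.mechanisms["kv"].reversal == -84.69
    assert model.calcium.reversal_init == 129.33
    assert model.mechanisms["h"].reversal == -30.0
    assert model.mechanisms["trp"].reversal == 0.0
    assert model.mechanisms["leak"].reversal == -70.0
    path = tmp_path / "model.yaml"
    model.to_yaml(path)
    back = ubcsim.UBCModel.from_yaml(path)
    for mech, gmax in expected.items():
        assert back.mechanisms[mech].gmax == gmax
    assert back.config_hash() == model.config_hash()
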