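"""Integration-engine contracts: analytic RC oracle, pipette circuit,
steady-state initialization, Kirchhoff consistency, determinism and
dt-refinement convergence."""

import math

import numpy as np
import pytest

import ubcsim
from ubcsim import analysis
from ubcsim.engine import (
    ProtocolSpec,
    apply_channel_block,
    build_arrays,
    convergence_check,
    init_steady_state,
    kirchhoff_residuals,
    run,
    _run_kernel,
)
from ubcsim.model import UBCModel

LEAK_G = 2.101e-5  # S/cm^2


def _mech_cfg(**over):
    base = {
        "leak": {"gmax": LEAK_G, "reversal": -70.0, "density": {"all": 1.0}},
        "trp": {"gmax": 0.0, "reversal": 0.0},
        "h": {"gmax": 0.0, "reversal": -30.0},
        "kv": {"gmax": 0.0, "reversal": -84.69},
        "ka": {"gmax": 0.0, "reversal": -84.69},
        "kslow": {"gmax": 0.0, "reversal": -84.69},
        "kca": {"gmax": 0.0, "reversal": -84.69},
        "cahva": {"gmax": 0.0},
        "calva": {"gmax": 0.0},
        "na": {"gmax": 0.0, "reversal": 63.0},
    }
    base.update(over)
    return base


def soma_only_passive() -> UBCModel:
    """A single spherical compartment with leak only — the analytic RC cell."""
    cfg = {
        "name": "rc-oracle",
        "temperature": 30.0,
        "morphology": {
            "compartments": [
                {"name": "soma", "shape": "sphere", "diameter": 8.0, "parent": None}
            ],
        },
        "mechanisms": _mech_cfg(),
        "calcium": {"compartments": []},
        "cascade": {},
    }
    return UBCModel.from_dict(cfg)


def canonical_passive() -> UBCModel:
    """Canonical 13-compartment geometry with every active conductance off."""
    model = ubcsim.load_canonical()
    cfg = model.to_dict()
    cfg["mechanisms"] = _mech_cfg()
    return UBCModel.from_dict(cfg)


class TestPassiveOracle:
    def test_rc_charging_matches_closed_form(self):
        """Current step on the single-compartment leak cell against the
        analytic V(t) = E + IR(1 - exp(-t/tau)); < 0.1% of the step."""
        model = soma_only_passive()
        tr = analysis.step_response(model, 5.0, duration=300.0, holding=-70.0,
                                    pre_time=20.0, post_time=0.0, dt=0.01)
        soma = model.morphology["soma"]
        r_gohm = 1.0 / (LEAK_G * soma.effective_area_um2 * 1e-8) * 1e-9
        tau = r_gohm * soma.capacitance_pF  # GOhm * pF = ms
        sel = tr.time >= 20.0
        t_rel = tr.time[sel] - 20.0
        expected = -70.0 + 0.005 * r_gohm * 1e3 * (1.0 - np.exp(-t_rel / tau))
        err = np.max(np.abs(tr.soma_v[sel] - expected))
        assert err < 1e-3 * 0.005 * r_gohm * 1e3  # < 0.1% of the step amplitude

    def test_passive_dt_convergence(self):
        model = soma_only_passive()
        proto = ProtocolSpec(holding=-70.0, pre_time=20.0, steps=((5.0, 200.0),))
        rep = convergence_check(model, proto, [0.025, 0.0125])
        assert rep["max_dv"].iloc[0] < 0.01  # mV

    def test_convergence_needs_two_dts(self):
        with pytest.raises(ValueError):
            convergence_check(soma_only_passive(), ProtocolSpec(), [0.025])

    def test_vc_transient_recovers_series_resistance(self):
        """The initial clamp current of the passive canonical cell
        recovers the 20 Mohm pipette within 10% (finely resolved:
        I(0+) = dV / R_s), and the fitted transient recovers the full
        membrane capacitance."""
        model = canonical_passive()
        tr = analysis.passive_transient(model, dt=0.001, duration=100.0)
        onset = 50.0
        pre = (tr.time >= 30.0) & (tr.time < onset)
        i_base = tr.stim[pre].mean()
        k = np.searchsorted(tr.time, onset + 0.001)
        r_s_peak = abs(-10.0 / (tr.stim[k] - i_base))  # mV/nA = MOhm
        assert r_s_peak == pytest.approx(20.0, rel=0.10)
        fit = analysis.fit_triexponential(tr, onset, 100.0, -10.0)
        assert fit.c_in == pytest.approx(16.7, rel=0.05)

    def test_two_compartment_circuit_oracle(self):
        """Analytic pipette-plus-cell transient (R = 1 GOhm, C = 16 pF,
        R_s = 20 MOhm): the fit recovers all three within 5%."""
        r, c, rs = 1.0, 16.0, 0.02  # GOhm, pF, GOhm
        tau = c * rs * r / (rs + r)  # ms
        dv = -10.0
        t = np.arange(0.0, 300.0, 0.005)
        onset = 50.0
        i_ss = dv / (r + rs) * 1e-3  # nA
        i = np.where(t >= onset,
                     (dv / rs * 1e-3 - i_ss) * np.exp(-(t - onset) / tau) + i_ss,
                     0.0)
        fit = analysis.fit_triexponential((t, i), onset, 250.0, dv, drift=False)
        c_est = fit.c_in
        r_est = abs(dv / fit.offset) * 1e-3 - rs
        assert c_est * (r + rs) ** 2 / r**2 == pytest.approx(c, rel=0.05)
        assert r_est == pytest.approx(r, rel=0.05)
        assert fit.r_s == pytest.approx(rs * 1e3, rel=0.10)


class TestSteadyState:
    def test_holding_is_self_consistent(self, canonical):
        """Released from the computed init with the holding bias applied,
        the soma stays within 0.5 mV of the target for 1 s."""
        tr = run(canonical, ProtocolSpec(holding=-80.0, pre_time=1000.0))
        assert np.max(np.abs(tr.soma_v - (-80.0))) < 0.5

    def test_resting_potential_without_injection(self, canonical):
        """With no bias the model settles near the reported resting
        potential (experimental range -66.7 +/- 1.8 mV)."""
        arr = build_arrays(canonical)
        from ubcsim.engine import _fresh_state

        st = _fresh_state(arr, -70.0)
        n = int(6000.0 / 0.025)
        z = np.zeros(n)
        _run_kernel(arr, st, n, 0.025, z, 0, z, z, n)
        assert -72.0 < st.v[arr.soma] < -63.0

    def test_kirchhoff_consistency_at_steady_state(self, canonical):
        """After a deep relaxation every nodal current balance closes to
        < 1e-6 nA."""
        arr = build_arrays(canonical)
        state, bias = init_steady_state(arr, -80.0, use_cache=True)
        n = int(8000.0 / 0.025)
        z = np.zeros(n)
        inj = np.full(n, bias)
        _run_kernel(arr, state, n, 0.025, z, 0, inj, z, n)
        res = kirchhoff_residuals(arr, state, bias)
        assert np.max(np.abs(res)) < 1e-6

    def test_holding_outside_range_rejected(self, canonical):
        with pytest.raises(ValueError):
            init_steady_state(canonical, -20.0)

    def test_passive_rest_needs_no_bias(self):
        model = soma_only_passive()
        _, bias = init_steady_state(model, -70.0, use_cache=False)
        assert abs(bias) < 1e-9  # nA; holding at the leak reversal


class TestDeterminism:
    def test_identical_runs_bit_identical(self, canonical):
        proto = ProtocolSpec(holding=-80.0, pre_time=50.0, steps=((16.0, 100.0),))
        t1 = run(canonical, proto)
        t2 = run(canonical, proto)
        assert np.array_equal(t1.v, t2.v)
        assert np.array_equal(t1.ca, t2.ca)
        assert np.array_equal(t1.currents, t2.currents)
        assert t1.meta["config_hash"] == t2.meta["config_hash"]


class TestChannelBlock:
    def test_empty_block_is_identity(self, canonical):
        proto = ProtocolSpec(holding=-80.0, pre_time=50.0, steps=((8.0, 80.0),))
        t1 = run(canonical, proto)
        t2 = run(apply_channel_block(canonical, set()), proto)
        assert np.array_equal(t1.v, t2.v)

    def test_unknown_mechanism_rejected(self, canonical):
        with pytest.raises(KeyError):
            apply_channel_block(canonical, {"kv", "not_a_channel"})

    def test_blocked_mechanism_carries_no_current(self, canonical):
        proto = ProtocolSpec(holding=-80.0, pre_time=50.0, steps=((16.0, 100.0),))
        tr = run(apply_channel_block(canonical, {"h"}), proto)
        assert np.all(tr.current("h") == 0.0)

    def test_original_model_untouched(self, canonical):
        g0 = canonical.mechanisms["h"].gmax
        apply_channel_block(canonical, {"h"})
        assert canonical.mechanisms["h"].gmax == g0


class TestPipette:
    def test_pipette_irrelevant_in_current_clamp(self, canonical):
        """Removing the pipette leaves current-clamp behavior unchanged —
        it only enters the voltage-clamp circuit."""
        proto = ProtocolSpec(holding=-80.0, pre_time=50.0, steps=((16.0, 100.0),))
        t1 = run(canonical, proto)
        stripped = canonical.copy()
        stripped.morphology.pipette = None
        t2 = run(stripped, proto)
        assert np.allclose(t1.v, t2.v, atol=1e-12)


class TestProtocolValidation:
    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(mode="space_clamp")

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(dt=0.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(steps=((10.0, 0.0),))
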