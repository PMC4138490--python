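"""Shared fixtures.

Expensive full-model simulations (canonical step, sag, LOR and the
pharmacological blocks) are session-scoped so the acceptance tests and
the window/property tests share single runs.
"""

import numpy as np
import pytest

import ubcsim
from ubcsim import analysis


@pytest.fixture(scope="session")
def canonical():
    return ubcsim.load_canonical()


@pytest.fixture(scope="session")
def step16(canonical):
    """+16 pA, 800 ms from -80 mV."""
    return analysis.step_response(canonical, 16.0)


@pytest.fixture(scope="session")
def step16_metrics(step16):
    return analysis.step_metrics(step16)


@pytest.fixture(scope="session")
def sag20(canonical):
    """-20 pA, 800 ms from -80 mV."""
    return analysis.step_response(canonical, -20.0)


@pytest.fixture(scope="session")
def passive_fit(canonical):
    tr = analysis.passive_transient(canonical)
    return analysis.fit_triexponential(
        tr, step_onset=50.0, step_duration=250.0, delta_v=-10.0,
        access_resistance=20.0,
    )


def _lor_with_metrics(model, bias=None, **kwargs):
    tr = analysis.lor_response(model, bias_nA=bias, **kwargs)
    onset = tr.meta["stim_onset"]
    train_end = tr.meta["pulse_times"][-1] + 10.0 if tr.meta["pulse_times"] else onset
    return tr, analysis.lor_metrics(tr, onset, train_end)


@pytest.fixture(scope="session")
def lor_canonical(canonical):
    """10-pulse 100 Hz train on the intact model."""
    return _lor_with_metrics(canonical)


@pytest.fixture(scope="session")
def control_bias(lor_canonical):
    """Holding current of the intact model at -80 mV; the in-silico
    pharmacology keeps it fixed (as when a blocker is washed in without
    re-adjusting the amplifier)."""
    return lor_canonical[0].meta["holding_current_nA"]


@pytest.fixture(scope="session")
def lor_trp_blocked(canonical, control_bias):
    return _lor_with_metrics(canonical.with_block({"trp"}), bias=control_bias)


@pytest.fixture(scope="session")
def lor_h_blocked(canonical, control_bias):
    return _lor_with_metrics(canonical.with_block({"h"}), bias=control_bias)


@pytest.fixture(scope="session")
def lor_ca_blocked(canonical, control_bias):
    return _lor_with_metrics(canonical.with_block({"cahva", "calva"}), bias=control_bias)


@pytest.fixture(scope="session")
def lor_h_trp_blocked(canonical, control_bias):
    return _lor_with_metrics(canonical.with_block({"h", "trp"}), bias=control_bias)
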