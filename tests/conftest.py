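"""Shared fixtures: the packaged model and one trace per scenario.

Scenario traces are session-scoped because a full 300 pt run takes about a
second; every test that inspects scenario dynamics reuses the same trace.
"""

from __future__ import annotations

import pytest

import terpnet as tn

SEED = 0


@pytest.fixture(scope="session")
def params():
    return tn.default_parameters(SEED)


@pytest.fixture(scope="session")
def full_model(params):
    return tn.build_model(params)


@pytest.fixture(scope="session")
def trace_s1(params):
    return tn.run_scenario(1, params)


@pytest.fixture(scope="session")
def trace_s2(params):
    return tn.run_scenario(2, params)


@pytest.fixture(scope="session")
def trace_s3(params):
    return tn.run_scenario(3, params)


@pytest.fixture(scope="session")
def trace_s4(params):
    return tn.run_scenario(4, params)


@pytest.fixture(scope="session")
def trace_s5(params):
    return tn.run_scenario(5, params)


@pytest.fixture(scope="session")
def trace_s5_control(params):
    """Scenario 5 with the crossSwitch script suppressed (no crosstalk)."""
    return tn.run_scenario(5, params, cross_script=False)
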