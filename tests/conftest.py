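"""Shared fixtures: the expensive closed-loop reference runs are computed
once per session and reused across metric, property and acceptance tests."""

from __future__ import annotations

import pytest

from ecco2rsim.config import SimSetup
from ecco2rsim.protocol import reference_scenarios, run


@pytest.fixture(scope="session")
def setup() -> SimSetup:
    return SimSetup()


@pytest.fixture(scope="session")
def scenarios():
    return reference_scenarios(seed=1)


@pytest.fixture(scope="session")
def target20_run(scenarios):
    """Reference water run: 1.0 L/min, target 20 mmHg, feedback on."""
    return run(scenarios["target_20"])


@pytest.fixture(scope="session")
def fixed_runs(scenarios):
    """Fixed-sweep control arms at 1.0 and 2.0 L/min."""
    return {name: run(scenarios[name]) for name in ("fixed_1.0", "fixed_2.0")}
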