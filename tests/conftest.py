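"""Shared fixtures: expensive 50-year trajectories are run once per session."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import glymphsim as g

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def e3_params() -> g.ModelParams:
    return g.default_params("E3")


@pytest.fixture(scope="session")
def registry() -> dict[str, g.Scenario]:
    return g.builtin_scenarios()


@pytest.fixture(scope="session")
def scenario_trajs(registry) -> dict[str, g.Trajectory]:
    """Full 50-year runs of all nine built-in scenarios."""
    return {name: g.run_simulation(scen) for name, scen in registry.items()}


@pytest.fixture(scope="session")
def baseline(scenario_trajs) -> g.Trajectory:
    return scenario_trajs["normal_aging"]


@pytest.fixture(scope="session")
def report(scenario_trajs, baseline) -> g.RatioReport:
    return g.normalized_report(list(scenario_trajs.values()), baseline)
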