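"""The nine built-in simulation arms, the normalized endpoint report, and
the one-at-a-time sensitivity sweeps.

Every scenario shares the calibrated baseline parameters and differs only
in heart rate, vessel-stiffening profile, ApoE allele, or the
stimulated-generation multiplier k4.  Endpoints (the four deposit pools
at 50 years) are reported normalized to the normal-aging baseline.

The vessel-stiffening arms use the ``flow_off`` compliance law by
default: they represent a glymphatic drive that is functionally abolished
for the whole run, which is the regime in which parenchymal deposition
explodes while vessel-wall deposition collapses.  The ``inverse`` law
(velocity halved at a two-fold stiffness) remains selectable for milder
stiffening.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import Trajectory, run_simulation
from .errors import InvariantError, ParameterError
from .params import ModelParams, default_params
from .physiology import Physiology, StiffnessProfile


@dataclass(frozen=True)
class Scenario:
    """One named simulation arm: physiology plus parameter overrides."""

    name: str
    heart_rate: float = 60.0
    stiffness: StiffnessProfile | None = None
    apoe: str = "E3"
    k4_override: float | None = None
    notes: str = ""

    def build_params(self, base: ModelParams | None = None) -> ModelParams:
        p = default_params(self.apoe) if base is None else base
        if base is not None and self.apoe.upper().removeprefix("APOE") == "E4":
            p = p.with_overrides(k6=0.12)
        if self.k4_override is not None:
            p = p.with_overrides(k4=self.k4_override)
        return p

    def build_physiology(self) -> Physiology:
        return Physiology(heart_rate=self.heart_rate,
                          stiffness=self.stiffness, apoe=self.apoe)


_STIFF = StiffnessProfile(fold_change=2.0, duration=18250.0,
                          compliance_law="flow_off")

BASELINE_NAME = "normal_aging"


def builtin_scenarios() -> dict[str, Scenario]:
    """Registry of the nine study arms, keyed by name."""
    scenarios = [
        Scenario("normal_aging", notes="healthy aging baseline, HR 60, ApoE3"),
        Scenario("bradycardia", heart_rate=50.0,
                 notes="slow heart rate weakens glymphatic drive"),
        Scenario("elevated_hr", heart_rate=90.0,
                 notes="exercise-like heart rate strengthens glymphatic drive"),
        Scenario("stiffness_2x", stiffness=_STIFF,
                 notes="two-fold exponential vessel stiffening, flow_off law"),
        Scenario("apoe4", apoe="E4",
                 notes="slowed LRP-1 transport (k6 0.4 -> 0.12/day)"),
        Scenario("apoe4_bradycardia", heart_rate=50.0, apoe="E4"),
        Scenario("apoe4_stiffness", stiffness=_STIFF, apoe="E4"),
        Scenario("bradycardia_stiffness", heart_rate=50.0, stiffness=_STIFF),
        Scenario("generation_2x", k4_override=2.0,
                 notes="stimulated-generation multiplier raised 1.5 -> 2.0"),
    ]
    return {s.name: s for s in scenarios}


# ---------------------------------------------------------------------------
# Normalized endpoint report
# ---------------------------------------------------------------------------

#: endpoint column -> (compartment, species) labels
_ENDPOINTS = {
    "C9": ("parenchyma", "Ab40"),
    "C10": ("parenchyma", "Ab42"),
    "C3": ("vessel", "Ab40"),
    "C6": ("vessel", "Ab42"),
}


@dataclass(frozen=True)
class RatioReport:
    """Endpoint deposits per scenario, normalized to the aging baseline."""

    table: pd.DataFrame  # scenario, compartment, species, endpoint_molecules,
                         # ratio_to_baseline, percent_of_baseline

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")

    def ratio(self, scenario: str, compartment: str, species: str) -> float:
        t = self.table
        row = t[(t.scenario == scenario) & (t.compartment == compartment)
                & (t.species == species)]
        if len(row) != 1:
            raise ParameterError(
                f"no unique report row for {scenario}/{compartment}/{species}")
        return float(row.ratio_to_baseline.iloc[0])

    def __str__(self) -> str:
        wide = self.table.pivot_table(
            index="scenario", columns=["compartment", "species"],
            values="ratio_to_baseline", sort=False)
        return wide.to_string(float_format=lambda x: f"{x:.4g}")


def normalized_report(trajectories: list[Trajectory],
                      baseline: Trajectory) -> RatioReport:
    """Build the endpoint table: final deposits of every arm divided by the
    normal-aging baseline (baseline ratios are exactly 1).

    A zero baseline endpoint yields a NaN ratio rather than an exception.
    """
    for traj in trajectories:
        if (len(traj.times) != len(baseline.times)
                or traj.times[-1] != baseline.times[-1]):
            raise ParameterError(
                f"trajectory {traj.scenario_name!r} does not share the "
                "baseline horizon/recording grid")
    rows = []
    for traj in trajectories:
        for col, (compartment, species) in _ENDPOINTS.items():
            value = traj.endpoint(col)
            ref = baseline.endpoint(col)
            ratio = value / ref if ref != 0.0 else float("nan")
            rows.append({
                "scenario": traj.scenario_name,
                "compartment": compartment,
                "species": species,
                "endpoint_molecules": value,
                "ratio_to_baseline": ratio,
                "percent_of_baseline": 100.0 * ratio,
            })
    return RatioReport(pd.DataFrame(rows))


def run_report(years: float = 50.0, dt: float = 1.0,
               base_params: ModelParams | None = None) -> RatioReport:
    """Run all nine built-in scenarios and return the normalized report."""
    registry = builtin_scenarios()
    trajs = {}
    for name, scen in registry.items():
        params = scen.build_params(base_params)
        trajs[name] = run_simulation(scen, years=years, dt=dt, params=params)
    baseline = trajs[BASELINE_NAME]
    return normalized_report(list(trajs.values()), baseline)


# ---------------------------------------------------------------------------
# Sensitivity sweeps
# ---------------------------------------------------------------------------

SWEEPABLE = ("pvs_init_fraction_scale", "k4")


def sensitivity_sweep(param_name: str, values: list[float],
                      scenario: Scenario | None = None,
                      years: float = 50.0,
                      base_params: ModelParams | None = None) -> pd.DataFrame:
    """One full run per value of a single swept quantity.

    ``pvs_init_fraction_scale`` scales the initial perivascular Aβ pools;
    ``k4`` replaces the stimulated-generation multiplier.  The returned
    table carries the four deposit endpoints plus their relative change
    against the scenario's default setting.
    """
    if param_name not in SWEEPABLE:
        raise ParameterError(
            f"unknown sweep parameter {param_name!r}; expected one of {SWEEPABLE}")
    for v in values:
        if not np.isfinite(v) or v <= 0:
            raise ParameterError(f"sweep values must be finite and > 0, got {v}")
    if scenario is None:
        scenario = builtin_scenarios()[BASELINE_NAME]
    params = scenario.build_params(base_params)

    def run_with(value: float | None) -> Trajectory:
        if value is None:  # scenario default
            return run_simulation(scenario, years=years, params=params)
        if param_name == "pvs_init_fraction_scale":
            return run_simulation(scenario, years=years, params=params,
                                  pvs_init_scale=value)
        return run_simulation(scenario, years=years,
                              params=params.with_overrides(k4=value))

    ref = run_with(None)
    rows = []
    for v in values:
        traj = run_with(v)
        row = {"param": param_name, "value": v}
        for col in _ENDPOINTS:
            row[col] = traj.endpoint(col)
            ref_val = ref.endpoint(col)
            row[f"rel_change_{col}"] = (
                (traj.endpoint(col) - ref_val) / ref_val if ref_val else float("nan"))
        rows.append(row)
    columns = (["param", "value"] + list(_ENDPOINTS)
               + [f"rel_change_{c}" for c in _ENDPOINTS])
    return pd.DataFrame(rows, columns=columns)
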