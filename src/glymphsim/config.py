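"""Run-configuration files (TOML) with fail-closed validation.

Silent typos in rate-constant names would corrupt the science, so every
unknown key — at the top level, in the ``[scenario]`` table, in
``[scenario.stiffness]`` and in ``[params]`` — is an error naming the
offending key, never a warning.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import ConfigError
from .params import ModelParams
from .physiology import StiffnessProfile
from .scenarios import Scenario, builtin_scenarios

_TOP_KEYS = {"scenario", "years", "dt", "record_stride", "output_dir",
             "formats", "params"}
_SCENARIO_KEYS = {"name", "heart_rate", "apoe", "k4_override", "stiffness",
                  "notes"}
_STIFFNESS_KEYS = {"fold_change", "duration_days", "compliance_law"}
_FORMATS = {"csv", "json"}


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one simulation run."""

    scenario: Scenario
    years: float = 50.0
    dt: float = 1.0
    record_stride: float = 1.0
    output_dir: Path = Path(".")
    formats: tuple[str, ...] = ("csv", "json")
    param_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.years <= 0:
            raise ConfigError("years must be > 0")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.record_stride < self.dt:
            raise ConfigError("record_stride must be >= dt")
        bad = set(self.formats) - _FORMATS
        if bad:
            raise ConfigError(f"unknown output format(s): {sorted(bad)}")

    def build_params(self) -> ModelParams:
        params = self.scenario.build_params()
        if self.param_overrides:
            params = params.with_overrides(**self.param_overrides)
        return params


def _check_keys(table: dict, allowed: set[str], where: str) -> None:
    unknown = set(table) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {where}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")


def _scenario_from_table(table: dict) -> Scenario:
    _check_keys(table, _SCENARIO_KEYS, "[scenario]")
    kwargs = dict(table)
    stiff_table = kwargs.pop("stiffness", None)
    stiffness = None
    if stiff_table is not None:
        _check_keys(stiff_table, _STIFFNESS_KEYS, "[scenario.stiffness]")
        stiffness = StiffnessProfile(
            fold_change=float(stiff_table.get("fold_change", 2.0)),
            duration=float(stiff_table.get("duration_days", 18250.0)),
            compliance_law=stiff_table.get("compliance_law", "inverse"),
        )
    if "name" not in kwargs:
        raise ConfigError("[scenario] table requires a 'name' key")
    return Scenario(stiffness=stiffness, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    ``scenario`` may be the name of a built-in arm or an inline
    ``[scenario]`` table; absent optional keys take their defaults.
    """
    path = Path(path)
    try:
        data = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    _check_keys(data, _TOP_KEYS, str(path))

    if "scenario" not in data:
        raise ConfigError("config requires a 'scenario' key")
    raw = data["scenario"]
    if isinstance(raw, str):
        registry = builtin_scenarios()
        if raw not in registry:
            raise ConfigError(
                f"unknown scenario {raw!r}; valid names: {sorted(registry)}")
        scenario = registry[raw]
    elif isinstance(raw, dict):
        scenario = _scenario_from_table(raw)
    else:
        raise ConfigError("'scenario' must be a name or a table")

    overrides = data.get("params", {})
    if not isinstance(overrides, dict):
        raise ConfigError("[params] must be a table of ModelParams fields")
    known = {f.name for f in fields(ModelParams)}
    _check_keys(overrides, known, "[params]")

    formats = data.get("formats", ["csv", "json"])
    return RunConfig(
        scenario=scenario,
        years=float(data.get("years", 50.0)),
        dt=float(data.get("dt", 1.0)),
        record_stride=float(data.get("record_stride", data.get("dt", 1.0))),
        output_dir=Path(data.get("output_dir", ".")),
        formats=tuple(formats),
        param_overrides={k: float(v) for k, v in overrides.items()},
    )
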