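"""Run configuration, serialization and test-fixture generation.

The run configuration is a single YAML document with a versioned
schema.  Every block mirrors one of the package's parameter
dataclasses; unknown keys are rejected with the offending field named,
and ``dump_config`` materializes all defaults explicitly so that
``load(dump(cfg)) == cfg`` holds losslessly.  Simulation output goes
to a tidy long-format CSV (day, variable, group, value) plus a JSON
budget summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .forcing import LightForcing
from .foodweb import TrophicGroupSpec, baltic_default_specs
from .metrics import ClassificationRule
from .scenarios import Scenario, make_scenario
from .simulate import SimulationConfig, SimulationResult

__all__ = [
    "ConfigError",
    "GridSpec",
    "RunConfig",
    "load_config",
    "dump_config",
    "write_result",
    "fixture_quota_series",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclass(frozen=True)
class GridSpec:
    """Resolution of the 3-factor scenario cube."""

    n_fish: int = 5
    n_nutrient: int = 7
    n_kbg: int = 6
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_fish", "n_nutrient", "n_kbg"):
            if getattr(self, name) < 1:
                raise ConfigError(f"grid.{name} must be >= 1")


#: desk-scale grid preset used for scaled-down regime runs
SCALED_GRID = GridSpec(n_fish=3, n_nutrient=5, n_kbg=5)


@dataclass
class RunConfig:
    """Complete, explicit description of a run."""

    forcing: LightForcing = field(default_factory=LightForcing)
    groups: dict = field(default_factory=baltic_default_specs)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scenario: Scenario | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    rule: ClassificationRule = field(default_factory=ClassificationRule)
    outdir: str = "out"
    log_level: str = "INFO"


def _build(cls, data: dict, block: str):
    """Instantiate a parameter dataclass, naming any unknown key."""
    if not isinstance(data, dict):
        raise ConfigError(f"{block}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{block}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{block}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"schema_version: unsupported version {version}")
    known = {"forcing", "groups", "simulation", "scenario", "grid", "rule",
             "outdir", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"top level: unknown key(s) {sorted(unknown)}")

    cfg = RunConfig()
    if "forcing" in raw:
        cfg.forcing = _build(LightForcing, raw["forcing"], "forcing")
    if "simulation" in raw:
        cfg.simulation = _build(SimulationConfig, raw["simulation"], "simulation")
    if "rule" in raw:
        cfg.rule = _build(ClassificationRule, raw["rule"], "rule")
    if "grid" in raw:
        cfg.grid = _build(GridSpec, raw["grid"], "grid")
    if "scenario" in raw and raw["scenario"] is not None:
        sdata = dict(raw["scenario"])
        if "PO4_0" in sdata:
            cfg.scenario = _build(Scenario, sdata, "scenario")
        else:
            known_s = {f.name for f in fields(Scenario)} - {"PO4_0"}
            unknown = set(sdata) - known_s
            if unknown:
                raise ConfigError(f"scenario: unknown key(s) {sorted(unknown)}")
            try:
                cfg.scenario = make_scenario(**sdata)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"scenario: {exc}") from exc
    if "groups" in raw:
        specs = baltic_default_specs()
        if not isinstance(raw["groups"], dict):
            raise ConfigError("groups: expected a mapping of group name to fields")
        for name, over in raw["groups"].items():
            if name not in specs:
                raise ConfigError(f"groups: unknown group {name!r}")
            base = dataclasses.asdict(specs[name])
            if not isinstance(over, dict):
                raise ConfigError(f"groups.{name}: expected a mapping")
            unknown = set(over) - set(base)
            if unknown:
                raise ConfigError(f"groups.{name}: unknown key(s) {sorted(unknown)}")
            base.update(over)
            try:
                specs[name] = TrophicGroupSpec(**base)
            except ValueError as exc:
                raise ConfigError(f"groups.{name}: {exc}") from exc
        cfg.groups = specs
    if "outdir" in raw:
        cfg.outdir = str(raw["outdir"])
    if "log_level" in raw:
        cfg.log_level = str(raw["log_level"])
    return cfg


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def dump_config(config: RunConfig, path) -> None:
    """Write a configuration with every default materialized explicitly."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "forcing": _plain(config.forcing),
        "groups": {name: _plain(spec) for name, spec in config.groups.items()},
        "simulation": _plain(config.simulation),
        "scenario": _plain(config.scenario) if config.scenario else None,
        "grid": _plain(config.grid),
        "rule": _plain(config.rule),
        "outdir": config.outdir,
        "log_level": config.log_level,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_result(result: SimulationResult, csv_path, json_path=None) -> None:
    """Write a run as a tidy CSV plus a JSON budget/scenario summary."""
    result.to_frame().to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {
            "scenario": _plain(result.scenario),
            "config": _plain(result.config),
            "ledger": _plain(result.ledger),
        }
        Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True))


def fixture_quota_series(n_days: int, fraction_below: float,
                         threshold: float) -> np.ndarray:
    """Deterministic daily fish-quota series for classifier testing.

    Exactly ``round(fraction_below * n_days)`` leading days sit at half
    the threshold; the remaining days sit at 1.5x the threshold.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 0.0 <= fraction_below <= 1.0:
        raise ValueError("fraction_below must be in [0, 1]")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n_below = round(fraction_below * n_days)
    series = np.full(n_days, 1.5 * threshold)
    series[:n_below] = 0.5 * threshold
    return series
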