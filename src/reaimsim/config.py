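"""Run configuration: YAML loading with strict validation.

A config file is a flat YAML mapping of model parameters plus an optional
``cost`` block and sweep settings, e.g.::

    total_population: 5000
    exposure_rate: 150
    p_initial_reach: 0.5
    p_disengage: 0.2
    scenario: both
    grid_resolution: 21
    cost:
      initial_reach: {base_cost: 1.0, steepness: 3.0}

Every key is optional; omitted keys fall back to the model defaults
(N=5000, E=150/yr, 50-year horizon, 12 steps/yr, all proportions 0, unit
cost curves with steepness 3).  Unknown keys and out-of-range values are
rejected with an error naming the offending key.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .costs import ActivityCost, CostParameters
from .model import Parameters, make_default_parameters
from .scenarios import SCENARIO_NAMES

__all__ = ["RunConfig", "load_config", "ConfigError"]

_PARAM_KEYS = (
    "total_population",
    "exposure_rate",
    "p_initial_reach",
    "p_disengage",
    "p_delayed_reach",
    "p_reengage",
    "steps_per_year",
    "horizon_years",
)
_RUN_KEYS = ("scenario", "grid_resolution", "output_dir", "formats")
_ACTIVITY_KEYS = ("initial_reach", "delayed_reach", "maintenance", "reengagement")
_FORMATS = ("csv", "json", "png")


class ConfigError(ValueError):
    """Invalid or unparsable run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a run or sweep."""

    params: Parameters = field(default_factory=make_default_parameters)
    costs: CostParameters = field(default_factory=CostParameters)
    scenario: str = "all"
    grid_resolution: int = 21
    output_dir: Path = Path(".")
    formats: tuple[str, ...] = ("csv",)


def _build_costs(raw: dict) -> CostParameters:
    kwargs = {}
    for key, value in raw.items():
        if key not in _ACTIVITY_KEYS:
            raise ConfigError(
                f"unknown cost activity '{key}' (expected one of {list(_ACTIVITY_KEYS)})"
            )
        if not isinstance(value, dict):
            raise ConfigError(f"cost.{key} must be a mapping of base_cost/steepness")
        extra = set(value) - {"base_cost", "steepness"}
        if extra:
            raise ConfigError(f"unknown key 'cost.{key}.{extra.pop()}'")
        try:
            kwargs[key] = ActivityCost(**value)
        except ValueError as exc:
            raise ConfigError(f"cost.{key}: {exc}") from exc
    return CostParameters(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file.

    An empty file yields the full defaults.  Raises :class:`ConfigError`
    (with the offending key named) on unknown keys, parse errors, or values
    outside their valid ranges, and :class:`FileNotFoundError` for a missing
    file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(raw).__name__}")

    known = set(_PARAM_KEYS) | set(_RUN_KEYS) | {"cost"}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config key '{key}'")

    param_overrides = {k: raw[k] for k in _PARAM_KEYS if k in raw}
    try:
        params = replace(make_default_parameters(), **param_overrides)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    costs = _build_costs(raw.get("cost", {}))

    scenario = raw.get("scenario", "all")
    if scenario != "all" and scenario not in SCENARIO_NAMES:
        raise ConfigError(
            f"scenario: unknown scenario '{scenario}' "
            f"(valid: {', '.join(SCENARIO_NAMES)} or 'all')"
        )

    grid_resolution = raw.get("grid_resolution", 21)
    if not isinstance(grid_resolution, int) or grid_resolution < 2:
        raise ConfigError(
            f"grid_resolution must be an integer >= 2, got {grid_resolution}"
        )

    formats = raw.get("formats", ["csv"])
    if isinstance(formats, str):
        formats = [formats]
    for fmt in formats:
        if fmt not in _FORMATS:
            raise ConfigError(f"formats: unknown format '{fmt}' (valid: {_FORMATS})")

    return RunConfig(
        params=params,
        costs=costs,
        scenario=scenario,
        grid_resolution=grid_resolution,
        output_dir=Path(raw.get("output_dir", ".")),
        formats=tuple(formats),
    )
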