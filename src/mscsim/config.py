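"""Run configuration: TOML loading, validation, lossless round-trip.

A config file has up to five tables — ``[differentiation]``, ``[mechanics]``,
``[environment]``, ``[protocol]``, ``[run]`` — whose keys mirror the
parameter dataclasses.  Missing keys fall back to the validated defaults
(the experimentally calibrated parameter set); unknown keys are rejected
with an error naming the key.  An empty file is a valid config equal to the
defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

from .params import (
    DifferentiationParams,
    MechanicsParams,
    OxygenEnvironment,
    params_asdict,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "UnknownKeyError",
    "InvalidValueError",
    "load_config",
    "loads_config",
    "dump_config",
]


class ConfigError(Exception):
    """Base class for configuration problems."""


class UnknownKeyError(ConfigError):
    """A key or table not part of the schema."""


class InvalidValueError(ConfigError):
    """A value violating a parameter invariant."""


_RUN_DEFAULTS: Dict[str, Any] = {
    "seed": 0,
    "out_dir": "results",
    "record_every_days": 0.1,
}
_ENV_DEFAULTS: Dict[str, Any] = {"pO2_percent": 20.0}
_PROTOCOL_DEFAULTS: Dict[str, Any] = {
    "name": "",
    "n": 200,
    "duration_days": 5.0,
    "dt_seconds": 120.0,
}


@dataclass
class RunConfig:
    """Fully validated configuration of one simulation run."""

    differentiation: DifferentiationParams = field(default_factory=DifferentiationParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    environment: Dict[str, Any] = field(default_factory=lambda: dict(_ENV_DEFAULTS))
    protocol: Dict[str, Any] = field(default_factory=lambda: dict(_PROTOCOL_DEFAULTS))
    run: Dict[str, Any] = field(default_factory=lambda: dict(_RUN_DEFAULTS))

    @property
    def env(self) -> OxygenEnvironment:
        return OxygenEnvironment.from_percent(
            self.environment["pO2_percent"], self.differentiation
        )

    @property
    def seed(self) -> int:
        return int(self.run["seed"])

    def asdict(self) -> Dict[str, Any]:
        return {
            "differentiation": params_asdict(self.differentiation),
            "mechanics": params_asdict(self.mechanics),
            "environment": dict(self.environment),
            "protocol": dict(self.protocol),
            "run": dict(self.run),
        }


def _merged(defaults: Dict[str, Any], given: Dict[str, Any], table: str) -> Dict[str, Any]:
    out = dict(defaults)
    for key, value in given.items():
        if key not in defaults:
            raise UnknownKeyError(f"unknown key {key!r} in table [{table}]")
        out[key] = value
    return out


def _build_params(cls, given: Dict[str, Any], table: str):
    known = {f.name for f in dataclasses.fields(cls)}
    for key in given:
        if key not in known:
            raise UnknownKeyError(f"unknown key {key!r} in table [{table}]")
    try:
        return cls(**given)
    except (ValueError, TypeError) as err:
        raise InvalidValueError(f"invalid value in table [{table}]: {err}") from err


def loads_config(text: str) -> RunConfig:
    """Parse a TOML string into a validated RunConfig."""
    try:
        raw = tomllib.loads(text)
    except tomllib.TOMLDecodeError as err:
        raise ConfigError(f"config does not parse as TOML: {err}") from err
    known_tables = {"differentiation", "mechanics", "environment", "protocol", "run"}
    for table in raw:
        if table not in known_tables:
            raise UnknownKeyError(f"unknown table [{table}]")
    cfg = RunConfig(
        differentiation=_build_params(
            DifferentiationParams, raw.get("differentiation", {}), "differentiation"),
        mechanics=_build_params(MechanicsParams, raw.get("mechanics", {}), "mechanics"),
        environment=_merged(_ENV_DEFAULTS, raw.get("environment", {}), "environment"),
        protocol=_merged(_PROTOCOL_DEFAULTS, raw.get("protocol", {}), "protocol"),
        run=_merged(_RUN_DEFAULTS, raw.get("run", {}), "run"),
    )
    try:
        cfg.env  # validates pO2_percent
    except ValueError as err:
        raise InvalidValueError(f"invalid value in table [environment]: {err}") from err
    return cfg


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    return loads_config(path.read_text())


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    raise ConfigError(f"cannot serialize value of type {type(v).__name__}")


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig to TOML; loads_config(dump_config(c)) == c."""
    lines = []
    for table, values in cfg.asdict().items():
        lines.append(f"[{table}]")
        for key, value in values.items():
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    return "\n".join(lines)
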