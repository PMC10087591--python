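"""TOML run configuration: validation, defaults, round-trip serialization.

A config file has a ``[simulation]`` section holding the
:class:`~conformity.metapop.SimParams` fields, a ``[sweep]`` section with
the beta/d grids and replicate count, an ``[estimator]`` section with the
regression options, and top-level ``output_dir`` / ``log_level``.  Every
field is validated against its owning module's ranges before any
computation starts, and unknown keys are rejected (typo safety).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError, DomainError
from .metapop import SimParams

__all__ = ["RunConfig", "SweepGrid", "EstimatorOptions", "load_config", "save_config"]

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass(frozen=True)
class SweepGrid:
    betas: tuple = (2.8,)
    ds: tuple = (0.02,)
    replicates: int = 20

    def __post_init__(self) -> None:
        if len(self.betas) == 0 or len(self.ds) == 0:
            raise ConfigError("sweep grids `betas` and `ds` must be non-empty")
        if self.replicates < 1:
            raise ConfigError(f"sweep `replicates` must be >= 1, got {self.replicates}")


@dataclass(frozen=True)
class EstimatorOptions:
    weighting: str = "binomial"
    unanimity: str = "haldane"

    def __post_init__(self) -> None:
        if self.weighting not in ("ols", "binomial"):
            raise ConfigError(f"estimator `weighting` must be ols|binomial, got {self.weighting!r}")
        if self.unanimity not in ("haldane", "drop"):
            raise ConfigError(f"estimator `unanimity` must be haldane|drop, got {self.unanimity!r}")


@dataclass(frozen=True)
class RunConfig:
    simulation: SimParams = field(default_factory=SimParams)
    sweep: SweepGrid = field(default_factory=SweepGrid)
    estimator: EstimatorOptions = field(default_factory=EstimatorOptions)
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.log_level not in _LOG_LEVELS:
            raise ConfigError(f"log_level must be one of {_LOG_LEVELS}, got {self.log_level!r}")


def _build(cls, section: dict, where: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(section) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{where}]: {sorted(unknown)}")
    kwargs = {}
    for key, value in section.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except DomainError as exc:
        raise ConfigError(f"invalid value in [{where}]: {exc}") from exc
    except TypeError as exc:
        raise ConfigError(f"bad [{where}] section: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration, filling defaults for
    every omitted field."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"malformed TOML in {path}: {exc}") from exc
    known_sections = {"simulation", "sweep", "estimator"}
    known_top = known_sections | {"output_dir", "log_level"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    simulation = _build(SimParams, raw.get("simulation", {}), "simulation")
    sweep = _build(SweepGrid, raw.get("sweep", {}), "sweep")
    estimator = _build(EstimatorOptions, raw.get("estimator", {}), "estimator")
    return RunConfig(
        simulation=simulation,
        sweep=sweep,
        estimator=estimator,
        output_dir=raw.get("output_dir", "."),
        log_level=raw.get("log_level", "INFO"),
    )


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (tuple, list)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise ConfigError(f"cannot serialize {value!r} to TOML")


def save_config(config: RunConfig, path) -> None:
    """Serialize a config so that load_config(save_config(c)) == c."""
    lines = [
        f"output_dir = {_toml_value(config.output_dir)}",
        f"log_level = {_toml_value(config.log_level)}",
    ]
    for section_name, obj in (
        ("simulation", config.simulation),
        ("sweep", config.sweep),
        ("estimator", config.estimator),
    ):
        lines.append("")
        lines.append(f"[{section_name}]")
        for f in dataclasses.fields(obj):
            lines.append(f"{f.name} = {_toml_value(getattr(obj, f.name))}")
    Path(path).write_text("\n".join(lines) + "\n")


def config_record(config: RunConfig) -> dict:
    """Flat dict of every effective parameter, for logs and metadata
    emitted alongside outputs (no silent defaults)."""
    return {
        "simulation": dataclasses.asdict(config.simulation),
        "sweep": dataclasses.asdict(config.sweep),
        "estimator": dataclasses.asdict(config.estimator),
        "output_dir": config.output_dir,
        "log_level": config.log_level,
    }
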