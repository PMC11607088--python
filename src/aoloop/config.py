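"""Plain-text (YAML) configuration with validated sections and overrides.

An empty file (or missing sections) yields the full default configuration:
the ultrafast system parameters.  Every key maps onto a field of one of the
dataclass configs; unknown keys raise a ``ConfigError`` naming the key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .aberrations import ScenarioPSDModel, scenario_model
from .control import LoopConfig
from .dm import DMConfig
from .loopsim import TimingConfig
from .optics import OpticalConfig
from .shws import LensletGeometry, SensorConfig

__all__ = ["ConfigError", "FullConfig", "RunConfig", "load_config", "apply_overrides"]

_SECTIONS = {
    "optical": OpticalConfig,
    "sensor": SensorConfig,
    "geometry": LensletGeometry,
    "dm": DMConfig,
    "loop": LoopConfig,
    "timing": TimingConfig,
}


class ConfigError(ValueError):
    pass


@dataclass
class FullConfig:
    optical: OpticalConfig
    sensor: SensorConfig
    geometry: LensletGeometry
    dm: DMConfig
    loop: LoopConfig
    timing: TimingConfig
    scenario: ScenarioPSDModel


@dataclass
class RunConfig:
    """Experiment-run parameters: where, and with what seed."""

    config_path: str | None = None
    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"


def _build_section(cls, data: dict, section: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in field_names:
            raise ConfigError(f"unknown key {section}.{key}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> FullConfig:
    """Load and validate a YAML configuration file.

    ``overrides`` maps dotted keys (``"loop.loop_rate"``) to values applied
    on top of the file contents.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top level of the config file must be a mapping")
    for section in raw:
        if section not in _SECTIONS and section != "scenario":
            raise ConfigError(f"unknown section {section!r}")
    if overrides:
        for dotted, value in overrides.items():
            section, _, key = dotted.partition(".")
            if not key:
                raise ConfigError(f"override {dotted!r} must be section.key")
            raw.setdefault(section, {})[key] = value

    parts = {name: _build_section(cls, raw.get(name, {}) or {}, name)
             for name, cls in _SECTIONS.items()}
    scen_raw = dict(raw.get("scenario", {}) or {})
    tag = scen_raw.pop("scenario_tag", "normal")
    try:
        scenario = scenario_model(tag, **scen_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid scenario section: {exc}") from exc
    return FullConfig(scenario=scenario, **parts)


def apply_overrides(pairs) -> dict:
    """Parse ``section.key=value`` strings into an override mapping."""
    out = {}
    for pair in pairs:
        if "=" not in pair:
            raise ConfigError(f"override {pair!r} must look like section.key=value")
        dotted, _, value = pair.partition("=")
        out[dotted.strip()] = yaml.safe_load(value)
    return out
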