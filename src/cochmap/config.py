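"""JSON configuration loading for the analysis and the cohort generator.

A config file is a JSON object with optional sections ``geometry``,
``greenwood``, ``array``, ``family`` and ``generator``; each section
holds field overrides for the corresponding dataclass.  Unknown sections
or fields raise immediately so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import json
from dataclasses import fields
from pathlib import Path

from .electrode_map import ElectrodeArray
from .geometry import GeometryConfig
from .stats import TestFamily
from .synthetic_cohort import GeneratorConfig
from .tonotopy import GreenwoodParams

__all__ = ["RunConfig", "load_config"]

_SECTIONS = {
    "geometry": GeometryConfig,
    "greenwood": GreenwoodParams,
    "array": ElectrodeArray,
    "family": TestFamily,
    "generator": GeneratorConfig,
}


class RunConfig:
    """Bundle of all configurable objects for one run."""

    def __init__(self, geometry=None, greenwood=None, array=None, family=None, generator=None):
        self.geometry = geometry or GeometryConfig()
        self.greenwood = greenwood or GreenwoodParams()
        self.array = array or ElectrodeArray()
        self.family = family or TestFamily()
        self.generator = generator or GeneratorConfig()


def _build(cls, overrides: dict, source: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown field(s) {sorted(unknown)} in section {source!r}")
    coerced = {}
    for key, value in overrides.items():
        if isinstance(value, list):
            value = tuple(value)
        if isinstance(value, dict):
            # keyed tables (e.g. the generator's per-cell effect sizes):
            # partial overrides merge into the defaults
            parsed = {_parse_key(k): v for k, v in value.items()}
            default = getattr(cls(), key, None)
            value = {**default, **parsed} if isinstance(default, dict) else parsed
        coerced[key] = value
    return cls(**coerced)


def _parse_key(k: str):
    return tuple(k.split("/")) if "/" in k else k


def load_config(path) -> RunConfig:
    """Load a JSON config file into a :class:`RunConfig`."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a JSON object")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s) {sorted(unknown)} in {path}")
    built = {name: _build(cls, raw[name], name) for name, cls in _SECTIONS.items() if name in raw}
    return RunConfig(**built)
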