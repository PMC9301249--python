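"""YAML configuration loading with light schema validation.

The config file has two optional top-level blocks, ``world`` and ``run``,
whose keys map onto :class:`~sedpower.synthetic_world.WorldConfig` and
:class:`~sedpower.aggregation.RunConfig` fields.  Unknown keys are
rejected so typos fail loudly.  Nested per-domain blocks and curve/redox
parameter blocks are supported by field name.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .aggregation import RunConfig
from .grid_model import Domain
from .sediment_column import MeshConfig
from .synthetic_world import (
    DomainParams,
    OpdParams,
    SedRateCurve,
    SmtParams,
    WorldConfig,
)

__all__ = ["load_config", "load_world_config", "load_run_config"]


def _apply(obj, data: dict, path: str) -> None:
    valid = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown config key {path}.{key}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply(current, value, f"{path}.{key}")
        elif key == "domains" and isinstance(value, dict):
            for dom_name, dom_block in value.items():
                dom = Domain(dom_name)
                _apply(current[dom], dom_block, f"{path}.domains.{dom_name}")
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            setattr(obj, key, tuple(value))
        else:
            setattr(obj, key, value)


def load_world_config(data: dict | None) -> WorldConfig:
    cfg = WorldConfig()
    if data:
        _apply(cfg, data, "world")
    cfg.validate()
    return cfg


def load_run_config(data: dict | None) -> RunConfig:
    cfg = RunConfig()
    if data:
        _apply(cfg, data, "run")
    cfg.validate()
    return cfg


def load_config(path: str | Path | None) -> tuple[WorldConfig, RunConfig]:
    """Load ``(WorldConfig, RunConfig)`` from a YAML file (or defaults)."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {"world", "run"}
        if unknown:
            raise ValueError(f"unknown top-level config blocks: {sorted(unknown)}")
    return load_world_config(data.get("world")), load_run_config(data.get("run"))
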