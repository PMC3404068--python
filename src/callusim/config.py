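"""YAML configuration loading, validation and round-tripping.

The configuration file mirrors :class:`~callusim.orchestrator.SimulationConfig`
as nested sections (``geometry``, ``load``, ``transport``, ``cells``,
``rules``, ``prendergast``, ``materials``) plus top-level scalars.  Values
are given in the units the model tables print (mm, N, s, percent strain,
m^2/s for the oxygen diffusivity, fmol/cell/hr, mmHg); unit conversions
happen inside the parameter classes.  Every omitted key falls back to the
model defaults and the applied default is logged, so a run log always
records the full parameter set actually used.  Unknown keys are an error,
reported with their key path.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Any, Dict

import numpy as np
import yaml

from .cells import CellParams
from .differentiation import PrendergastParams, RuleParams
from .fem import LoadCase
from .geometry import GeometrySpec
from .materials import MaterialTable, Phenotype
from .orchestrator import SimulationConfig
from .transport import TransportParams

__all__ = ["load_config", "dump_config", "save_config"]

log = logging.getLogger("callusim.config")

_SECTIONS = {
    "geometry": GeometrySpec,
    "load": LoadCase,
    "transport": TransportParams,
    "cells": CellParams,
    "rules": RuleParams,
    "prendergast": PrendergastParams,
}

_MATERIAL_PROPS = ("young", "permeability", "poisson", "porosity")


def _build_section(cls, data: Dict[str, Any], path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    for name in sorted(valid - set(data)):
        default = getattr(cls(), name)
        log.info("config default applied: %s.%s = %r", path, name, default)
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value under '{path}': {exc}") from exc


def _build_materials(data: Dict[str, Any]) -> MaterialTable:
    table = MaterialTable()
    unknown = set(data) - set(_MATERIAL_PROPS) - {"fluid_viscosity"}
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} under 'materials'")
    for prop in _MATERIAL_PROPS:
        for phen_name, value in (data.get(prop) or {}).items():
            try:
                phen = Phenotype[phen_name.upper()]
            except KeyError as exc:
                raise ValueError(
                    f"unknown phenotype '{phen_name}' under 'materials.{prop}'"
                ) from exc
            getattr(table, prop)[int(phen)] = float(value)
    if "fluid_viscosity" in data:
        table.fluid_viscosity = float(data["fluid_viscosity"])
    # re-run the table invariants after overrides
    table.__post_init__()
    return table


def load_config(path: str) -> SimulationConfig:
    """Load and fully validate a simulation configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: Dict[str, Any]) -> SimulationConfig:
    raw = dict(raw)
    kwargs: Dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        data = raw.pop(section, {}) or {}
        if not isinstance(data, dict):
            raise ValueError(f"section '{section}' must be a mapping")
        kwargs[section] = _build_section(cls, data, section)
    kwargs["materials"] = _build_materials(raw.pop("materials", {}) or {})
    scalar_fields = {
        f.name
        for f in dataclasses.fields(SimulationConfig)
        if f.name not in _SECTIONS and f.name != "materials"
    }
    unknown = set(raw) - scalar_fields
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
    for name in sorted(scalar_fields - set(raw)):
        log.info(
            "config default applied: %s = %r",
            name,
            getattr(SimulationConfig(), name),
        )
    kwargs.update(raw)
    try:
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def dump_config(config: SimulationConfig) -> Dict[str, Any]:
    """Plain-dict form of a configuration (YAML/JSON serialisable)."""
    out: Dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        out[section] = dataclasses.asdict(getattr(config, section))
    mat = config.materials
    out["materials"] = {
        prop: {
            p.name.lower(): float(getattr(mat, prop)[int(p)]) for p in Phenotype
        }
        for prop in _MATERIAL_PROPS
    }
    out["materials"]["fluid_viscosity"] = mat.fluid_viscosity
    for f in dataclasses.fields(SimulationConfig):
        if f.name in _SECTIONS or f.name == "materials":
            continue
        out[f.name] = getattr(config, f.name)
    return out


def save_config(config: SimulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dump_config(config), fh, sort_keys=True)
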