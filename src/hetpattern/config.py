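"""Validated YAML configuration I/O.

A configuration file has four sections::

    parameters:   # every ModelParameters symbol, flat key = symbol name
      beta_R: 0.02
      ...
    simulation:   # SimulationConfig fields (optional, defaults applied)
      dt: 0.01
      t_end: 72.0
      ...
    noise:        # NoiseSettings fields (optional)
      omega_phi: 0.12
      omega_lambda: 0.05
      seed: 0
    mutant:       # MutantSpec factors (optional, default wild type)
      rho_A_factor: 0.0

Unknown keys anywhere are rejected; missing required parameter keys raise a
validation error naming the offenders.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .model_core import ModelParameters, wild_type_parameters
from .simulate import MutantSpec, NoiseSettings, SimulationConfig

__all__ = ["load_config", "save_config", "default_config"]


def _build(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    if cls is ModelParameters:
        known -= {"enforce_commitment_convention"}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    if cls is ModelParameters:
        missing = known - set(section)
        if missing:
            raise ValueError(f"missing keys in section {name!r}: {sorted(missing)}")
    return cls(**section)


def load_config(
    path,
) -> Tuple[SimulationConfig, ModelParameters, NoiseSettings, MutantSpec]:
    """Load and validate a YAML configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(raw) - {"parameters", "simulation", "noise", "mutant"}
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    if "parameters" not in raw:
        raise ValueError(f"{path}: missing required section 'parameters'")
    params = _build(ModelParameters, raw["parameters"], "parameters")
    config = _build(SimulationConfig, raw.get("simulation", {}) or {}, "simulation")
    noise = _build(NoiseSettings, raw.get("noise", {}) or {}, "noise")
    mutant = _build(MutantSpec, raw.get("mutant", {}) or {}, "mutant")
    return config, params, noise, mutant


def save_config(
    path,
    config: SimulationConfig,
    params: ModelParameters,
    noise: NoiseSettings,
    mutant: Optional[MutantSpec] = None,
) -> None:
    """Write a configuration file that round-trips through load_config."""
    doc = {
        "parameters": params.to_dict(),
        "simulation": config.to_dict(),
        "noise": {
            "omega_phi": noise.omega_phi,
            "omega_lambda": noise.omega_lambda,
            "seed": noise.seed,
        },
        "mutant": (mutant or MutantSpec()).to_dict(),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def default_config() -> Tuple[SimulationConfig, ModelParameters, NoiseSettings, MutantSpec]:
    """Wild-type defaults (calibrated preset, standard run settings)."""
    return SimulationConfig(), wild_type_parameters(), NoiseSettings(), MutantSpec()
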