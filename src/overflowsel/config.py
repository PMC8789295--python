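"""Run configuration: YAML parsing, validation, and resolution to objects.

A run config is a flat-ish YAML mapping with optional sections::

    seed: 1
    model:
      alpha: 0.2        # any ModelParameters field
      couple_volumes: false
    size_law:
      V0: 0.28
      epsilon: 1.33
    droplet:
      diameter: 50.0    # any DropletDesign field
    synthetic:
      noise_cv: 0.05    # any SyntheticDesign field

Unknown keys are rejected so that typos fail loudly instead of silently
falling back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .droplets import DropletDesign, Genotype
from .parameters import ModelParameters
from .sizelaw import SizeGrowthLaw
from .synthetic import SyntheticDesign

__all__ = ["RunConfig", "load_config", "load_genotypes", "config_hash"]


def _dataclass_from_mapping(cls, mapping: dict[str, Any], section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section "
            f"{section!r}; known keys: {sorted(known)}"
        )
    return cls(**mapping)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    params: ModelParameters
    size_law: SizeGrowthLaw
    droplet: DropletDesign
    synthetic: SyntheticDesign
    couple_volumes: bool = False
    seed: int = 0
    verbosity: int = 1

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self,
            seed=seed,
            droplet=replace(self.droplet, seed=seed),
            synthetic=replace(self.synthetic, seed=seed),
        )

    def as_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "verbosity": self.verbosity,
            "model": {
                **{f.name: getattr(self.params, f.name)
                   for f in fields(ModelParameters)},
                "couple_volumes": self.couple_volumes,
            },
            "size_law": {f.name: getattr(self.size_law, f.name)
                         for f in fields(SizeGrowthLaw)},
            "droplet": {f.name: getattr(self.droplet, f.name)
                        for f in fields(DropletDesign)},
            "synthetic": {f.name: getattr(self.synthetic, f.name)
                          for f in fields(SyntheticDesign)},
        }


_SECTIONS = {"model", "size_law", "droplet", "synthetic", "seed", "verbosity"}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run config; missing keys fall back to the defaults."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(
            f"unknown top-level config key(s) {sorted(unknown)}; "
            f"known: {sorted(_SECTIONS)}"
        )
    model_raw = dict(raw.get("model") or {})
    couple = bool(model_raw.pop("couple_volumes", False))
    seed = int(raw.get("seed", 0))
    cfg = RunConfig(
        params=_dataclass_from_mapping(ModelParameters, model_raw, "model"),
        size_law=_dataclass_from_mapping(
            SizeGrowthLaw, dict(raw.get("size_law") or {}), "size_law"
        ),
        droplet=_dataclass_from_mapping(
            DropletDesign, dict(raw.get("droplet") or {}), "droplet"
        ),
        synthetic=_dataclass_from_mapping(
            SyntheticDesign, dict(raw.get("synthetic") or {}), "synthetic"
        ),
        couple_volumes=couple,
        seed=seed,
        verbosity=int(raw.get("verbosity", 1)),
    )
    return cfg.with_seed(seed)


def load_genotypes(
    path: str | Path, base: ModelParameters | None = None
) -> list[Genotype]:
    """Load competing genotypes from YAML.

    The file holds a list of mappings, each with a ``name``, an optional
    ``phi`` and optional ``params`` overrides of the base model parameters.
    """
    base = base or ModelParameters()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"genotype file {path} must hold a non-empty list")
    out = []
    for entry in raw:
        entry = dict(entry)
        name = entry.pop("name")
        phi = float(entry.pop("phi", 0.25))
        overrides = dict(entry.pop("params", {}) or {})
        if entry:
            raise ValueError(
                f"unknown genotype key(s) {sorted(entry)} for {name!r}"
            )
        out.append(
            Genotype(name=name, params=base.with_overrides(**overrides), phi=phi)
        )
    return out


def config_hash(cfg: RunConfig) -> str:
    """Short deterministic digest of the resolved configuration."""
    blob = json.dumps(cfg.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
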