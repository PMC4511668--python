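"""Simulation configuration.

A :class:`SimulationConfig` holds every parameter of one forward-time run of
the neutral host-microbiome model:

* ``num_hosts`` (N) — constant Wright-Fisher host population size;
* ``slots_per_host`` (n) — fixed microbiome capacity of each host;
* ``num_taxa`` (m) — number of microbial taxa in the environmental pool;
* ``parental_fraction`` (x) — per-slot probability that a slot is filled from
  the parent's microbiome rather than from the environment (MA_x; x=0 is pure
  environmental acquisition, x=1 pure parental acquisition);
* ``pooled_env_fraction`` (y) — weight of the pooled (previous host
  generation) component in the environment offered to offspring (ME_y; y=0 is
  the fixed environment, y=1 the fully pooled environment).

Defaults are the full study scale: N=500 hosts, n=1000 slots, m=150 taxa.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = ["SimulationConfig"]


@dataclass(frozen=True)
class SimulationConfig:
    num_hosts: int = 500
    slots_per_host: int = 1000
    num_taxa: int = 150
    parental_fraction: float = 0.0
    pooled_env_fraction: float = 0.0
    max_generations: int = 10_000
    record_interval: int = 100
    seed: int = 0
    stop_on_stabilization: bool = False
    stabilization_window: int = 500
    stabilization_tolerance: float = 1e-4
    min_generations: int = 1000
    stop_on_absorption: bool = False
    track_genealogy: bool = True
    richness_mode: str = "global"
    fixed_distribution: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("num_hosts", "slots_per_host", "num_taxa", "max_generations",
                     "record_interval"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        for name in ("parental_fraction", "pooled_env_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.stabilization_window < 2:
            raise ValueError("stabilization_window must be >= 2")
        if self.stabilization_tolerance <= 0:
            raise ValueError("stabilization_tolerance must be positive")
        if self.richness_mode not in ("global", "observed"):
            raise ValueError("richness_mode must be 'global' or 'observed'")
        if self.fixed_distribution is not None:
            vec = np.asarray(self.fixed_distribution, dtype=float)
            if vec.shape != (self.num_taxa,):
                raise ValueError("fixed_distribution must have length num_taxa")
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError("fixed_distribution must be non-negative and sum to 1")

    def fixed_env(self) -> np.ndarray:
        """Fixed-environment relative abundances (uniform unless overridden)."""
        if self.fixed_distribution is not None:
            return np.asarray(self.fixed_distribution, dtype=float)
        return np.full(self.num_taxa, 1.0 / self.num_taxa)

    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "SimulationConfig":
        """Load a config from a flat key-value YAML file; kwargs take precedence."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data["fixed_distribution"] is not None:
            data["fixed_distribution"] = list(data["fixed_distribution"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
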