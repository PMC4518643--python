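"""Run configuration: validated parameter bundle with YAML loading.

Defaults are the reference parameter set of the method: fit-set
cardinalities 20 (finest-level subchains) and 40 (coarse chain), 120 nm
minimum inter-bead distance at maximum resolution, 10 um maximum distance
between any two beads, 100 degrees maximum curvature.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig", "ConfigError", "file_sha256"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    resolution_bp: int = 100_000
    fit_pairs_high: int = 20
    fit_pairs_low: int = 40
    exclude_adjacent: bool = True
    min_pair_dist: float = 120.0
    max_pair_dist: float = 10_000.0
    max_curvature_deg: float = 100.0
    curvature_convention: str = "bend"
    bond_range: tuple[float, float] | None = None
    r_ref: float = 60.0
    t0: float | None = None
    alpha: float = 0.98
    t_min: float | None = None
    max_sweeps: int = 400
    moves_per_sweep: int | None = None
    stall_sweeps: int = 50
    max_planar_delta: float = 15.0
    max_dihedral_delta: float = 30.0
    bond_delta_frac: float = 0.05
    n_block_replicates: int = 1
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        from .annealing import AnnealingSchedule
        from .chain import ConstraintSet

        if self.resolution_bp <= 0:
            raise ConfigError("resolution_bp must be positive")
        for name in ("fit_pairs_high", "fit_pairs_low", "replicates", "n_block_replicates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.bond_range is not None:
            self.bond_range = tuple(float(x) for x in self.bond_range)  # type: ignore[assignment]
        # reuse the domain types' own validation
        ConstraintSet(
            min_pair_dist=self.min_pair_dist,
            max_pair_dist=self.max_pair_dist,
            max_curvature_deg=self.max_curvature_deg,
            bond_range=self.bond_range,
            curvature_convention=self.curvature_convention,
        )
        AnnealingSchedule(
            t0=self.t0, alpha=self.alpha, t_min=self.t_min,
            max_sweeps=self.max_sweeps, moves_per_sweep=self.moves_per_sweep,
            max_planar_delta=self.max_planar_delta,
            max_dihedral_delta=self.max_dihedral_delta,
            bond_delta_frac=self.bond_delta_frac, stall_sweeps=self.stall_sweeps,
        )

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "RunConfig":
        """Load a YAML key-value config; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        if overrides:
            data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def estimator_kwargs(self) -> dict:
        d = self.to_dict()
        d.pop("replicates")
        d.pop("seed")
        return d


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
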