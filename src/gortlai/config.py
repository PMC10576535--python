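"""Run configuration: every tunable of the pipeline with literature defaults."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .lai_model import GortParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    Defaults reproduce the published choices where stated: clumping 1.58,
    projection 0.5, 0.002-degree cells, 80% canopy-energy height, +/-3 sigma
    integration extent and +/-3 sd trimming.
    """

    bin_dz: float = 0.15
    noise_k: float = 0.0  # threshold widening: tau = sigmean * (1 + k)
    smooth_sigma_bins: float = 1.0
    smooth_before_denoise: bool = False  # filter first, then threshold
    em_tol: float = 1e-6
    em_max_iter: int = 200
    constrained: bool = True
    merge_tol_bins: Optional[float] = None
    min_component_weight: float = 0.01
    min_amplitude_frac: float = 0.05
    min_separation_bins: int = 3
    extent_sigmas: float = 3.0
    energy_fraction: float = 0.8
    cell_deg: float = 0.002
    clumping: float = 1.58
    projection: float = 0.5
    ratio_mode: str = "grid"  # "grid" | "per_pulse" | "fixed"
    fixed_ratio: float = 2.5
    clamp_negative_ratios: bool = True
    raw_rvz: bool = False
    seed: int = 0

    @property
    def gort(self) -> GortParams:
        return GortParams(clumping=self.clumping, projection=self.projection)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a TOML (.toml) or YAML (.yml/.yaml) file."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    elif path.suffix in (".yml", ".yaml"):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")
    return RunConfig.from_dict(data)
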