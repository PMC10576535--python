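"""GORT cover/gap equations, closed-form LAI inversion and baselines.

Forward model: canopy cover above height h is

    fcover(h) = (Rv(h) / Rv(0)) * 1 / (1 + (rho_v/rho_g) * Rg / Rv(0))

and total LAI follows from the gap probability at canopy bottom:

    LAI = (C / G) * ln(1 + Rv(0) / ((rho_v/rho_g) * Rg))

with clumping index C (default 1.58) and projection coefficient G (default
0.5, spherical leaf-angle distribution).  Baselines: a fixed-ratio inversion
(2.5, or 2.0) and an ordinary-least-squares NDVI->LAI regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np

from .canopy_energy import EnergyPartition

__all__ = [
    "GortParams",
    "LAIResult",
    "NdviLaiModel",
    "fcover_above",
    "gap_probability",
    "lai_total",
    "lai_profile",
    "lai_fixed_ratio_baseline",
    "fit_ndvi_lai",
]

SATURATION_EPS = 1e-12
DEFAULT_FIXED_RATIO = 2.5


@dataclass(frozen=True)
class GortParams:
    """Canopy structure parameters: clumping index C and projection G."""

    clumping: float = 1.58
    projection: float = 0.5

    def __post_init__(self) -> None:
        if not self.clumping > 0:
            raise ValueError("clumping index must be > 0")
        if not 0 < self.projection <= 1:
            raise ValueError("projection coefficient must be in (0, 1]")

    @property
    def k(self) -> float:
        """The C/G prefactor of the log-transform."""
        return self.clumping / self.projection


@dataclass
class LAIResult:
    """Per-pulse inversion output with provenance of the ratio used."""

    shotnumber: Optional[str]
    lai: float
    fcover_bottom: float
    ratio_used: float
    ratio_source: str  # "grid" | "fixed" | "per_pulse" | "global_fallback"
    valid: bool = True
    lon: float = float("nan")
    lat: float = float("nan")


def fcover_above(rv_h: float, rv0: float, rg: float, ratio: float) -> float:
    """Canopy cover fraction above the height where Rv(h) has accumulated."""
    if rv0 <= 0:
        return 0.0
    if rv_h < 0 or rv_h > rv0 * (1 + 1e-12):
        raise ValueError(f"Rv(h)={rv_h} outside [0, Rv(0)={rv0}]")
    if rg < 0 or ratio < 0:
        raise ValueError("Rg and ratio must be >= 0")
    return (rv_h / rv0) / (1.0 + ratio * rg / rv0)


def gap_probability(rv_h: float, rv0: float, rg: float, ratio: float) -> float:
    """1 - fcover_above(...)."""
    return 1.0 - fcover_above(rv_h, rv0, rg, ratio)


def lai_total(rv0: float, rg: float, ratio: float, p: GortParams = GortParams()) -> float:
    """Closed-form total LAI: (C/G) * ln(1 + Rv(0) / (ratio * Rg)).

    Returns 0 when there is no canopy energy and NaN (invalid) when the
    denominator ``ratio * Rg`` vanishes while canopy energy is present.
    """
    if rv0 < 0:
        raise ValueError("Rv(0) must be >= 0")
    if rv0 == 0:
        return 0.0
    denom = ratio * rg
    if denom <= 0:
        return float("nan")
    return p.k * math.log1p(rv0 / denom)


def lai_profile(
    partition: EnergyPartition, ratio: float, p: GortParams = GortParams()
) -> Callable[[float], float]:
    """Vertical LAI profile: LAI(h) = -(C/G) * ln(1 - fcover(h)).

    The returned callable maps elevation to cumulative LAI above it; it is
    non-decreasing downward and equals :func:`lai_total` at canopy bottom
    (algebraic identity).  Saturated cover (fcover -> 1) raises.
    """

    def profile(z: float) -> float:
        rv_h = partition.rv_above(z)
        fc = fcover_above(rv_h, partition.rv0, partition.rg, ratio) if partition.rv0 > 0 else 0.0
        if fc >= 1.0 - SATURATION_EPS:
            raise ValueError(f"cover saturated (fcover={fc}) at elevation {z}")
        return -p.k * math.log1p(-fc)

    return profile


def lai_fixed_ratio_baseline(
    rv0: float,
    rg: float,
    p: GortParams = GortParams(),
    ratio: float = DEFAULT_FIXED_RATIO,
    shotnumber: Optional[str] = None,
) -> LAIResult:
    """Inversion with a fixed literature ratio (default 2.5; 2.0 also in use)."""
    lai = lai_total(rv0, rg, ratio, p)
    valid = np.isfinite(lai)
    fc = fcover_above(rv0, rv0, rg, ratio) if rv0 > 0 else 0.0
    return LAIResult(
        shotnumber=shotnumber,
        lai=lai,
        fcover_bottom=fc,
        ratio_used=ratio,
        ratio_source="fixed",
        valid=bool(valid),
    )


@dataclass
class NdviLaiModel:
    """OLS line LAI = slope * NDVI + intercept; predictions floored at 0."""

    slope: float
    intercept: float
    r2: Optional[float]
    n: int

    def predict(self, ndvi: np.ndarray) -> np.ndarray:
        ndvi = np.asarray(ndvi, dtype=float)
        return np.maximum(self.slope * ndvi + self.intercept, 0.0)


def fit_ndvi_lai(ndvi: np.ndarray, lai_ref: np.ndarray) -> NdviLaiModel:
    """Fit the empirical NDVI->LAI line by ordinary least squares."""
    ndvi = np.asarray(ndvi, dtype=float)
    lai_ref = np.asarray(lai_ref, dtype=float)
    if ndvi.shape != lai_ref.shape or ndvi.size < 2:
        raise ValueError("ndvi and lai_ref must share length >= 2")
    if np.ptp(ndvi) == 0:
        raise ValueError("constant ndvi: singular regression")
    slope, intercept = np.polyfit(ndvi, lai_ref, 1)
    fitted = slope * ndvi + intercept
    ss_tot = float(np.sum((lai_ref - lai_ref.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - float(np.sum((lai_ref - fitted) ** 2)) / ss_tot
    return NdviLaiModel(slope=float(slope), intercept=float(intercept), r2=r2, n=ndvi.size)
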