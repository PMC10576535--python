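"""Canopy/ground component classification and energy integrals.

The component with the lowest elevation (latest bin) is the ground return;
everything above it is canopy.  Component energies are analytic Gaussian
integrals over a +/- n-sigma start-stop range (default 3 sigma, 99.73% of the
mass), clipped to the record and scaled by the vertical bin spacing.  The
cumulative canopy energy profile accumulates the canopy-only reconstruction
downward from the canopy top; ``z80`` is the elevation where it reaches a
given fraction (default 80%) of the total canopy energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import erf

from .decomposition import Decomposition, GaussianComponent, reconstruct_waveform
from .waveform_prep import Waveform

__all__ = [
    "EnergyPartition",
    "classify_components",
    "component_integral",
    "compute_energy_partition",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
DEFAULT_EXTENT_SIGMAS = 3.0
DEFAULT_ENERGY_FRACTION = 0.8


@dataclass
class EnergyPartition:
    """Energy split of one pulse: ground integral, canopy integral, profile.

    ``cum_elevations``/``cum_energy`` tabulate cumulative canopy energy
    accumulated downward from the canopy top (0 at the top, ``rv0`` at the
    bottom).  ``z_frac`` is the elevation where the accumulation reaches
    ``fraction * rv0`` (``None`` when there is no canopy energy).
    """

    rg: float
    rv0: float
    cum_elevations: np.ndarray
    cum_energy: np.ndarray
    z_frac: Optional[float]
    fraction: float
    ground_component_index: int
    n_canopy: int

    @property
    def rv_z(self) -> float:
        """Canopy energy above ``z_frac`` — ``fraction * rv0`` by construction."""
        return self.fraction * self.rv0

    def rv_above(self, z: float) -> float:
        """Cumulative canopy energy from the canopy top down to elevation ``z``."""
        if self.rv0 == 0.0:
            return 0.0
        # cum_elevations is strictly decreasing; interp wants increasing x
        return float(
            np.interp(-z, -self.cum_elevations, self.cum_energy, left=0.0, right=self.rv0)
        )


def classify_components(
    d: Decomposition,
) -> Tuple[List[GaussianComponent], GaussianComponent]:
    """Split a decomposition into (canopy components, ground component).

    The latest-centered (lowest elevation) component is ground; the rest are
    canopy.  A single-component decomposition is all ground.
    """
    if d.n_components < 1:
        raise ValueError("cannot classify an empty decomposition")
    return list(d.components[:-1]), d.components[-1]


def component_integral(
    c: GaussianComponent,
    extent_sigmas: float = DEFAULT_EXTENT_SIGMAS,
    bin_dz: float = 1.0,
    clip: Optional[Tuple[float, float]] = None,
) -> float:
    """Analytic energy of one Gaussian echo over its start-stop range.

    Integrates ``A * exp(-(t - tm)^2 / (2 sigma^2))`` over
    ``[tm - n*sigma, tm + n*sigma]`` (optionally clipped to ``clip`` bin
    bounds), scaled by ``bin_dz``.  ``extent_sigmas=None`` gives the full-line
    integral ``A * sigma * sqrt(2 pi)``.
    """
    full = c.amplitude * c.sigma * _SQRT_2PI
    if extent_sigmas is None and clip is None:
        return full * bin_dz
    lo = -np.inf if extent_sigmas is None else c.center - extent_sigmas * c.sigma
    hi = np.inf if extent_sigmas is None else c.center + extent_sigmas * c.sigma
    if clip is not None:
        lo, hi = max(lo, clip[0]), min(hi, clip[1])
    if hi <= lo:
        return 0.0

    def _cdf(t: float) -> float:
        if not np.isfinite(t):
            return 1.0 if t > 0 else 0.0
        return 0.5 * (1.0 + erf((t - c.center) / (c.sigma * math.sqrt(2.0))))

    return full * (_cdf(hi) - _cdf(lo)) * bin_dz


def compute_energy_partition(
    d: Decomposition,
    wave: Waveform,
    extent_sigmas: float = DEFAULT_EXTENT_SIGMAS,
    fraction: float = DEFAULT_ENERGY_FRACTION,
    raw_rvz: bool = False,
) -> EnergyPartition:
    """Compute Rg, Rv(0), the cumulative canopy profile and its z-fraction height.

    ``raw_rvz`` accumulates the raw denoised waveform over the canopy extent
    instead of the canopy-only reconstruction.
    """
    canopy, ground = classify_components(d)
    bin_dz = wave.bin_dz
    nbins = wave.nbins
    clip = (0.0, float(nbins - 1))
    rg = component_integral(ground, extent_sigmas, bin_dz, clip=clip)
    rv0 = sum(component_integral(c, extent_sigmas, bin_dz, clip=clip) for c in canopy)

    bins = np.arange(nbins, dtype=float)
    if not canopy:
        cum = np.zeros(nbins)
        return EnergyPartition(
            rg=rg,
            rv0=0.0,
            cum_elevations=wave.elevations.copy(),
            cum_energy=cum,
            z_frac=None,
            fraction=fraction,
            ground_component_index=d.n_components - 1,
            n_canopy=0,
        )

    if raw_rvz:
        # raw waveform restricted to the canopy start-stop extent
        lo = min(c.center - extent_sigmas * c.sigma for c in canopy)
        hi = max(c.center + extent_sigmas * c.sigma for c in canopy)
        mask = (bins >= lo) & (bins <= hi)
        profile = np.where(mask, wave.amplitudes, 0.0)
    else:
        canopy_only = Decomposition(components=list(canopy), bias=0.0)
        profile = reconstruct_waveform(canopy_only, bins)
    cum = np.cumsum(profile) * bin_dz
    total = cum[-1]
    if total > 0:
        cum = cum * (rv0 / total)  # normalize so the profile closes on Rv(0)
    target = fraction * rv0
    z_frac = _interp_crossing(wave.elevations, cum, target)
    return EnergyPartition(
        rg=rg,
        rv0=rv0,
        cum_elevations=wave.elevations.copy(),
        cum_energy=cum,
        z_frac=z_frac,
        fraction=fraction,
        ground_component_index=d.n_components - 1,
        n_canopy=len(canopy),
    )


def _interp_crossing(
    elevations: np.ndarray, cum: np.ndarray, target: float
) -> Optional[float]:
    """Highest elevation where the downward accumulation reaches ``target``."""
    if cum[-1] <= 0:
        return None
    idx = int(np.argmax(cum >= target))
    if cum[idx] < target:
        return float(elevations[-1])
    if idx == 0 or cum[idx] == cum[idx - 1]:
        return float(elevations[idx])
    f = (target - cum[idx - 1]) / (cum[idx] - cum[idx - 1])
    return float(elevations[idx - 1] + f * (elevations[idx] - elevations[idx - 1]))
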