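"""Forward simulator: pulse tables with matched cover values and known truth.

Scenes draw pulse locations over a geographic extent, assign each pulse an
LAI from a smooth random field (and optionally a spatially varying
reflectivity ratio), convert LAI to a canopy/ground energy split with the
forward GORT relation, and synthesize a Gaussian-mixture waveform whose
component energies realize that split.  The emitted cover column is the
forward-model cover at the pulse's 80%-canopy-energy height, so the ratio
estimator is exactly consistent with truth when cover noise is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd

from .lai_model import GortParams
from .waveform_prep import PulseRecord

__all__ = ["SceneSpec", "forward_energies", "simulate_waveform", "simulate_scene"]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_MASS_3SIG = math.erf(3.0 / math.sqrt(2.0))  # 0.9973002


@dataclass
class SceneSpec:
    """Ground truth and noise parameters for one synthetic scene."""

    extent: Tuple[float, float, float, float] = (-72.20, 42.50, -72.10, 42.56)
    n_pulses: int = 500
    lai_range: Tuple[float, float] = (0.0, 8.0)
    true_ratio: float = 2.45
    ratio_variation: float = 0.0  # peak-to-peak amplitude of the ratio field
    canopy_bottom: float = 3.0  # meters above ground
    canopy_top: float = 20.0
    ground_elev: float = 300.0
    ground_elev_variation: float = 20.0
    total_energy: float = 2000.0
    n_canopy_components: Tuple[int, int] = (1, 3)  # inclusive range
    canopy_sigma_m: Tuple[float, float] = (0.5, 2.0)
    ground_sigma_m: Tuple[float, float] = (0.3, 0.8)
    noise_sd: float = 0.0
    sigmean: float = 10.0
    fvc_noise_sd: float = 0.0
    energy_fraction: float = 0.8  # cover is emitted at this canopy-energy height
    bin_dz: float = 0.15
    ndvi_slope: float = 0.05  # weakly informative NDVI = a + b * LAI + noise
    ndvi_intercept: float = 0.3
    ndvi_noise_sd: float = 0.0
    gort: GortParams = field(default_factory=GortParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lai_range[0] < 0:
            raise ValueError("lai_range must be non-negative")
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be > 0")
        if self.n_pulses < 1:
            raise ValueError("scene needs at least one pulse")


def forward_energies(
    lai: float, ratio: float, rg: float, p: GortParams = GortParams()
) -> float:
    """Canopy energy Rv(0) realizing a target LAI at a given ratio and Rg.

    Inverse of the closed-form inversion: Rv(0) = ratio * Rg * (exp(G*LAI/C) - 1).
    """
    if lai < 0:
        raise ValueError("lai must be >= 0")
    if ratio <= 0 or rg <= 0:
        raise ValueError("ratio and Rg must be > 0")
    return ratio * rg * math.expm1(lai / p.k)


def _smooth_field(rng: np.random.Generator, n_terms: int = 4) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """A smooth random field on the unit square with values in [0, 1]."""
    freqs = rng.uniform(0.5, 3.0, size=(n_terms, 2))
    phases = rng.uniform(0, 2 * np.pi, size=n_terms)
    amps = rng.uniform(0.5, 1.0, size=n_terms)

    def f(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        acc = np.zeros(np.broadcast(u, v).shape)
        for (fu, fv), ph, a in zip(freqs, phases, amps):
            acc = acc + a * np.cos(2 * np.pi * (fu * u + fv * v) + ph)
        lo, hi = -amps.sum(), amps.sum()
        return (acc - lo) / (hi - lo)

    return f


def simulate_waveform(
    rv0: float,
    rg: float,
    spec: SceneSpec,
    rng: np.random.Generator,
    shotnumber: str = "0",
    lon: float = float("nan"),
    lat: float = float("nan"),
    ground_elev: Optional[float] = None,
    fvc: Optional[float] = None,
    ndvi: Optional[float] = None,
) -> PulseRecord:
    """Synthesize one pulse whose component energies realize (rv0, rg).

    Canopy energy is split across 1-3 Gaussians at random heights within the
    canopy layer; the ground Gaussian sits at the ground elevation.  Component
    amplitudes are set so each +/-3 sigma integral (times bin_dz) matches its
    assigned energy.  Additive white Gaussian noise rides on a constant
    ``sigmean`` offset; zt/zg derive from the noiseless signal support.
    """
    if rv0 < 0 or rg < 0:
        raise ValueError("energies must be >= 0")
    g0 = spec.ground_elev if ground_elev is None else ground_elev
    sigma_g = rng.uniform(*spec.ground_sigma_m)
    n_canopy = int(rng.integers(spec.n_canopy_components[0], spec.n_canopy_components[1] + 1))
    if rv0 == 0:
        n_canopy = 0

    centers_m = [g0]
    sigmas_m = [sigma_g]
    energies = [rg]
    if n_canopy:
        for _ in range(64):  # resample until echoes clear each other and the ground
            cz = np.sort(rng.uniform(g0 + spec.canopy_bottom, g0 + spec.canopy_top, n_canopy))[::-1]
            cs = rng.uniform(*spec.canopy_sigma_m, size=n_canopy)
            gaps_ok = all(
                cz[i] - cz[i + 1] >= 2.0 * (cs[i] + cs[i + 1]) for i in range(n_canopy - 1)
            )
            if gaps_ok and cz.min() - g0 >= 2.0 * (cs.max() + sigma_g):
                break
        fracs = rng.dirichlet(np.full(n_canopy, 2.0))
        centers_m = list(cz) + centers_m
        sigmas_m = list(cs) + sigmas_m
        energies = list(rv0 * fracs) + energies

    centers_m = np.asarray(centers_m)
    sigmas_m = np.asarray(sigmas_m)
    energies = np.asarray(energies)
    amps = energies / (sigmas_m / spec.bin_dz * _SQRT_2PI * _MASS_3SIG * spec.bin_dz)

    top = float((centers_m + 4.0 * sigmas_m).max())
    bottom = float((centers_m - 4.0 * sigmas_m).min())
    nbins = int(math.ceil((top - bottom) / spec.bin_dz)) + 1
    elev = top - np.arange(nbins) * spec.bin_dz
    signal = np.zeros(nbins)
    for a, cz, s in zip(amps, centers_m, sigmas_m):
        signal += a * np.exp(-((elev - cz) ** 2) / (2.0 * s**2))
    noise = rng.normal(0.0, spec.noise_sd, nbins) if spec.noise_sd > 0 else 0.0
    rxwave = np.maximum(signal + spec.sigmean + noise, 0.0)

    return PulseRecord(
        shotnumber=shotnumber,
        lon=lon,
        lat=lat,
        zt=float(elev[0]),
        zg=float(g0),
        sigmean=spec.sigmean,
        rxwave=rxwave,
        bin_dz=spec.bin_dz,
        fvc=fvc,
        ndvi=ndvi,
    )


def true_fvc(rv0: float, rg: float, ratio: float, fraction: float) -> float:
    """Forward-model cover at the given canopy-energy fraction height."""
    if rv0 <= 0:
        return 0.0
    return fraction * rv0 / (rv0 + ratio * rg)


def simulate_scene(spec: SceneSpec) -> Tuple[list, pd.DataFrame]:
    """Simulate a scene: (list of PulseRecord, truth DataFrame).

    Truth rows carry per-pulse lai, ratio, Rv(0), Rg, the noise-free cover and
    the emitted (possibly noisy) cover.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    lon_min, lat_min, lon_max, lat_max = spec.extent
    lai_field = _smooth_field(rng)
    ratio_field = _smooth_field(rng)
    elev_field = _smooth_field(rng)

    lons = rng.uniform(lon_min, lon_max, spec.n_pulses)
    lats = rng.uniform(lat_min, lat_max, spec.n_pulses)
    u = (lons - lon_min) / (lon_max - lon_min)
    v = (lats - lat_min) / (lat_max - lat_min)
    lai = spec.lai_range[0] + (spec.lai_range[1] - spec.lai_range[0]) * lai_field(u, v)
    ratio = spec.true_ratio + spec.ratio_variation * (ratio_field(u, v) - 0.5)
    ratio = np.maximum(ratio, 0.05)
    g_elev = spec.ground_elev + spec.ground_elev_variation * (elev_field(u, v) - 0.5)

    pulses = []
    truth_rows = []
    for i in range(spec.n_pulses):
        total = spec.total_energy * rng.uniform(0.8, 1.2)
        rg = total / (1.0 + ratio[i] * math.expm1(lai[i] / spec.gort.k))
        rv0 = forward_energies(lai[i], ratio[i], rg, spec.gort) if lai[i] > 0 else 0.0
        fvc0 = true_fvc(rv0, rg, ratio[i], spec.energy_fraction)
        fvc = fvc0
        if spec.fvc_noise_sd > 0:
            fvc = fvc0 + rng.normal(0.0, spec.fvc_noise_sd)
        fvc = float(np.clip(fvc, 1e-6, 1.0))
        ndvi = spec.ndvi_intercept + spec.ndvi_slope * lai[i]
        if spec.ndvi_noise_sd > 0:
            ndvi += rng.normal(0.0, spec.ndvi_noise_sd)
        ndvi = float(np.clip(ndvi, -1.0, 1.0))
        shot = str(i)
        pulses.append(
            simulate_waveform(
                rv0,
                rg,
                spec,
                rng,
                shotnumber=shot,
                lon=float(lons[i]),
                lat=float(lats[i]),
                ground_elev=float(g_elev[i]),
                fvc=fvc,
                ndvi=ndvi,
            )
        )
        truth_rows.append(
            {
                "shotnumber": shot,
                "lon": float(lons[i]),
                "lat": float(lats[i]),
                "lai": float(lai[i]),
                "ratio": float(ratio[i]),
                "rv0": float(rv0),
                "rg": float(rg),
                "fvc_true": float(fvc0),
                "fvc": fvc,
                "ndvi": ndvi,
            }
        )
    return pulses, pd.DataFrame(truth_rows)
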