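"""Raw pulse data model, background-noise removal and Gaussian smoothing.

A pulse is a single large-footprint laser shot: a geolocated return waveform
(one amplitude per time bin) plus the elevations of the highest detected
signal (``zt``) and the lowest detected mode (``zg``) and the mean background
noise level recorded for the shot (``sigmean``).  Waveforms are mapped onto a
strictly decreasing elevation axis anchored at ``zt`` so that "energy above
height h" is computable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PulseRecord",
    "PulseValidationError",
    "Waveform",
    "bin_elevations",
    "remove_noise",
    "gaussian_smooth",
]

DEFAULT_BIN_DZ = 0.15
"""Default vertical bin spacing in meters."""


class PulseValidationError(ValueError):
    """A pulse record violates its invariants (per-record, recoverable)."""


@dataclass
class PulseRecord:
    """One laser shot: waveform, geolocation, noise level, optional covariates.

    Parameters
    ----------
    shotnumber : opaque shot identifier.
    lon, lat : geographic coordinates, degrees WGS84.
    zt : elevation of the highest detected signal, meters.
    zg : elevation of the lowest detected mode, meters.
    sigmean : mean background noise level, amplitude units.
    rxwave : return waveform, one amplitude per time bin.
    bin_dz : vertical spacing per bin, meters (> 0).
    fvc : fractional vegetation cover in [0, 1], or ``None``.
    ndvi : normalized difference vegetation index in [-1, 1], or ``None``.
    """

    shotnumber: str
    lon: float
    lat: float
    zt: float
    zg: float
    sigmean: float
    rxwave: np.ndarray
    bin_dz: float = DEFAULT_BIN_DZ
    fvc: Optional[float] = None
    ndvi: Optional[float] = None

    def __post_init__(self) -> None:
        self.rxwave = np.asarray(self.rxwave, dtype=float)

    def validate(self) -> None:
        """Raise :class:`PulseValidationError` if any invariant is broken."""
        if not (np.isfinite(self.zt) and np.isfinite(self.zg)):
            raise PulseValidationError(
                f"shot {self.shotnumber}: non-finite zt/zg ({self.zt}, {self.zg})"
            )
        if self.zt < self.zg:
            raise PulseValidationError(
                f"shot {self.shotnumber}: zt ({self.zt}) < zg ({self.zg})"
            )
        if self.rxwave.ndim != 1 or self.rxwave.size < 2:
            # a single-bin record is only admissible in the degenerate
            # zt == zg case (no vertical extent at all)
            if not (self.rxwave.size == 1 and self.zt == self.zg):
                raise PulseValidationError(
                    f"shot {self.shotnumber}: waveform needs >= 2 bins"
                )
        if not np.all(np.isfinite(self.rxwave)):
            raise PulseValidationError(
                f"shot {self.shotnumber}: non-finite waveform amplitude"
            )
        if not np.isfinite(self.sigmean) or self.sigmean < 0:
            raise PulseValidationError(
                f"shot {self.shotnumber}: sigmean must be finite and >= 0"
            )
        if not self.bin_dz > 0:
            raise PulseValidationError(
                f"shot {self.shotnumber}: bin_dz must be > 0"
            )
        if self.fvc is not None and not (0.0 <= self.fvc <= 1.0):
            raise PulseValidationError(
                f"shot {self.shotnumber}: fvc {self.fvc} outside [0, 1]"
            )
        if self.ndvi is not None and not (-1.0 <= self.ndvi <= 1.0):
            raise PulseValidationError(
                f"shot {self.shotnumber}: ndvi {self.ndvi} outside [-1, 1]"
            )


@dataclass
class Waveform:
    """A waveform on an elevation axis.

    ``elevations`` is strictly decreasing with constant step ``-bin_dz``;
    bin 0 sits at the elevation of the highest detected signal.
    """

    amplitudes: np.ndarray
    elevations: np.ndarray
    denoised: bool = False
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.amplitudes.shape != self.elevations.shape:
            raise ValueError("amplitudes and elevations must have equal length")

    @property
    def nbins(self) -> int:
        return int(self.amplitudes.size)

    @property
    def bin_dz(self) -> float:
        if self.elevations.size < 2:
            return DEFAULT_BIN_DZ
        return float(self.elevations[0] - self.elevations[1])

    def elevation_of_bin(self, t: float) -> float:
        """Elevation at (possibly fractional) bin coordinate ``t``."""
        return float(self.elevations[0] - t * self.bin_dz)

    def bin_of_elevation(self, z: float) -> float:
        """Fractional bin coordinate of elevation ``z`` (inverse affine map)."""
        return float((self.elevations[0] - z) / self.bin_dz)


def bin_elevations(pulse: PulseRecord) -> Waveform:
    """Map waveform bins to elevations: bin ``i`` lies at ``zt - i * bin_dz``."""
    pulse.validate()
    n = pulse.rxwave.size
    elevations = pulse.zt - np.arange(n, dtype=float) * pulse.bin_dz
    return Waveform(amplitudes=pulse.rxwave.copy(), elevations=elevations)


def remove_noise(wave: Waveform, sigmean: float, k: float = 0.0) -> Waveform:
    """Remove the per-shot background-noise floor from a waveform.

    With threshold ``tau = sigmean * (1 + k)``: bins at or above ``tau`` keep
    ``amplitude - sigmean`` (the baseline is subtracted so energy integrals
    measure signal above the noise floor); bins below ``tau`` are zeroed.

    ``k`` widens the cut above the mean noise level (e.g. to a few noise
    standard deviations) without shifting the subtracted baseline.
    """
    if not (np.isfinite(sigmean) and sigmean >= 0):
        raise ValueError(f"sigmean must be finite and >= 0, got {sigmean}")
    tau = sigmean * (1.0 + k)
    amp = wave.amplitudes
    out = np.where(amp >= tau, np.maximum(amp - sigmean, 0.0), 0.0)
    return replace(wave, amplitudes=out, denoised=True)


def gaussian_smooth(wave: Waveform, kernel_sigma_bins: float = 1.0) -> Waveform:
    """Smooth with a unit-sum Gaussian kernel (truncated at 4 sigma, reflect).

    Conserves total amplitude of signals supported away from the edges.
    """
    if not kernel_sigma_bins > 0:
        raise ValueError("kernel_sigma_bins must be > 0")
    out = gaussian_filter1d(
        wave.amplitudes, sigma=kernel_sigma_bins, mode="reflect", truncate=4.0
    )
    return replace(wave, amplitudes=out, smoothed=True)
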