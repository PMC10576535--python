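"""Shared builders for synthetic waveforms used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from gortlai.waveform_prep import Waveform


def gaussian_sum_waveform(components, n, noise_sd=0.0, sigmean=0.0, rng=None,
                          top_elev=300.0, bin_dz=0.15):
    """Waveform = sum of (A, center_bin, sigma_bins) Gaussians + offset + noise."""
    t = np.arange(n, dtype=float)
    amp = np.zeros(n)
    for a, c, s in components:
        amp += a * np.exp(-((t - c) ** 2) / (2.0 * s**2))
    amp += sigmean
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise needs an rng")
        amp = amp + rng.normal(0.0, noise_sd, n)
    amp = np.maximum(amp, 0.0)
    elev = top_elev - t * bin_dz
    return Waveform(amplitudes=amp, elevations=elev)


def close_peak_waveform(rng, noise_sd=6.0, sigmean=20.0):
    """Two canopy peaks 1.5-2.5 sigma apart plus a ground peak, with noise.

    Returns (waveform, truth_components) where truth is [(A, center, sigma)].
    """
    sig = rng.uniform(3, 5)
    sep = rng.uniform(1.5, 2.5) * sig
    c1 = rng.uniform(30, 40)
    c2 = c1 + sep
    g = c2 + rng.uniform(6, 8) * sig
    truth = [
        (rng.uniform(60, 100), c1, sig),
        (rng.uniform(60, 100), c2, sig * rng.uniform(0.9, 1.1)),
        (rng.uniform(80, 120), g, rng.uniform(2, 3)),
    ]
    n = int(g + 8 * sig)
    wave = gaussian_sum_waveform(truth, n, noise_sd=noise_sd, sigmean=sigmean, rng=rng)
    return wave, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
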