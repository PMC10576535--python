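"""Agreement metrics and accuracy reports.

Covers three comparisons: waveform-fit quality, raw-vs-fitted energy-integral
agreement (ground and canopy separately), and estimated-vs-reference LAI
accuracy per method.  Pearson correlation and the coefficient of
determination (1 - SSres/SStot) are computed independently; they are not
interchangeable for biased predictors, so reports carry both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np

from .canopy_energy import classify_components, component_integral
from .decomposition import Decomposition
from .waveform_prep import Waveform

__all__ = [
    "AccuracyReport",
    "pearson_r",
    "r_squared",
    "mse",
    "rmse",
    "mae",
    "integral_agreement",
    "accuracy_report",
]


def _check(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must share length >= 2")


def pearson_r(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Pearson correlation; ``None`` when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def r_squared(obs: np.ndarray, pred: np.ndarray) -> Optional[float]:
    """Coefficient of determination 1 - SSres/SStot (may be negative)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    _check(obs, pred)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return None
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def mse(obs: np.ndarray, pred: np.ndarray) -> float:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    _check(obs, pred)
    return float(np.mean((obs - pred) ** 2))


def rmse(obs: np.ndarray, pred: np.ndarray) -> float:
    return math.sqrt(mse(obs, pred))


def mae(obs: np.ndarray, pred: np.ndarray) -> float:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    _check(obs, pred)
    return float(np.mean(np.abs(obs - pred)))


@dataclass
class AccuracyReport:
    """One method's accuracy row against reference values."""

    method: str
    correlation: Optional[float]
    r2: Optional[float]
    r2_pearson_sq: Optional[float]
    rmse: float
    mae: float
    n: int

    def to_dict(self) -> Dict[str, object]:
        return asdict(self)


def integral_agreement(
    waveforms: Sequence[Waveform],
    decompositions: Sequence[Decomposition],
    extent_sigmas: float = 3.0,
) -> Dict[str, Dict[str, Optional[float]]]:
    """Raw-vs-fitted energy agreement across an ensemble, for Rg and Rv.

    For each pulse the raw integral sums the denoised waveform over the
    classified component extents (ground: the last component's +/- n sigma
    window; canopy: union of the others'), while the fitted integral is the
    analytic component mass over the same window.  Returns per-parameter
    R2 and RMSE across the ensemble.
    """
    if len(waveforms) == 0 or len(waveforms) != len(decompositions):
        raise ValueError("need equal, non-empty waveform/decomposition lists")
    raw = {"Rg": [], "Rv": []}
    fit = {"Rg": [], "Rv": []}
    for wave, d in zip(waveforms, decompositions):
        canopy, ground = classify_components(d)
        bins = np.arange(wave.nbins, dtype=float)
        dz = wave.bin_dz
        clip = (0.0, float(wave.nbins - 1))

        g_mask = np.abs(bins - ground.center) <= extent_sigmas * ground.sigma
        raw["Rg"].append(float(wave.amplitudes[g_mask].sum() * dz))
        fit["Rg"].append(component_integral(ground, extent_sigmas, dz, clip=clip))

        c_mask = np.zeros(wave.nbins, dtype=bool)
        for c in canopy:
            c_mask |= np.abs(bins - c.center) <= extent_sigmas * c.sigma
        c_mask &= ~g_mask  # ground window takes precedence where they overlap
        raw["Rv"].append(float(wave.amplitudes[c_mask].sum() * dz))
        fit["Rv"].append(
            sum(component_integral(c, extent_sigmas, dz, clip=clip) for c in canopy)
        )
    out = {}
    for key in ("Rg", "Rv"):
        obs = np.asarray(raw[key])
        prd = np.asarray(fit[key])
        out[key] = {"r2": r_squared(obs, prd), "rmse": rmse(obs, prd), "n": obs.size}
    return out


def accuracy_report(
    est_lai: np.ndarray, ref_lai: np.ndarray, method_label: str
) -> AccuracyReport:
    """Accuracy of estimated vs reference LAI for one method."""
    est = np.asarray(est_lai, dtype=float)
    ref = np.asarray(ref_lai, dtype=float)
    _check(est, ref)
    r = pearson_r(ref, est)
    return AccuracyReport(
        method=method_label,
        correlation=r,
        r2=r_squared(ref, est),
        r2_pearson_sq=None if r is None else r * r,
        rmse=rmse(ref, est),
        mae=mae(ref, est),
        n=est.size,
    )
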