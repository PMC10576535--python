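"""Gaussian waveform decomposition by (optionally constrained) EM.

The denoised waveform is modeled as a bias plus a superposition of Gaussian
components.  Fitting runs amplitude-weighted EM: each bin position acts as a
pseudo-sample whose sample weight is the bin's denoised amplitude.  In the
constrained variant each component mean is projected, at every M-step, onto
the box ``[mu_j0 - sigma_j0, mu_j0 + sigma_j0]`` defined by its *initial*
parameters; this keeps close echoes from being merged during optimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .waveform_prep import Waveform

__all__ = [
    "GaussianComponent",
    "EMState",
    "Decomposition",
    "project_interval",
    "estimate_initial_components",
    "em_decompose",
    "polish_components",
    "refine_amplitudes",
    "reconstruct_waveform",
    "fit_metrics",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_HWHM_TO_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))
SIGMA_FLOOR_BINS = 0.25
WEIGHT_COLLAPSE = 1e-12


@dataclass
class GaussianComponent:
    """One fitted Gaussian echo: A * exp(-(t - tm)^2 / (2 * sigma^2))."""

    amplitude: float  # A, amplitude units, > 0
    center: float  # tm, bin coordinate
    sigma: float  # bins, > 0
    weight: float = 1.0  # mixture weight in (0, 1]

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(-((t - self.center) ** 2) / (2.0 * self.sigma**2))


@dataclass
class EMState:
    """Bookkeeping for one EM run (pseudo-samples, seeds, trace)."""

    pseudo_samples: np.ndarray
    sample_weights: np.ndarray
    init_centers: np.ndarray
    init_widths: np.ndarray
    n_iter: int = 0
    loglik_trace: List[float] = field(default_factory=list)
    dropped: List[int] = field(default_factory=list)


@dataclass
class Decomposition:
    """Fitted mixture: bias + components ordered by center (highest first)."""

    components: List[GaussianComponent]
    bias: float = 0.0
    converged: bool = False
    fit: Dict[str, Optional[float]] = field(default_factory=dict)
    state: Optional[EMState] = None

    @property
    def n_components(self) -> int:
        return len(self.components)

    def __post_init__(self) -> None:
        self.components.sort(key=lambda c: c.center)


def project_interval(x: float, a: float, b: float) -> float:
    """Project ``x`` onto the closed interval ``[a, b]``."""
    if a > b:
        raise ValueError(f"empty interval: a ({a}) > b ({b})")
    return min(max(x, a), b)


def estimate_initial_components(
    wave: Waveform,
    min_amplitude_frac: float = 0.05,
    min_separation_bins: int = 3,
) -> List[GaussianComponent]:
    """Seed one component per retained local maximum of a smoothed waveform.

    Center = peak bin, amplitude = peak value, width = half-width at half
    maximum divided by sqrt(2 ln 2), floored at one bin.  Peaks below
    ``min_amplitude_frac`` of the global maximum, or closer than
    ``min_separation_bins`` to a larger peak, are dropped.  Coincident-height
    neighbors keep the earlier (higher-elevation) bin.
    """
    amp = wave.amplitudes
    if amp.size == 0 or not np.any(amp > 0):
        return []
    height = min_amplitude_frac * float(amp.max())
    # pad so maxima at the array edges are detectable
    padded = np.concatenate(([0.0], amp, [0.0]))
    peaks, _ = find_peaks(padded, height=height, distance=max(min_separation_bins, 1))
    if peaks.size == 0:
        return []
    widths_full, _, _, _ = peak_widths(padded, peaks, rel_height=0.5)
    comps = []
    for pk, fwhm in zip(peaks, widths_full):
        sigma = max((fwhm / 2.0) * _HWHM_TO_SIGMA, 1.0)
        comps.append(
            GaussianComponent(
                amplitude=float(padded[pk]), center=float(pk - 1), sigma=float(sigma)
            )
        )
    comps.sort(key=lambda c: c.center)
    return comps


def _log_gauss(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log N(x; mu, sigma) as an (n_samples, n_components) matrix."""
    z = (x[:, None] - mu[None, :]) / sigma[None, :]
    return -0.5 * z**2 - np.log(sigma[None, :] * _SQRT_2PI)


def em_decompose(
    wave: Waveform,
    init: Sequence[GaussianComponent],
    constrained: bool = True,
    tol: float = 1e-6,
    max_iter: int = 200,
    merge_tol: Optional[float] = None,
    min_weight: float = 0.0,
) -> Decomposition:
    """Fit a Gaussian mixture to the denoised waveform by weighted EM.

    Parameters
    ----------
    wave : denoised waveform (bias assumed removed).
    init : seed components; their centers/widths define the constraint boxes.
    constrained : project each mean onto ``[mu_j0 - sigma_j0, mu_j0 + sigma_j0]``
        at every M-step.
    tol : relative log-likelihood change declaring convergence.
    max_iter : iteration cap.
    merge_tol : if set, fuse components whose centers ended closer than this
        many bins (weighted average); off by default.
    min_weight : drop fitted components carrying less than this fraction of
        the total mass (guards against residual-noise wisps); off by default.

    Returns a :class:`Decomposition` whose component amplitudes are recovered
    as ``A = w * W_tot / (sigma * sqrt(2 pi))`` with ``W_tot`` the total
    denoised amplitude mass, and whose ``fit`` dict carries R2/MAE/MSE/RMSE of
    the reconstruction against the input waveform.
    """
    if len(init) == 0:
        raise ValueError("em_decompose needs a non-empty initial component list")
    amp = wave.amplitudes
    support = amp > 0
    if not np.any(support):
        raise ValueError("all-zero waveform cannot be decomposed")
    x = np.flatnonzero(support).astype(float)
    c = amp[support]
    w_tot = float(c.sum())

    mu = np.array([comp.center for comp in init], dtype=float)
    sigma = np.maximum([comp.sigma for comp in init], SIGMA_FLOOR_BINS).astype(float)
    mu0 = mu.copy()
    sigma0 = sigma.copy()
    # seed weights from the seed amplitudes' implied masses
    mass = np.array([comp.amplitude * comp.sigma for comp in init], dtype=float)
    w = mass / mass.sum() if mass.sum() > 0 else np.full(len(init), 1.0 / len(init))

    state = EMState(
        pseudo_samples=x, sample_weights=c, init_centers=mu0, init_widths=sigma0
    )
    keep_idx = np.arange(len(init))
    prev_ll = -np.inf
    converged = False

    for it in range(max_iter):
        log_p = _log_gauss(x, mu, sigma) + np.log(w)[None, :]
        m = log_p.max(axis=1)
        log_tot = m + np.log(np.exp(log_p - m[:, None]).sum(axis=1))
        ll = float(np.dot(c, log_tot))
        state.loglik_trace.append(ll)
        gamma = np.exp(log_p - log_tot[:, None])  # responsibilities, rows sum to 1

        nj = gamma.T @ c  # weighted responsibility mass per component
        alive = nj > WEIGHT_COLLAPSE * w_tot
        if not np.all(alive):
            state.dropped.extend(int(i) for i in keep_idx[~alive])
            mu, sigma, mu0, sigma0, nj = (
                a[alive] for a in (mu, sigma, mu0, sigma0, nj)
            )
            gamma = gamma[:, alive]
            keep_idx = keep_idx[alive]
            if mu.size == 0:
                raise ValueError("all components collapsed during EM")

        mu_new = (gamma * c[:, None]).T @ x / nj
        if constrained:
            mu_new = np.clip(mu_new, mu0 - sigma0, mu0 + sigma0)
        var = np.einsum("kn,kn->k", gamma.T * c[None, :], (x[None, :] - mu_new[:, None]) ** 2)
        sigma_new = np.sqrt(var / nj)
        sigma_new = np.maximum(sigma_new, SIGMA_FLOOR_BINS)
        mu, sigma = mu_new, sigma_new
        w = nj / w_tot
        w = w / w.sum()

        state.n_iter = it + 1
        if prev_ll > -np.inf:
            denom = max(abs(prev_ll), 1.0)
            if abs(ll - prev_ll) / denom < tol:
                converged = True
                break
        prev_ll = ll

    amps = w * w_tot / (sigma * _SQRT_2PI)
    comps = [
        GaussianComponent(amplitude=float(a), center=float(m_), sigma=float(s), weight=float(wj))
        for a, m_, s, wj in zip(amps, mu, sigma, w)
    ]
    comps.sort(key=lambda cmp: cmp.center)
    if min_weight > 0.0 and len(comps) > 1:
        kept = [cmp for cmp in comps if cmp.weight >= min_weight]
        comps = kept or [max(comps, key=lambda cmp: cmp.weight)]
    if merge_tol is not None:
        comps = _merge_close(comps, merge_tol)

    d = Decomposition(components=comps, bias=0.0, converged=converged, state=state)
    fitted = reconstruct_waveform(d, np.arange(amp.size, dtype=float))
    d.fit = fit_metrics(amp, fitted)
    return d


def polish_components(
    d: Decomposition,
    wave: Waveform,
    center_slack: float = 2.0,
) -> Decomposition:
    """Bounded nonlinear least-squares polish of an EM decomposition.

    Refines every (amplitude, center, sigma) triple against the waveform by
    trust-region least squares, starting from the EM solution with centers
    boxed to ``+/- center_slack`` bins of it (so the polish stays in the EM
    basin and cannot merge echoes).  Under additive white noise this is the
    efficient (maximum-likelihood) estimate, which the moment-based EM
    updates are not; run it on a baseline-subtracted, un-thresholded waveform
    for unbiased amplitudes.
    """
    from scipy.optimize import curve_fit

    bins = np.arange(wave.nbins, dtype=float)

    def model(x, *p):
        out = np.zeros_like(x)
        for j in range(0, len(p), 3):
            a, c, s = p[j : j + 3]
            out = out + a * np.exp(-((x - c) ** 2) / (2.0 * s**2))
        return out

    p0, lo, hi = [], [], []
    for comp in d.components:
        p0 += [comp.amplitude, comp.center, comp.sigma]
        lo += [0.0, comp.center - center_slack, SIGMA_FLOOR_BINS]
        hi += [np.inf, comp.center + center_slack, np.inf]
    try:
        popt, _ = curve_fit(
            model, bins, wave.amplitudes - d.bias, p0=p0, bounds=(lo, hi), maxfev=2000
        )
    except RuntimeError:  # no convergence: keep the EM solution
        return d
    masses = np.array([popt[j] * popt[j + 2] for j in range(0, len(popt), 3)])
    weights = masses / masses.sum()
    comps = [
        GaussianComponent(
            amplitude=float(popt[j]),
            center=float(popt[j + 1]),
            sigma=float(popt[j + 2]),
            weight=float(w),
        )
        for j, w in zip(range(0, len(popt), 3), weights)
    ]
    out = Decomposition(components=comps, bias=d.bias, converged=d.converged, state=d.state)
    out.fit = fit_metrics(wave.amplitudes, reconstruct_waveform(out, bins))
    return out


def refine_amplitudes(d: Decomposition, wave: Waveform) -> Decomposition:
    """Least-squares refit of component amplitudes at fixed centers/widths.

    Solves ``min_A || W - sum_m A_m G_m ||`` over the waveform bins (a linear
    problem once centers and sigmas are fixed), clipping amplitudes at a tiny
    positive floor.  Near-optimal for additive white noise, where the
    mass-based EM amplitudes carry the integrated noise of each component's
    support.  Weights are rebuilt from the refit masses; fit metrics are
    recomputed.
    """
    bins = np.arange(wave.nbins, dtype=float)
    basis = np.stack(
        [np.exp(-((bins - c.center) ** 2) / (2.0 * c.sigma**2)) for c in d.components],
        axis=1,
    )
    target = wave.amplitudes - d.bias
    amps, *_ = np.linalg.lstsq(basis, target, rcond=None)
    amps = np.maximum(amps, 1e-12)
    masses = amps * np.array([c.sigma for c in d.components])
    weights = masses / masses.sum()
    comps = [
        GaussianComponent(amplitude=float(a), center=c.center, sigma=c.sigma, weight=float(w))
        for a, c, w in zip(amps, d.components, weights)
    ]
    out = Decomposition(components=comps, bias=d.bias, converged=d.converged, state=d.state)
    out.fit = fit_metrics(wave.amplitudes, reconstruct_waveform(out, bins))
    return out


def _merge_close(
    comps: List[GaussianComponent], merge_tol: float
) -> List[GaussianComponent]:
    """Fuse runs of components whose centers lie within ``merge_tol`` bins."""
    merged: List[GaussianComponent] = []
    for comp in comps:
        if merged and comp.center - merged[-1].center < merge_tol:
            a, b = merged[-1], comp
            wsum = a.weight + b.weight
            center = (a.center * a.weight + b.center * b.weight) / wsum
            # moment-match the pooled second moment
            var = (
                a.weight * (a.sigma**2 + (a.center - center) ** 2)
                + b.weight * (b.sigma**2 + (b.center - center) ** 2)
            ) / wsum
            sigma = max(math.sqrt(var), SIGMA_FLOOR_BINS)
            mass = a.amplitude * a.sigma + b.amplitude * b.sigma
            merged[-1] = GaussianComponent(
                amplitude=mass / sigma, center=center, sigma=sigma, weight=wsum
            )
        else:
            merged.append(comp)
    return merged


def reconstruct_waveform(d: Decomposition, bins: np.ndarray) -> np.ndarray:
    """Evaluate ``bias + sum_m A_m exp(-(t - t_m)^2 / (2 sigma_m^2))``."""
    bins = np.asarray(bins, dtype=float)
    out = np.full(bins.shape, float(d.bias))
    for comp in d.components:
        out += comp.evaluate(bins)
    return out


def fit_metrics(observed: np.ndarray, fitted: np.ndarray) -> Dict[str, Optional[float]]:
    """R2 (1 - SSres/SStot), MAE, MSE, RMSE between two equal-length vectors.

    R2 is ``None`` when the observed vector is constant.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape or observed.size < 2:
        raise ValueError("observed and fitted must share length >= 2")
    resid = observed - fitted
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    rmse = math.sqrt(mse)
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return {"r2": r2, "mae": mae, "mse": mse, "rmse": rmse}
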