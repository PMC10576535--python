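"""Per-pulse reflectivity-ratio estimation and the gridded trimmed-mean field.

The canopy/ground reflectivity ratio of a pulse follows from its energy split
and the spectral cover estimate at its location:

    rho_v / rho_g = Rv(z) / (FVC * Rg) - Rv(0) / Rg

Pulses are binned onto a regular geographic grid (square cells, default
0.002 degrees); each cell's value is the mean of its pulses after a single
pass dropping values outside mean +/- 3 sample standard deviations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "RatioEstimate",
    "RatioGrid",
    "compute_ratio",
    "grid_index",
    "trim_outliers",
    "build_ratio_grid",
    "lookup_ratio",
    "grid_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_CELL_DEG = 0.002


@dataclass
class RatioEstimate:
    """One pulse's canopy/ground reflectivity ratio."""

    shotnumber: Optional[str] = None
    lon: float = float("nan")
    lat: float = float("nan")
    rho_ratio: float = float("nan")
    fvc_used: float = float("nan")
    clamped: bool = False
    valid: bool = False


@dataclass
class RatioGrid:
    """Regular geographic grid of trimmed-mean reflectivity ratios.

    Cells are half-open ``[origin + i*cell, origin + (i+1)*cell)`` on each
    axis; ``cell_mean`` is ``nrows x ncols`` with NaN marking empty cells.
    """

    origin_lon: float
    origin_lat: float
    cell_deg: float
    ncols: int
    nrows: int
    cell_mean: np.ndarray
    cell_count: np.ndarray
    global_mean: float = float("nan")

    @property
    def n_cells(self) -> int:
        return self.ncols * self.nrows


def compute_ratio(
    rv_z: float,
    rv0: float,
    rg: float,
    fvc: Optional[float],
    clamp_negative: bool = True,
) -> RatioEstimate:
    """Estimate rho_v/rho_g from the energy split and spectral cover.

    Negative raw values are clamped to 0 by default (``clamped`` flags it);
    with ``clamp_negative=False`` they are marked invalid instead.  A pulse
    with no ground energy or no usable cover value is invalid.
    """
    est = RatioEstimate(rho_ratio=float("nan"), clamped=False, valid=False)
    if fvc is None or not np.isfinite(fvc) or fvc <= 0 or rg <= 0:
        return est
    est.fvc_used = float(fvc)
    raw = rv_z / (fvc * rg) - rv0 / rg
    if raw < 0:
        if not clamp_negative:
            return est
        est.rho_ratio = 0.0
        est.clamped = True
    else:
        est.rho_ratio = float(raw)
    est.valid = True
    return est


def grid_index(lon: float, lat: float, grid: RatioGrid) -> Tuple[int, int]:
    """Cell (col, row) containing a point; half-open edges, lower/left inclusive."""
    col = math.floor((lon - grid.origin_lon) / grid.cell_deg)
    row = math.floor((lat - grid.origin_lat) / grid.cell_deg)
    if not (0 <= col < grid.ncols and 0 <= row < grid.nrows):
        raise ValueError(
            f"point ({lon}, {lat}) outside grid extent "
            f"[{grid.origin_lon}, {grid.origin_lon + grid.ncols * grid.cell_deg}) x "
            f"[{grid.origin_lat}, {grid.origin_lat + grid.nrows * grid.cell_deg})"
        )
    return int(col), int(row)


def trim_outliers(values: np.ndarray) -> np.ndarray:
    """Single-pass 3-sigma trim: drop values outside mean +/- 3 sample sd.

    Inputs with fewer than 3 values, or zero spread, pass through unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        return values
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        return values
    mean = float(values.mean())
    keep = np.abs(values - mean) <= 3.0 * sd
    return values[keep]


def _snap_extent(
    lons: np.ndarray, lats: np.ndarray, cell_deg: float
) -> Tuple[float, float, int, int]:
    """Bounding box snapped outward to the cell lattice."""
    origin_lon = math.floor(lons.min() / cell_deg) * cell_deg
    origin_lat = math.floor(lats.min() / cell_deg) * cell_deg
    ncols = int(math.floor((lons.max() - origin_lon) / cell_deg)) + 1
    nrows = int(math.floor((lats.max() - origin_lat) / cell_deg)) + 1
    return origin_lon, origin_lat, ncols, nrows


def empty_grid(
    extent: Tuple[float, float, float, float], cell_deg: float = DEFAULT_CELL_DEG
) -> RatioGrid:
    """A grid covering an explicit (lon_min, lat_min, lon_max, lat_max) extent."""
    lon_min, lat_min, lon_max, lat_max = extent
    ncols = max(1, int(math.ceil((lon_max - lon_min) / cell_deg - 1e-9)))
    nrows = max(1, int(math.ceil((lat_max - lat_min) / cell_deg - 1e-9)))
    return RatioGrid(
        origin_lon=lon_min,
        origin_lat=lat_min,
        cell_deg=cell_deg,
        ncols=ncols,
        nrows=nrows,
        cell_mean=np.full((nrows, ncols), np.nan),
        cell_count=np.zeros((nrows, ncols), dtype=int),
    )


def build_ratio_grid(
    estimates: Sequence[RatioEstimate],
    extent: Optional[Tuple[float, float, float, float]] = None,
    cell_deg: float = DEFAULT_CELL_DEG,
) -> RatioGrid:
    """Grid the valid ratio estimates and take each cell's trimmed mean.

    The extent defaults to the data bounding box snapped outward to the cell
    lattice.  Cells without valid pulses stay NaN; the grid also records the
    global trimmed mean of all valid ratios as its empty-cell fallback.
    """
    valid = [e for e in estimates if e.valid and np.isfinite(e.lon) and np.isfinite(e.lat)]
    if not valid:
        raise ValueError("no valid ratio estimates to grid")
    lons = np.array([e.lon for e in valid])
    lats = np.array([e.lat for e in valid])
    ratios = np.array([e.rho_ratio for e in valid])
    if extent is None:
        origin_lon, origin_lat, ncols, nrows = _snap_extent(lons, lats, cell_deg)
        grid = RatioGrid(
            origin_lon=origin_lon,
            origin_lat=origin_lat,
            cell_deg=cell_deg,
            ncols=ncols,
            nrows=nrows,
            cell_mean=np.full((nrows, ncols), np.nan),
            cell_count=np.zeros((nrows, ncols), dtype=int),
        )
    else:
        grid = empty_grid(extent, cell_deg)

    cols = np.floor((lons - grid.origin_lon) / grid.cell_deg).astype(int)
    rows = np.floor((lats - grid.origin_lat) / grid.cell_deg).astype(int)
    inside = (cols >= 0) & (cols < grid.ncols) & (rows >= 0) & (rows < grid.nrows)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d pulses fall outside the grid extent; skipped", n_out)
    cell_values: Dict[int, List[float]] = {}
    flat = rows[inside] * grid.ncols + cols[inside]
    for f, r in zip(flat, ratios[inside]):
        cell_values.setdefault(int(f), []).append(float(r))
    for f, vals in cell_values.items():
        trimmed = trim_outliers(np.asarray(vals))
        grid.cell_mean.flat[f] = trimmed.mean()
        grid.cell_count.flat[f] = len(vals)
    grid.global_mean = float(trim_outliers(ratios).mean())
    return grid


def lookup_ratio(grid: RatioGrid, lon: float, lat: float) -> Tuple[float, str]:
    """Ratio for a point: its cell's trimmed mean, or the global fallback.

    Returns ``(ratio, source)`` where source is ``"grid"`` or
    ``"global_fallback"``.  Out-of-extent points raise.
    """
    col, row = grid_index(lon, lat, grid)
    value = grid.cell_mean[row, col]
    if np.isnan(value):
        logger.warning(
            "cell (%d, %d) has no pulses; falling back to global mean %.4f",
            col,
            row,
            grid.global_mean,
        )
        return float(grid.global_mean), "global_fallback"
    return float(value), "grid"


def grid_summary(grid: RatioGrid) -> Dict[str, float]:
    """Summary statistics of the occupied cells (max/min/mean/sd over cells)."""
    occupied = grid.cell_mean[~np.isnan(grid.cell_mean)]
    out = {
        "n_cells": int(grid.n_cells),
        "n_occupied": int(occupied.size),
        "ncols": int(grid.ncols),
        "nrows": int(grid.nrows),
        "cell_deg": float(grid.cell_deg),
    }
    if occupied.size:
        out.update(
            max=float(occupied.max()),
            min=float(occupied.min()),
            mean=float(occupied.mean()),
            sd=float(occupied.std(ddof=1)) if occupied.size > 1 else 0.0,
        )
    return out
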