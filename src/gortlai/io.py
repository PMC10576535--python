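"""Readers and writers for the CSV dialects, plus GeoTIFF point sampling.

Pulse CSV: header ``shotnumber,lon,lat,zt,zg,sigmean,rxwave[,fvc,ndvi]`` with
``rxwave`` a single quoted field of semicolon-separated amplitudes.
Components, energy, ratio, grid and LAI tables are flat CSVs; reports are
JSON.  GeoTIFFs are handled with tifffile via the ModelPixelScale /
ModelTiepoint tags (north-up rasters in WGS84).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .decomposition import Decomposition, GaussianComponent
from .lai_model import LAIResult
from .ratio_fusion import RatioEstimate, RatioGrid
from .waveform_prep import DEFAULT_BIN_DZ, PulseRecord, PulseValidationError

__all__ = [
    "PulseCSVError",
    "read_pulse_csv",
    "write_pulse_csv",
    "write_components_csv",
    "read_components_csv",
    "write_energy_csv",
    "read_energy_csv",
    "write_ratios_csv",
    "read_ratios_csv",
    "write_grid_csv",
    "read_grid_csv",
    "write_lai_csv",
    "write_report_json",
    "sample_raster_at",
    "write_geotiff",
]

logger = logging.getLogger(__name__)

PULSE_COLUMNS = ["shotnumber", "lon", "lat", "zt", "zg", "sigmean", "rxwave"]


class PulseCSVError(ValueError):
    """Malformed pulse CSV; message carries the offending row numbers."""


def _parse_optional(value: Optional[str]) -> Optional[float]:
    if value is None or value == "":
        return None
    return float(value)


def read_pulse_csv(
    path, bin_dz: float = DEFAULT_BIN_DZ, strict: bool = True
) -> List[PulseRecord]:
    """Read a pulse table; malformed rows raise (strict) or are skipped.

    Errors are reported with 1-based data row numbers.
    """
    records: List[PulseRecord] = []
    errors: List[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in PULSE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise PulseCSVError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                wave_field = row["rxwave"]
                if wave_field is None or wave_field == "":
                    raise ValueError("empty rxwave")
                rxwave = np.array(
                    [float(v) for v in wave_field.split(";")], dtype=float
                )
                rec = PulseRecord(
                    shotnumber=row["shotnumber"],
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    zt=float(row["zt"]),
                    zg=float(row["zg"]),
                    sigmean=float(row["sigmean"]),
                    rxwave=rxwave,
                    bin_dz=bin_dz,
                    fvc=_parse_optional(row.get("fvc")),
                    ndvi=_parse_optional(row.get("ndvi")),
                )
                rec.validate()
                records.append(rec)
            except (ValueError, KeyError, PulseValidationError) as exc:
                errors.append(f"row {i}: {exc}")
    if errors:
        if strict:
            raise PulseCSVError(f"{path}: " + "; ".join(errors))
        for msg in errors:
            logger.warning("%s: skipped %s", path, msg)
    return records


def write_pulse_csv(records: Sequence[PulseRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(PULSE_COLUMNS + ["fvc", "ndvi"])
        for r in records:
            writer.writerow(
                [
                    r.shotnumber,
                    repr(float(r.lon)),
                    repr(float(r.lat)),
                    repr(float(r.zt)),
                    repr(float(r.zg)),
                    repr(float(r.sigmean)),
                    ";".join(repr(float(a)) for a in r.rxwave),
                    "" if r.fvc is None else repr(float(r.fvc)),
                    "" if r.ndvi is None else repr(float(r.ndvi)),
                ]
            )


COMPONENT_COLUMNS = [
    "shotnumber",
    "component_index",
    "amplitude",
    "center_bin",
    "center_elev_m",
    "sigma_bins",
    "weight",
    "r2",
    "rmse",
    "converged",
    "zt",
    "bin_dz",
    "nbins",
]


def write_components_csv(
    rows: Sequence[Dict[str, object]], path
) -> None:
    """Write per-component rows (one row per fitted Gaussian)."""
    pd.DataFrame(rows, columns=COMPONENT_COLUMNS).to_csv(path, index=False)


def components_rows(
    shotnumber: str, d: Decomposition, zt: float, bin_dz: float, nbins: int
) -> List[Dict[str, object]]:
    """Flatten one decomposition into component CSV rows."""
    return [
        {
            "shotnumber": shotnumber,
            "component_index": i,
            "amplitude": c.amplitude,
            "center_bin": c.center,
            "center_elev_m": zt - c.center * bin_dz,
            "sigma_bins": c.sigma,
            "weight": c.weight,
            "r2": d.fit.get("r2"),
            "rmse": d.fit.get("rmse"),
            "converged": d.converged,
            "zt": zt,
            "bin_dz": bin_dz,
            "nbins": nbins,
        }
        for i, c in enumerate(d.components)
    ]


def read_components_csv(path) -> Dict[str, Dict[str, object]]:
    """Read components back, grouped by shot.

    Returns ``{shot: {"decomposition": Decomposition, "zt": ..., "bin_dz": ...,
    "nbins": ...}}``.
    """
    df = pd.read_csv(path, dtype={"shotnumber": str})
    out: Dict[str, Dict[str, object]] = {}
    for shot, grp in df.groupby("shotnumber", sort=False):
        grp = grp.sort_values("component_index")
        comps = [
            GaussianComponent(
                amplitude=float(r.amplitude),
                center=float(r.center_bin),
                sigma=float(r.sigma_bins),
                weight=float(r.weight),
            )
            for r in grp.itertuples()
        ]
        first = grp.iloc[0]
        d = Decomposition(
            components=comps,
            converged=bool(first.converged),
            fit={"r2": float(first.r2), "rmse": float(first.rmse)},
        )
        out[str(shot)] = {
            "decomposition": d,
            "zt": float(first.zt),
            "bin_dz": float(first.bin_dz),
            "nbins": int(first.nbins),
        }
    return out


ENERGY_COLUMNS = ["shotnumber", "Rg", "Rv0", "z80_m", "ground_index", "n_canopy"]


def write_energy_csv(rows: Sequence[Dict[str, object]], path) -> None:
    pd.DataFrame(rows, columns=ENERGY_COLUMNS).to_csv(path, index=False)


def read_energy_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"shotnumber": str})


def write_ratios_csv(estimates: Sequence[RatioEstimate], path) -> None:
    rows = [
        {
            "shotnumber": e.shotnumber,
            "lon": e.lon,
            "lat": e.lat,
            "rho_ratio": e.rho_ratio,
            "clamped": e.clamped,
            "valid": e.valid,
        }
        for e in estimates
    ]
    pd.DataFrame(
        rows, columns=["shotnumber", "lon", "lat", "rho_ratio", "clamped", "valid"]
    ).to_csv(path, index=False)


def read_ratios_csv(path) -> List[RatioEstimate]:
    df = pd.read_csv(path, dtype={"shotnumber": str})
    return [
        RatioEstimate(
            shotnumber=str(r.shotnumber),
            lon=float(r.lon),
            lat=float(r.lat),
            rho_ratio=float(r.rho_ratio),
            clamped=bool(r.clamped),
            valid=bool(r.valid),
        )
        for r in df.itertuples()
    ]


def write_grid_csv(grid: RatioGrid, path) -> None:
    """One row per occupied cell: col,row,lon_min,lat_min,mean_ratio,n.

    A leading metadata row (col=-1) stores origin, cell size, shape and the
    global fallback mean so the grid round-trips exactly.
    """
    rows = [
        {
            "col": -1,
            "row": -1,
            "lon_min": grid.origin_lon,
            "lat_min": grid.origin_lat,
            "mean_ratio": grid.global_mean,
            "n": grid.ncols * 100000 + grid.nrows,  # packed shape
            "cell_deg": grid.cell_deg,
        }
    ]
    for row in range(grid.nrows):
        for col in range(grid.ncols):
            if not np.isnan(grid.cell_mean[row, col]):
                rows.append(
                    {
                        "col": col,
                        "row": row,
                        "lon_min": grid.origin_lon + col * grid.cell_deg,
                        "lat_min": grid.origin_lat + row * grid.cell_deg,
                        "mean_ratio": grid.cell_mean[row, col],
                        "n": int(grid.cell_count[row, col]),
                        "cell_deg": grid.cell_deg,
                    }
                )
    pd.DataFrame(
        rows, columns=["col", "row", "lon_min", "lat_min", "mean_ratio", "n", "cell_deg"]
    ).to_csv(path, index=False)


def read_grid_csv(path) -> RatioGrid:
    df = pd.read_csv(path)
    meta = df[df.col == -1].iloc[0]
    ncols, nrows = int(meta.n) // 100000, int(meta.n) % 100000
    grid = RatioGrid(
        origin_lon=float(meta.lon_min),
        origin_lat=float(meta.lat_min),
        cell_deg=float(meta.cell_deg),
        ncols=ncols,
        nrows=nrows,
        cell_mean=np.full((nrows, ncols), np.nan),
        cell_count=np.zeros((nrows, ncols), dtype=int),
        global_mean=float(meta.mean_ratio),
    )
    for r in df[df.col >= 0].itertuples():
        grid.cell_mean[int(r.row), int(r.col)] = float(r.mean_ratio)
        grid.cell_count[int(r.row), int(r.col)] = int(r.n)
    return grid


LAI_COLUMNS = ["shotnumber", "lon", "lat", "lai", "fcover_bottom", "ratio_used", "ratio_source"]


def write_lai_csv(results: Sequence[LAIResult], path) -> None:
    rows = [
        {
            "shotnumber": r.shotnumber,
            "lon": r.lon,
            "lat": r.lat,
            "lai": r.lai,
            "fcover_bottom": r.fcover_bottom,
            "ratio_used": r.ratio_used,
            "ratio_source": r.ratio_source,
        }
        for r in results
        if r.valid
    ]
    pd.DataFrame(rows, columns=LAI_COLUMNS).to_csv(path, index=False)


def read_lai_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"shotnumber": str})


def write_report_json(report: object, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# GeoTIFF handling (north-up WGS84 rasters)

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


def _read_geo(tif: tifffile.TiffFile) -> Tuple[float, float, float, float, Optional[float]]:
    page = tif.pages[0]
    tags = page.tags
    try:
        sx, sy, _ = tags[_MODEL_PIXEL_SCALE].value
        tp = tags[_MODEL_TIEPOINT].value
    except KeyError as exc:
        raise ValueError("raster lacks GeoTIFF georeferencing tags") from exc
    # tiepoint maps raster (i, j) to model (x, y); standard case is (0, 0)
    ox = tp[3] - tp[0] * sx
    oy = tp[4] + tp[1] * sy
    nodata = None
    if _GDAL_NODATA in tags:
        try:
            nodata = float(tags[_GDAL_NODATA].value)
        except (TypeError, ValueError):
            nodata = None
    return ox, oy, sx, sy, nodata


def sample_raster_at(raster_path, lon: float, lat: float) -> Optional[float]:
    """Nearest-neighbor sample of a north-up WGS84 GeoTIFF at a point.

    Returns ``None`` (with a warning) for out-of-raster points or nodata.
    """
    with tifffile.TiffFile(raster_path) as tif:
        ox, oy, sx, sy, nodata = _read_geo(tif)
        data = tif.asarray()
    col = int(math.floor((lon - ox) / sx))
    row = int(math.floor((oy - lat) / sy))
    if not (0 <= row < data.shape[0] and 0 <= col < data.shape[1]):
        logger.warning("point (%s, %s) outside raster %s", lon, lat, raster_path)
        return None
    value = float(data[row, col])
    if nodata is not None and value == nodata:
        return None
    return value


def write_geotiff(
    path,
    data: np.ndarray,
    origin_lon: float,
    origin_lat_top: float,
    cell_deg: float,
    nodata: Optional[float] = None,
) -> None:
    """Write a single-band north-up WGS84 GeoTIFF (row 0 = northernmost)."""
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cell_deg, cell_deg, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, origin_lon, origin_lat_top, 0.0)),
    ]
    if nodata is not None:
        extratags.append((_GDAL_NODATA, "s", 0, str(nodata)))
    tifffile.imwrite(path, data.astype(np.float32), extratags=extratags)
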