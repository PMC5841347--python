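"""Environmental surfaces: saturation vapour pressure, VPD, averaging, regridding.

Vapour pressure deficit (VPD, kPa) is the saturated vapour pressure at the
daily maximum temperature minus the actual vapour pressure in the
afternoon — the drying capacity of the air.  Leaf area index (LAI,
dimensionless) proxies canopy shade.  Daily fields are reduced to long-term
means and aggregated to the coarse analysis grid by area weighting.

Rasters travel as 2-D arrays with NaN as the missing-value marker, indexed
``[iy, ix]`` with row 0 at the *bottom* (matching grid cell ids); ESRI ASCII
I/O flips rows accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import GridSpec

logger = logging.getLogger(__name__)

# Saturation vapour pressure constants (Jones 1992 empirical fit), kPa / degC
ESAT_A = 0.61375
ESAT_B = 17.502
ESAT_C = 240.97

UNITS = {"tmax": "degC", "vp": "kPa", "vpd": "kPa", "lai": "1"}


@dataclass(frozen=True)
class RasterGeom:
    """Geometry of a rectangular raster: lower-left corner, square cells."""

    x0: float
    y0: float
    cell_size: float
    nx: int
    ny: int

    @classmethod
    def from_grid(cls, grid: GridSpec) -> "RasterGeom":
        return cls(grid.origin[0], grid.origin[1], grid.cell_size, grid.nx, grid.ny)

    def x_edges(self) -> np.ndarray:
        return self.x0 + self.cell_size * np.arange(self.nx + 1)

    def y_edges(self) -> np.ndarray:
        return self.y0 + self.cell_size * np.arange(self.ny + 1)


@dataclass
class EnvironmentalSurface:
    variable: str
    values: np.ndarray  # (ny, nx), NaN = missing
    geom: RasterGeom
    period: str = ""

    @property
    def units(self) -> str:
        return UNITS.get(self.variable, "")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geom.ny, self.geom.nx):
            raise ValueError("raster shape does not match geometry")


def esat(t_celsius):
    """Saturation vapour pressure (kPa) at air temperature T (degC).

    esat(T) = 0.61375 * exp(17.502 T / (240.97 + T)).
    """
    t = np.asarray(t_celsius, dtype=float)
    if np.any(t <= -ESAT_C):
        raise ValueError(f"temperature at or below the formula pole (-{ESAT_C} degC)")
    out = ESAT_A * np.exp(ESAT_B * t / (ESAT_C + t))
    return float(out) if out.ndim == 0 else out


def vpd(tmax, vp):
    """Vapour pressure deficit: esat(tmax) - vp, clamped at zero (kPa).

    Supersaturated inputs (vp above esat) clamp to 0 with a counted warning;
    negative vapour pressure is a validation error.
    """
    vp_arr = np.asarray(vp, dtype=float)
    if np.any(vp_arr < 0):
        raise ValueError("negative vapour pressure")
    raw = esat(tmax) - vp_arr
    n_super = int(np.count_nonzero(raw < 0))
    if n_super:
        logger.warning("vpd: %d supersaturated value(s) clamped to 0", n_super)
    out = np.maximum(raw, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def temporal_average(daily_values, geom: RasterGeom | None = None,
                     period: str = "") -> np.ndarray | EnvironmentalSurface:
    """Per-cell arithmetic mean over non-missing days.

    ``daily_values`` is a sequence of same-shape 2-D arrays (or a 3-D array
    with time on axis 0).  Cells missing on every day stay missing.
    """
    stack = np.asarray(daily_values, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a stack of 2-D daily rasters")
    shapes = {a.shape for a in stack}
    if len(shapes) > 1:  # pragma: no cover - ragged input is caught by asarray
        raise ValueError("daily rasters differ in shape")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    if geom is None:
        return mean
    return EnvironmentalSurface("vpd", mean, geom, period)


def daily_vpd_average(tmax_days, vp_days, order: str = "daily_first") -> np.ndarray:
    """Long-term mean VPD from stacks of daily Tmax and VP rasters.

    ``order='daily_first'`` (default) computes VPD for each day and averages
    the daily deficits; ``order='average_first'`` averages Tmax and VP over
    time and computes one deficit from the means (sensitivity alternative —
    the two differ because esat is convex in temperature).
    """
    tmax_days = np.asarray(tmax_days, dtype=float)
    vp_days = np.asarray(vp_days, dtype=float)
    if tmax_days.shape != vp_days.shape:
        raise ValueError("tmax and vp stacks differ in shape")
    if order == "daily_first":
        daily = np.stack([vpd(t, v) for t, v in zip(tmax_days, vp_days)])
        return temporal_average(daily)
    if order == "average_first":
        return vpd(temporal_average(tmax_days), temporal_average(vp_days))
    raise ValueError(f"unknown order {order!r}")


def aggregate_to_grid(fine_values: np.ndarray, fine_geom: RasterGeom,
                      grid: GridSpec) -> np.ndarray:
    """Area-weighted mean of a fine raster over each coarse grid cell.

    Overlap areas are exact rectangle intersections, so nested fine cells
    get equal weights automatically.  Missing fine cells are excluded from
    the weight sum; a coarse cell with zero covered area is missing (NaN).
    """
    fine = np.asarray(fine_values, dtype=float)
    if fine.shape != (fine_geom.ny, fine_geom.nx):
        raise ValueError("fine raster shape does not match its geometry")
    fx = fine_geom.x_edges()
    fy = fine_geom.y_edges()
    out = np.full((grid.ny, grid.nx), np.nan)
    gx0, gy0 = grid.origin
    cs = grid.cell_size
    for iy in range(grid.ny):
        cy0, cy1 = gy0 + iy * cs, gy0 + (iy + 1) * cs
        j0 = max(np.searchsorted(fy, cy0, side="right") - 1, 0)
        j1 = min(np.searchsorted(fy, cy1, side="left"), fine_geom.ny)
        if j1 <= j0:
            continue
        oy = np.minimum(fy[j0 + 1 : j1 + 1], cy1) - np.maximum(fy[j0:j1], cy0)
        for ix in range(grid.nx):
            cx0, cx1 = gx0 + ix * cs, gx0 + (ix + 1) * cs
            i0 = max(np.searchsorted(fx, cx0, side="right") - 1, 0)
            i1 = min(np.searchsorted(fx, cx1, side="left"), fine_geom.nx)
            if i1 <= i0:
                continue
            ox = np.minimum(fx[i0 + 1 : i1 + 1], cx1) - np.maximum(fx[i0:i1], cx0)
            w = np.outer(oy, ox)
            block = fine[j0:j1, i0:i1]
            ok = ~np.isnan(block)
            wsum = w[ok].sum()
            if wsum > 0:
                out[iy, ix] = float((w[ok] * block[ok]).sum() / wsum)
    return out


def write_ascii_grid(path, values: np.ndarray, geom: RasterGeom,
                     nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid (.asc)."""
    vals = np.asarray(values, dtype=float)
    if vals.shape != (geom.ny, geom.nx):
        raise ValueError("raster shape does not match geometry")
    body = np.where(np.isnan(vals), nodata, vals)[::-1]  # top row first
    header = (
        f"ncols {geom.nx}\n"
        f"nrows {geom.ny}\n"
        f"xllcorner {geom.x0!r}\n"
        f"yllcorner {geom.y0!r}\n"
        f"cellsize {geom.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid -> (values, RasterGeom), NaN for NODATA."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
            pos = fh.tell()
        fh.seek(pos)
        body = np.loadtxt(fh)
    nx, ny = int(header["ncols"]), int(header["nrows"])
    body = np.atleast_2d(body)[::-1]  # back to bottom-row-first
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(body == nodata, np.nan, body)
    geom = RasterGeom(header["xllcorner"], header["yllcorner"],
                      header["cellsize"], nx, ny)
    return values, geom
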