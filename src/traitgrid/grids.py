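"""Equal-area analysis grids and the Albers equal-area conic projection.

Assemblages are built on a square grid in a projected plane so that every
cell covers the same ground area.  The default projection is the standard
Australian Albers parameter set (central meridian 132 degrees E, standard
parallels -18 and -36, latitude of origin 0, GRS80 ellipsoid), but every
parameter is configurable.

Cells are half-open squares ``[x, x + cell_size) x [y, y + cell_size)`` with
integer ids ``(ix, iy)`` counted from the lower-left grid origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel cell id for points outside the grid extent.
OFF_GRID = (-1, -1)


class ProjectionError(ValueError):
    """Raised when a coordinate cannot be projected (degenerate cone)."""


@dataclass(frozen=True)
class AlbersParams:
    """Parameters of an Albers equal-area conic projection on an ellipsoid.

    Defaults are the standard Australian Albers configuration.
    """

    central_meridian: float = 132.0
    standard_parallel_1: float = -18.0
    standard_parallel_2: float = -36.0
    latitude_of_origin: float = 0.0
    false_easting: float = 0.0
    false_northing: float = 0.0
    semi_major_axis: float = 6378137.0  # GRS80
    inverse_flattening: float = 298.257222101

    @property
    def eccentricity(self) -> float:
        f = 1.0 / self.inverse_flattening
        return float(np.sqrt(2.0 * f - f * f))


def _q(sin_phi: np.ndarray, e: float) -> np.ndarray:
    """Authalic q function (Snyder 3-12)."""
    es = e * sin_phi
    return (1.0 - e**2) * (
        sin_phi / (1.0 - es**2) - (1.0 / (2.0 * e)) * np.log((1.0 - es) / (1.0 + es))
    )


def _cone_constants(p: AlbersParams):
    e = p.eccentricity
    phi1 = np.radians(p.standard_parallel_1)
    phi2 = np.radians(p.standard_parallel_2)
    phi0 = np.radians(p.latitude_of_origin)
    m1 = np.cos(phi1) / np.sqrt(1.0 - (e * np.sin(phi1)) ** 2)
    m2 = np.cos(phi2) / np.sqrt(1.0 - (e * np.sin(phi2)) ** 2)
    q1 = _q(np.sin(phi1), e)
    q2 = _q(np.sin(phi2), e)
    if np.isclose(phi1, phi2):
        n = np.sin(phi1)
    else:
        n = (m1**2 - m2**2) / (q2 - q1)
    if n == 0.0:
        raise ProjectionError(
            "degenerate cone: standard parallels symmetric about the equator"
        )
    C = m1**2 + n * q1
    rho0 = p.semi_major_axis * np.sqrt(C - n * _q(np.sin(phi0), e)) / n
    return e, n, C, rho0


def project_lonlat(lon, lat, params: AlbersParams = AlbersParams()):
    """Forward Albers equal-area conic transform, degrees -> metres.

    Accepts scalars or arrays.  Raises :class:`ProjectionError` when the
    cone radical ``C - n q`` goes negative (latitude beyond the projectable
    domain of the chosen cone).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    e, n, C, rho0 = _cone_constants(params)
    a = params.semi_major_axis
    q = _q(np.sin(np.radians(lat)), e)
    radical = C - n * q
    if np.any(radical < 0):
        raise ProjectionError("latitude outside the projectable domain of the cone")
    rho = a * np.sqrt(radical) / n
    theta = n * np.radians(lon - params.central_meridian)
    x = rho * np.sin(theta) + params.false_easting
    y = rho0 - rho * np.cos(theta) + params.false_northing
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def inverse_project(x, y, params: AlbersParams = AlbersParams(), tol: float = 1e-12):
    """Inverse Albers transform, metres -> degrees (iterative latitude)."""
    x = np.asarray(x, dtype=float) - params.false_easting
    y = np.asarray(y, dtype=float) - params.false_northing
    e, n, C, rho0 = _cone_constants(params)
    a = params.semi_major_axis
    sgn = np.sign(n)
    rho = sgn * np.hypot(x, rho0 - y)
    theta = np.arctan2(sgn * x, sgn * (rho0 - y))
    q = (C - (rho * n / a) ** 2) / n
    # iterate Snyder 3-16 for latitude
    phi = np.arcsin(np.clip(q / 2.0, -1.0, 1.0))
    for _ in range(50):
        s = np.sin(phi)
        es = e * s
        delta = ((1.0 - es**2) ** 2 / (2.0 * np.cos(phi))) * (
            q / (1.0 - e**2)
            - s / (1.0 - es**2)
            + (1.0 / (2.0 * e)) * np.log((1.0 - es) / (1.0 + es))
        )
        phi = phi + delta
        if np.all(np.abs(delta) < tol):
            break
    lon = params.central_meridian + np.degrees(theta / n)
    lat = np.degrees(phi)
    if lon.ndim == 0:
        return float(lon), float(lat)
    return lon, lat


@dataclass(frozen=True)
class GridSpec:
    """A square analysis grid in the projected plane.

    ``origin`` is the lower-left corner of cell (0, 0); ``extent`` is the
    number of cells along x and y.
    """

    cell_size: float = 100_000.0
    origin: tuple[float, float] = (-1_500_000.0, -4_500_000.0)
    extent: tuple[int, int] = (30, 30)
    projection: AlbersParams = field(default_factory=AlbersParams)

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.extent[0] < 1 or self.extent[1] < 1:
            raise ValueError("grid extent must be at least 1x1")

    @property
    def nx(self) -> int:
        return self.extent[0]

    @property
    def ny(self) -> int:
        return self.extent[1]

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def centroid(self, ix, iy):
        """Centre of cell (ix, iy) in projected metres."""
        x0, y0 = self.origin
        cx = x0 + (np.asarray(ix) + 0.5) * self.cell_size
        cy = y0 + (np.asarray(iy) + 0.5) * self.cell_size
        return cx, cy

    def all_centroids(self) -> np.ndarray:
        """(n_cells, 2) centroid array in row-major (iy, ix) order."""
        ix, iy = np.meshgrid(np.arange(self.nx), np.arange(self.ny))
        cx, cy = self.centroid(ix.ravel(), iy.ravel())
        return np.column_stack([cx, cy])

    def cell_index(self, ix, iy):
        """Flat row-major index of a cell, consistent with all_centroids."""
        return np.asarray(iy) * self.nx + np.asarray(ix)


def assign_cell(x, y, grid: GridSpec):
    """Map projected points to half-open grid cells.

    Scalars return a ``(ix, iy)`` tuple or :data:`OFF_GRID`; arrays return
    integer arrays with -1 marking off-grid points (counted and logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x0, y0 = grid.origin
    ix = np.floor((x - x0) / grid.cell_size).astype(int)
    iy = np.floor((y - y0) / grid.cell_size).astype(int)
    inside = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    n_off = int(np.size(inside) - np.count_nonzero(inside))
    if n_off:
        logger.info("assign_cell: %d point(s) outside the grid extent", n_off)
    if x.ndim == 0:
        return (int(ix), int(iy)) if bool(inside) else OFF_GRID
    ix = np.where(inside, ix, -1)
    iy = np.where(inside, iy, -1)
    return ix, iy
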