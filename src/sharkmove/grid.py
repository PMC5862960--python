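"""Bathymetry grids: container, interpolation, and plain-text raster I/O.

Depth convention throughout the package: positive values are water depth in
meters below sea level; negative values are land elevation. A point is "at
sea" when its depth is > 0.

Grids are stored row 0 = southernmost row, with ``origin`` the cell *center*
of the south-west cell. On disk they round-trip through ESRI ASCII grid
(a single-band text raster with a nodata tag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class BathymetryGrid:
    """Regular lat/lon depth raster.

    Parameters
    ----------
    origin:
        (lat, lon) of the south-west cell center, degrees.
    cell_deg:
        Cell size in degrees (square cells).
    depth:
        2D array, shape (n_rows, n_cols); row index increases northward.
        Positive = water depth (m), negative = land elevation (m).
    nodata:
        Sentinel stored as NaN internally.
    """

    origin: tuple[float, float]
    cell_deg: float
    depth: np.ndarray = field(repr=False)
    nodata: float = -99999.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.cell_deg <= 0:
            raise ValueError("cell_deg must be positive")
        if self.depth.ndim != 2:
            raise ValueError("depth must be a 2D matrix")

    @property
    def n_rows(self) -> int:
        return self.depth.shape[0]

    @property
    def n_cols(self) -> int:
        return self.depth.shape[1]

    @property
    def lat_centers(self) -> np.ndarray:
        return self.origin[0] + self.cell_deg * np.arange(self.n_rows)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.origin[1] + self.cell_deg * np.arange(self.n_cols)

    def covers(self, lat, lon) -> np.ndarray:
        """True where (lat, lon) lies within the cell-center bounding box."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (
            (lat >= self.origin[0])
            & (lat <= self.origin[0] + self.cell_deg * (self.n_rows - 1))
            & (lon >= self.origin[1])
            & (lon <= self.origin[1] + self.cell_deg * (self.n_cols - 1))
        )


def depth_at(grid: BathymetryGrid, lat, lon):
    """Seafloor depth (m) under (lat, lon) by bilinear interpolation.

    Queries exactly on a cell center return that cell's value. Out-of-bounds
    queries raise; a NaN (nodata) corner falls back to the nearest valid cell
    with a warning.

    Note this is the depth of the water column under a surface position,
    never an animal's swimming depth.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    scalar = lat.ndim == 0 and lon.ndim == 0
    lat, lon = np.atleast_1d(lat), np.atleast_1d(lon)
    if not np.all(grid.covers(lat, lon)):
        raise ValueError("query position outside grid bounds")

    fi = (lat - grid.origin[0]) / grid.cell_deg
    fj = (lon - grid.origin[1]) / grid.cell_deg
    # snap to cell centers so exact-center queries return the cell value
    fi = np.where(np.abs(fi - np.round(fi)) < 1e-9, np.round(fi), fi)
    fj = np.where(np.abs(fj - np.round(fj)) < 1e-9, np.round(fj), fj)
    i0 = np.clip(np.floor(fi).astype(int), 0, grid.n_rows - 2)
    j0 = np.clip(np.floor(fj).astype(int), 0, grid.n_cols - 2)
    di = fi - i0
    dj = fj - j0

    z00 = grid.depth[i0, j0]
    z01 = grid.depth[i0, j0 + 1]
    z10 = grid.depth[i0 + 1, j0]
    z11 = grid.depth[i0 + 1, j0 + 1]
    out = (
        z00 * (1 - di) * (1 - dj)
        + z01 * (1 - di) * dj
        + z10 * di * (1 - dj)
        + z11 * di * dj
    )

    bad = ~np.isfinite(out)
    if np.any(bad):
        warnings.warn("nodata cell adjacent to query; using nearest valid cell", stacklevel=2)
        valid = np.argwhere(np.isfinite(grid.depth))
        vlat = grid.origin[0] + grid.cell_deg * valid[:, 0]
        vlon = grid.origin[1] + grid.cell_deg * valid[:, 1]
        for k in np.flatnonzero(bad):
            d2 = (vlat - lat[k]) ** 2 + (vlon - lon[k]) ** 2
            r, c = valid[np.argmin(d2)]
            out[k] = grid.depth[r, c]
    return out[0] if scalar else out


def multi_resolution_depth(grids: list[BathymetryGrid], lat, lon):
    """Depth from the first grid in ``grids`` that covers each position.

    Pass grids fine-to-coarse (e.g. a high-resolution coastal matrix first,
    an offshore low-resolution matrix second): the fine grid is preferred
    wherever it covers. Raises if a position is covered by no grid.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    scalar = lat.ndim == 0 and lon.ndim == 0
    lat, lon = np.atleast_1d(lat), np.atleast_1d(lon)
    out = np.full(lat.shape, np.nan)
    remaining = np.ones(lat.shape, dtype=bool)
    for g in grids:
        hit = remaining & g.covers(lat, lon)
        if np.any(hit):
            out[hit] = depth_at(g, lat[hit], lon[hit])
            remaining &= ~hit
    if np.any(remaining):
        raise ValueError("position covered by no supplied grid")
    return out[0] if scalar else out


def land_polygon(grid: BathymetryGrid):
    """Union of land cells (depth <= 0) as a shapely (multi)polygon.

    Cells are represented as squares in an equirectangular meter frame
    centered on the grid (the same frame used for home-range analysis
    helpers); use :func:`land_polygon_lonlat` for degree coordinates.
    """
    from shapely import box, union_all

    half = grid.cell_deg / 2.0
    rows, cols = np.nonzero(grid.depth <= 0)
    lats = grid.origin[0] + grid.cell_deg * rows
    lons = grid.origin[1] + grid.cell_deg * cols
    boxes = box(lons - half, lats - half, lons + half, lats + half)
    return union_all(boxes)


def write_ascii_grid(grid: BathymetryGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc). Rows written north-to-south."""
    path = Path(path)
    d = np.where(np.isfinite(grid.depth), grid.depth, grid.nodata)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcenter {grid.origin[1]:.10f}\n")
        fh.write(f"yllcenter {grid.origin[0]:.10f}\n")
        fh.write(f"cellsize {grid.cell_deg:.10f}\n")
        fh.write(f"nodata_value {grid.nodata}\n")
        np.savetxt(fh, d[::-1], fmt="%.3f")


def read_ascii_grid(path: str | Path) -> BathymetryGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    nodata = header.get("nodata_value", -99999.0)
    data = np.where(data == nodata, np.nan, data)
    return BathymetryGrid(
        origin=(header["yllcenter"], header["xllcenter"]),
        cell_deg=header["cellsize"],
        depth=data,
        nodata=nodata,
    )
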