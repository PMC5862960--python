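"""Synthetic oceanic-island seascapes.

Oceanic high islands sit on an insular shelf that slopes gently from the
shore out to a shelf break at 100-200 m depth, then drops steeply into
abyssal water (>1000 m). The generator reproduces that radial profile per
island; the seafloor at any point is governed by the nearest island.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sharkmove.geo import haversine_km
from sharkmove.grid import BathymetryGrid

SHELF_BREAK_DEPTH_M = 200.0


@dataclass
class Island:
    """Radially symmetric island: land core, shelf ramp, steep slope.

    Parameters
    ----------
    center:
        (lat, lon) of the island summit.
    land_radius_km:
        Radius of the emergent (land) core.
    shelf_width_km:
        Width of the insular shelf: depth ramps 0 -> 200 m over this
        distance beyond the coastline.
    peak_elevation_m:
        Land elevation at the center (stored negative in the grid).
    slope_m_per_km:
        Descent rate beyond the shelf break (steep; carries the floor past
        1000 m within a few km).
    """

    center: tuple[float, float]
    land_radius_km: float = 8.0
    shelf_width_km: float = 15.0
    peak_elevation_m: float = 1000.0
    slope_m_per_km: float = 200.0

    def profile_depth_m(self, dist_km):
        """Depth (m, negative = land) at a great-circle distance from center."""
        d = np.asarray(dist_km, dtype=float)
        coast = self.land_radius_km
        brk = coast + self.shelf_width_km
        land = -self.peak_elevation_m * (1.0 - d / coast)
        shelf = SHELF_BREAK_DEPTH_M * (d - coast) / self.shelf_width_km
        slope = SHELF_BREAK_DEPTH_M + self.slope_m_per_km * (d - brk)
        return np.where(d < coast, land, np.where(d < brk, shelf, slope))


def generate_seascape(
    islands: list[Island],
    origin: tuple[float, float],
    n_rows: int,
    n_cols: int,
    cell_deg: float,
    max_depth_m: float = 5000.0,
) -> BathymetryGrid:
    """Build a bathymetry grid from island definitions.

    Depth at each cell is the minimum (shallowest) of the per-island radial
    profiles, capped at ``max_depth_m``. Deterministic for a given config.

    Raises if no island is given, if any island's land core falls outside
    the grid, or if two islands' land cores overlap.
    """
    if not islands:
        raise ValueError("at least one island required")
    if cell_deg <= 0:
        raise ValueError("cell size must be positive")

    lat_max = origin[0] + cell_deg * (n_rows - 1)
    lon_max = origin[1] + cell_deg * (n_cols - 1)
    for isl in islands:
        la, lo = isl.center
        if not (origin[0] <= la <= lat_max and origin[1] <= lo <= lon_max):
            raise ValueError(f"island center {isl.center} outside grid bounds")
    for i, a in enumerate(islands):
        for b in islands[i + 1 :]:
            gap = haversine_km(a.center[0], a.center[1], b.center[0], b.center[1])
            if gap < a.land_radius_km + b.land_radius_km:
                raise ValueError("island land cores overlap")

    lats = origin[0] + cell_deg * np.arange(n_rows)
    lons = origin[1] + cell_deg * np.arange(n_cols)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    depth = np.full((n_rows, n_cols), max_depth_m)
    for isl in islands:
        d = haversine_km(glat, glon, isl.center[0], isl.center[1])
        depth = np.minimum(depth, isl.profile_depth_m(d))
    return BathymetryGrid(origin=origin, cell_deg=cell_deg, depth=depth)
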