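"""Local convex hull (LoCoH) utilization distributions.

A LoCoH home range is built by drawing a small convex hull around every
location ("root point") and its local neighbors, sorting hulls from densest
(most locations enclosed) to sparsest, and accumulating their union until a
stated fraction of all locations is enclosed — the isopleth at that level.
Low-level isopleths (10-25%) delineate the core use area; the 95% isopleth
approximates the full home range.

Three neighbor rules are supported:

- ``k``: the root plus its k-1 nearest neighbors;
- ``r``: the root plus all points within a fixed radius r;
- ``a`` (adaptive): the root plus nearest points added in increasing
  distance while the running sum of their distances stays <= a.

Time-based hull weighting is not implemented (the API accepts ``s`` but
rejects any value other than 0).

All coordinates are planar meters (project first); areas are reported in
square kilometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint
from shapely.ops import unary_union

from sharkmove.grid import BathymetryGrid, depth_at

DEFAULT_LEVELS = (0.10, 0.25, 0.50, 0.95)


def neighbor_sets(points: np.ndarray, method: str, value: float) -> list[np.ndarray]:
    """Per-root neighbor index sets (root included) under a LoCoH rule."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if value <= 0:
        raise ValueError("method value must be positive")
    if method == "k":
        k = int(value)
        if k > n:
            raise ValueError(f"k={k} exceeds number of points n={n}")
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=k)
        idx = np.atleast_2d(idx)
        return [np.asarray(row) for row in idx]
    if method == "r":
        tree = cKDTree(pts)
        return [np.asarray(s) for s in tree.query_ball_point(pts, r=float(value))]
    if method == "a":
        out = []
        for i in range(n):
            d = np.hypot(*(pts - pts[i]).T)
            order = np.argsort(d, kind="stable")
            csum = np.cumsum(d[order])
            take = order[: int(np.searchsorted(csum, float(value), side="right"))]
            if i not in take:  # root always included (distance 0)
                take = np.concatenate([[i], take])
            out.append(np.asarray(take))
        return out
    raise ValueError(f"unknown method {method!r}; expected 'k', 'r' or 'a'")


@dataclass
class HullSet:
    """Local hulls for one point set.

    ``enclosed_idx[i]`` holds the indices of *all* points on or inside hull
    i (not just its neighbor set); hulls are kept in root-point order.
    """

    points: np.ndarray = field(repr=False)
    polygons: list = field(repr=False)
    areas_m2: np.ndarray = field(repr=False)
    enclosed_idx: list[np.ndarray] = field(repr=False)

    @property
    def enclosed_counts(self) -> np.ndarray:
        return np.array([len(e) for e in self.enclosed_idx])

    def __len__(self) -> int:
        return len(self.polygons)


def build_hulls(points: np.ndarray, nbr_sets: list[np.ndarray]) -> HullSet:
    """Convex hull per root over root+neighbors, with enclosed-point counts.

    Degenerate neighbor sets (collinear or duplicate points) yield
    zero-area hulls; they participate in sorting rather than erroring.
    """
    pts = np.asarray(points, dtype=float)
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    tree = shapely.STRtree(geoms)
    polygons, areas, enclosed = [], [], []
    for nbrs in nbr_sets:
        hull = MultiPoint(pts[np.asarray(nbrs)]).convex_hull
        polygons.append(hull)
        areas.append(hull.area)
        cand = tree.query(hull, predicate="intersects")
        enclosed.append(np.sort(cand))
    return HullSet(pts, polygons, np.asarray(areas, dtype=float), enclosed)


@dataclass
class IsoplethSet:
    """Nested utilization-distribution polygons.

    For each level (ascending fraction of locations): the union geometry,
    its area in km^2, the achieved enclosed fraction (>= level), and the
    number of hulls accumulated.
    """

    levels: tuple[float, ...]
    geometries: list = field(repr=False)
    areas_km2: np.ndarray
    fractions: np.ndarray
    n_hulls: np.ndarray

    def level(self, lv: float):
        return self.geometries[self.levels.index(lv)]


def hull_order(hulls: HullSet) -> np.ndarray:
    """Density sort: enclosed count descending, ties by area ascending."""
    counts = hulls.enclosed_counts
    return np.lexsort((hulls.areas_m2, -counts))


def build_isopleths(hulls: HullSet, levels=DEFAULT_LEVELS, s: float = 0.0) -> IsoplethSet:
    """Accumulate density-sorted hulls into nested isopleths.

    Hulls are unioned in density order until the enclosed fraction of all
    points reaches each requested level; lower levels are therefore always
    spatially contained in higher ones.
    """
    if s != 0.0:
        raise NotImplementedError("time-based hull weighting (s != 0) is not supported")
    levels = tuple(sorted(float(v) for v in levels))
    if any(v <= 0 or v > 1 for v in levels):
        raise ValueError("isopleth levels must lie in (0, 1]")
    if len(hulls) == 0:
        raise ValueError("at least one hull required")

    order = hull_order(hulls)
    n_pts = len(hulls.points)
    covered = np.zeros(n_pts, dtype=bool)
    fractions_by_prefix = np.empty(len(order))
    for rank, h in enumerate(order):
        covered[hulls.enclosed_idx[h]] = True
        fractions_by_prefix[rank] = covered.sum() / n_pts

    geoms, areas, fracs, sizes = [], [], [], []
    for lv in levels:
        k = int(np.searchsorted(fractions_by_prefix, lv, side="left")) + 1
        k = min(k, len(order))
        union = unary_union([hulls.polygons[h] for h in order[:k]])
        geoms.append(union)
        areas.append(union.area / 1e6)
        fracs.append(fractions_by_prefix[k - 1])
        sizes.append(k)
    return IsoplethSet(levels, geoms, np.asarray(areas), np.asarray(fracs), np.asarray(sizes))


def locoh_isopleths(
    points: np.ndarray,
    method: str = "a",
    value: float | None = None,
    levels=DEFAULT_LEVELS,
) -> IsoplethSet:
    """Convenience wrapper: neighbor sets -> hulls -> isopleths."""
    nbrs = neighbor_sets(points, method, value)
    return build_isopleths(build_hulls(points, nbrs), levels)


def select_a_value(
    points: np.ndarray,
    candidates: list[float],
    land,
    level: float = 0.95,
    land_tolerance: float = 0.01,
) -> tuple[float | None, pd.DataFrame]:
    """Adaptive-method a-value selection diagnostics.

    For each candidate the ``level`` isopleth is built and scored on two
    criteria: interior holes (gaps within the surface) and overlap with
    terrestrial habitat (``land``: a shapely geometry in the same planar
    frame). The chosen a is the smallest candidate with zero holes and a
    land-overlap fraction <= ``land_tolerance`` of the isopleth area; if no
    candidate qualifies, ``(None, table)`` is returned with a warning.
    """
    if len(candidates) < 2:
        raise ValueError("at least two candidate a values required")
    rows = []
    for a in sorted(candidates):
        iso = locoh_isopleths(points, "a", a, levels=(level,))
        geom = iso.geometries[0]
        parts = list(getattr(geom, "geoms", [geom]))
        polys = [p for p in parts if p.geom_type == "Polygon"]
        holes = sum(len(p.interiors) for p in polys)
        n_parts = len(parts)
        area = geom.area
        overlap = geom.intersection(land).area / area if area > 0 else 0.0
        rows.append(
            {
                "a": a,
                "holes": holes,
                "n_parts": n_parts,
                "area_km2": area / 1e6,
                "land_overlap_frac": overlap,
                "acceptable": holes == 0 and overlap <= land_tolerance,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["acceptable"]]
    if ok.empty:
        warnings.warn("no candidate a value satisfies the selection criteria", stacklevel=2)
        return None, table
    return float(ok["a"].iloc[0]), table


def exclude_offshore_loops(
    track: pd.DataFrame,
    grid: BathymetryGrid,
    isobath_m: float = 4000.0,
) -> pd.DataFrame:
    """Drop runs of consecutive fixes whose seafloor depth exceeds an isobath.

    Offshore excursions beyond the coastal isobath (default 4,000 m) inflate
    coastal utilization distributions; maximal runs of fixes over deeper
    water are removed in full, purely by harvested depth (no trajectory
    judgment). Returns the coastal subset of the retained fixes.
    """
    r = track[track["retained"]] if "retained" in track.columns else track
    if r.empty:
        return r.copy()
    depths = depth_at(grid, r["lat"].to_numpy(), r["lon"].to_numpy())
    return r[depths <= isobath_m].copy()
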