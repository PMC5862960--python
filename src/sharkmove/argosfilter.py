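"""Argos track cleaning.

Raw Argos fix tables mix location classes of wildly different accuracy.
The cleaning pipeline, in order:

1. :func:`drop_class_z` — LC Z fixes carry no usable position.
2. :func:`remove_distant_outliers` — an automated radius-from-reference rule
   replacing ad-hoc manual removal of obviously spurious distant positions
   (default 2,500 km, beyond any plausible offshore excursion).
3. :func:`speed_filter` — the land-avoiding swim-speed filter: high-quality
   fixes (LC 1/2/3, plus GPS-quality 'G') anchor the filter and are never
   removed by it; each LC 0/A/B fix is kept only if it lies within a
   ``vmax`` km/h buffer of its most recent anchor and falls at sea.
4. :func:`thin_temporal_clusters` — collapse temporally clustered fixes
   (oversampling bias) to one representative per cluster.
5. :func:`project_to_planar` — UTM projection for planar home-range work.

Tracks are pandas DataFrames with columns ``time, lat, lon, lc`` plus
provenance columns ``retained`` (bool) and ``reason`` (one of
``distant_outlier, class_z, speed, land, cluster_thinned``, empty while
retained). Filters flag rather than delete, so retained fixes are always a
subsequence of the input and every removal is attributable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from sharkmove.geo import haversine_km
from sharkmove.grid import BathymetryGrid, depth_at
from sharkmove.projection import lonlat_to_utm

ANCHOR_CLASSES = frozenset({"1", "2", "3", "G"})
FILTERED_CLASSES = frozenset({"0", "A", "B"})

#: quality order used for cluster representatives (best first).
LC_RANK = {"G": 7, "3": 6, "2": 5, "1": 4, "0": 3, "A": 2, "B": 1, "Z": 0}

REMOVAL_REASONS = frozenset(
    {"distant_outlier", "class_z", "speed", "land", "cluster_thinned"}
)


def as_track(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a raw fix table into a provenance-carrying track.

    Sorts by time, coerces types, and adds ``retained``/``reason`` columns.
    """
    out = df.copy()
    out["time"] = pd.to_datetime(out["time"])
    out["lc"] = out["lc"].astype(str)
    out = out.sort_values("time", kind="stable").reset_index(drop=True)
    if "retained" not in out.columns:
        out["retained"] = True
    if "reason" not in out.columns:
        out["reason"] = ""
    ok = out["lc"] != "Z"
    lat, lon = out.loc[ok, "lat"], out.loc[ok, "lon"]
    if (lat.abs() > 90).any() or (lon.abs() > 180).any():
        raise ValueError("latitude/longitude out of range")
    return out


def retained(track: pd.DataFrame) -> pd.DataFrame:
    """The retained subsequence of a track."""
    return track[track["retained"]]


def _flag(track: pd.DataFrame, idx, reason: str) -> pd.DataFrame:
    out = track.copy()
    out.loc[idx, "retained"] = False
    out.loc[idx, "reason"] = reason
    return out


def drop_class_z(track: pd.DataFrame) -> pd.DataFrame:
    """Flag all LC Z fixes (no usable position)."""
    idx = track.index[track["retained"] & (track["lc"] == "Z")]
    return _flag(track, idx, "class_z")


def remove_distant_outliers(
    track: pd.DataFrame,
    reference: tuple[float, float],
    max_km: float = 2500.0,
) -> pd.DataFrame:
    """Flag fixes farther than ``max_km`` (great-circle) from ``reference``.

    ``reference`` is typically the tagging position. The default radius
    comfortably exceeds the longest offshore excursions seen in large
    coastal sharks (~1,500 km), so genuine movements are never clipped.
    """
    if max_km <= 0:
        raise ValueError("max_km must be positive")
    r = track["retained"] & track["lat"].notna()
    d = haversine_km(track.loc[r, "lat"], track.loc[r, "lon"], reference[0], reference[1])
    idx = track.index[r][np.asarray(d) > max_km]
    return _flag(track, idx, "distant_outlier")


def speed_filter(
    track: pd.DataFrame,
    vmax_kmh: float = 4.2,
    grid: BathymetryGrid | None = None,
) -> pd.DataFrame:
    """Anchor-based swim-speed and land filter for LC 0/A/B fixes.

    Anchors are retained LC 1/2/3/G fixes; they are exempt from removal.
    Each retained 0/A/B fix is kept iff its great-circle distance to the
    most recent anchor is within ``vmax_kmh`` times the elapsed hours AND
    (when ``grid`` is given) its position is at sea. Fixes preceding the
    first anchor are evaluated against the first subsequent anchor. With no
    anchors at all, every 0/A/B fix is removed and a warning is issued.

    Idempotent: a second application leaves the track unchanged.
    """
    r = track[track["retained"]]
    anchors = r[r["lc"].isin(ANCHOR_CLASSES)]
    targets = r[r["lc"].isin(FILTERED_CLASSES)]
    if targets.empty:
        return track.copy()
    if anchors.empty:
        warnings.warn("track has no anchor-quality fixes; removing all LC 0/A/B", stacklevel=2)
        return _flag(track, targets.index, "speed")

    at = anchors["time"].to_numpy()
    alat = anchors["lat"].to_numpy()
    alon = anchors["lon"].to_numpy()
    pos = np.searchsorted(at, targets["time"].to_numpy(), side="right") - 1
    pos = np.clip(pos, 0, len(at) - 1)  # pre-first-anchor -> first subsequent anchor

    dist = haversine_km(targets["lat"].to_numpy(), targets["lon"].to_numpy(), alat[pos], alon[pos])
    hours = np.abs((targets["time"].to_numpy() - at[pos]) / np.timedelta64(1, "h"))
    too_fast = dist > vmax_kmh * np.maximum(hours, 1e-9)

    out = _flag(track, targets.index[too_fast], "speed")
    if grid is not None:
        ok = targets.index[~too_fast]
        sub = track.loc[ok]
        covered = grid.covers(sub["lat"].to_numpy(), sub["lon"].to_numpy())
        if not covered.all():
            warnings.warn("fixes outside bathymetry grid skipped land test", stacklevel=2)
        at_sea = np.ones(len(sub), dtype=bool)
        if covered.any():
            at_sea[covered] = (
                depth_at(grid, sub["lat"].to_numpy()[covered], sub["lon"].to_numpy()[covered]) > 0
            )
        out = _flag(out, ok[~at_sea], "land")
    return out


def thin_temporal_clusters(
    track: pd.DataFrame,
    threshold: pd.Timedelta | None = None,
) -> pd.DataFrame:
    """Collapse temporally clustered retained fixes to one per cluster.

    A cluster is a maximal run of consecutive retained fixes whose
    successive gaps are all strictly below ``threshold`` (default: the
    median inter-fix interval of the retained track — evenly sampled tracks
    are untouched). The representative is the highest-quality fix in the
    run (earliest on ties); the rest are flagged ``cluster_thinned``.
    """
    r = track[track["retained"]]
    if len(r) < 2:
        return track.copy()
    gaps = r["time"].diff().iloc[1:]
    if threshold is None:
        threshold = gaps.median()
    new_cluster = np.ones(len(r), dtype=bool)
    new_cluster[1:] = (gaps >= threshold).to_numpy()
    cluster_id = np.cumsum(new_cluster)

    drop: list[int] = []
    rank = r["lc"].map(LC_RANK).to_numpy()
    idx = r.index.to_numpy()
    for cid in np.unique(cluster_id):
        members = np.flatnonzero(cluster_id == cid)
        if len(members) == 1:
            continue
        keep = members[np.argmax(rank[members])]  # argmax -> earliest on ties
        drop.extend(idx[m] for m in members if m != keep)
    return _flag(track, drop, "cluster_thinned")


def project_to_planar(track: pd.DataFrame, utm_zone: int = 4) -> np.ndarray:
    """Project the retained fixes to UTM meters; returns an (n, 2) array."""
    r = retained(track)
    x, y = lonlat_to_utm(r["lat"].to_numpy(), r["lon"].to_numpy(), zone=utm_zone)
    return np.column_stack([x, y])


def filter_pipeline(
    fixes: pd.DataFrame,
    reference: tuple[float, float],
    grid: BathymetryGrid | None = None,
    vmax_kmh: float = 4.2,
    outlier_km: float = 2500.0,
    thin: bool = True,
) -> pd.DataFrame:
    """The full cleaning pipeline in canonical order."""
    track = as_track(fixes)
    track = drop_class_z(track)
    track = remove_distant_outliers(track, reference, outlier_km)
    track = speed_filter(track, vmax_kmh, grid)
    if thin:
        track = thin_temporal_clusters(track)
    return track
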