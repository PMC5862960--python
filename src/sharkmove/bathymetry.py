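"""Seafloor-depth harvesting under surface fixes, and depth profiles.

The depth harvested under a satellite fix is the depth of the water column
below the animal's surface position — a habitat descriptor, never the
animal's swimming depth. Per-shark depth-frequency histograms are averaged
*across individuals* (not pooled fixes) so every animal contributes equally
to the group mean and standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sharkmove.grid import BathymetryGrid, depth_at, multi_resolution_depth  # noqa: F401

#: Default histogram edges: 50-m bins to 1000 m plus an open overflow bin.
DEFAULT_BIN_EDGES = tuple(np.arange(0.0, 1050.0, 50.0)) + (np.inf,)


@dataclass
class DepthProfile:
    """Per-shark and per-sex seafloor depth-frequency distributions."""

    bin_edges: np.ndarray
    per_shark: pd.DataFrame = field(repr=False)  # shark_id, sex, bin_low, bin_high, fraction
    by_sex: pd.DataFrame = field(repr=False)  # sex, bin_low, bin_high, mean, se, n, se_undefined


def harvest_depths(fixes: pd.DataFrame, grids) -> np.ndarray:
    """Seafloor depth under each fix; ``grids`` is a grid or fine->coarse list."""
    lat = fixes["lat"].to_numpy()
    lon = fixes["lon"].to_numpy()
    if isinstance(grids, BathymetryGrid):
        return depth_at(grids, lat, lon)
    return multi_resolution_depth(list(grids), lat, lon)


def depth_profile(
    fixes: pd.DataFrame,
    grids,
    bin_edges=DEFAULT_BIN_EDGES,
) -> DepthProfile:
    """Build per-shark normalized depth histograms and per-sex mean +/- SE.

    ``fixes`` needs columns shark_id, sex, lat, lon (retained fixes only).
    Fixes over land (depth <= 0) are excluded; a shark left with zero fixes
    is dropped with a warning. Groups of one shark report SE 0 with an
    ``se_undefined`` flag.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    fixes = fixes.copy()
    fixes["seafloor_m"] = harvest_depths(fixes, grids)

    rows = []
    for (shark, sex), sub in fixes.groupby(["shark_id", "sex"], sort=True):
        d = sub["seafloor_m"].to_numpy()
        d = d[d > 0]
        if d.size == 0:
            warnings.warn(f"shark {shark} has no at-sea fixes; excluded", stacklevel=2)
            continue
        counts, _ = np.histogram(d, bins=edges)
        frac = counts / counts.sum()
        for b in range(len(edges) - 1):
            rows.append(
                {
                    "shark_id": shark,
                    "sex": sex,
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "fraction": frac[b],
                }
            )
    per_shark = pd.DataFrame(rows)
    if per_shark.empty:
        raise ValueError("no shark yielded at-sea fixes")

    grp = per_shark.groupby(["sex", "bin_low", "bin_high"])["fraction"]
    by_sex = grp.agg(["mean", "count"]).reset_index()
    sd = grp.std(ddof=1).reset_index(drop=True)
    by_sex["se"] = (sd / np.sqrt(by_sex["count"])).fillna(0.0)
    by_sex["se_undefined"] = by_sex["count"] == 1
    by_sex = by_sex.rename(columns={"count": "n"})
    return DepthProfile(edges, per_shark, by_sex)


def fraction_within(profile: DepthProfile, depth_limit_m: float) -> pd.Series:
    """Mean fraction of fixes over seafloor shallower than ``depth_limit_m``,
    by sex (e.g. the share of locations inside the 100-m contour)."""
    b = profile.by_sex
    sel = b[b["bin_high"] <= depth_limit_m]
    return sel.groupby("sex")["mean"].sum()
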