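"""Core-attracted shark movement simulation.

Island-associated sharks typically hold a 'home' core area on the insular
shelf, make frequent short sorties within it, and occasionally range far
offshore before returning. The model is a biased correlated random walk in a
local planar frame around an attraction center: an Ornstein-Uhlenbeck-style
pull toward the center, first-order autocorrelated step noise, a hard speed
cap, land avoidance by redraw (sharks do not beach), per-step Bernoulli
surfacing, and a Poisson process of offshore excursions during which the
central pull is replaced by outward drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from sharkmove.geo import local_frame_to_lonlat
from sharkmove.grid import BathymetryGrid, depth_at
from sharkmove.simulate.rng import component_rng


@dataclass
class SharkSpec:
    """Identity and tagging metadata for one shark."""

    shark_id: str
    sex: str  # 'F' or 'M'
    total_length_cm: float
    island: str
    tagging_position: tuple[float, float]  # (lat, lon)
    tagged_at: datetime
    mature: bool = True

    def __post_init__(self) -> None:
        if self.total_length_cm <= 0:
            raise ValueError("total length must be positive")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")


@dataclass
class MovementParams:
    """Movement-model parameters.

    attraction_per_h is the OU pull rate toward the center (1/h);
    noise_km the per-step noise scale; mean/max speed in km/h (the cap is a
    hard constraint on realized step speed); surfacing_prob the per-step
    probability of being within surface-transmission reach; excursions are
    started at ``excursion_rate_per_day`` and last Exponential(mean hours).
    """

    attraction_center: tuple[float, float]
    attraction_per_h: float = 0.5
    noise_km: float = 0.5
    mean_speed_kmh: float = 1.6
    max_speed_kmh: float = 4.0
    surfacing_prob: float = 0.15
    excursion_rate_per_day: float = 0.01
    excursion_mean_h: float = 72.0
    noise_corr: float = 0.5  # step-to-step noise autocorrelation

    def __post_init__(self) -> None:
        for name in ("attraction_per_h", "noise_km", "mean_speed_kmh",
                     "max_speed_kmh", "surfacing_prob", "excursion_rate_per_day",
                     "excursion_mean_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TruePath:
    """Ground-truth track on a regular time grid."""

    shark_id: str
    times: pd.DatetimeIndex
    lat: np.ndarray = field(repr=False)
    lon: np.ndarray = field(repr=False)
    at_surface: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.times)


def simulate_shark_track(
    spec: SharkSpec,
    params: MovementParams,
    grid: BathymetryGrid,
    duration_days: float,
    step_min: float = 1.0,
    seed: int = 0,
    max_redraws: int = 25,
) -> TruePath:
    """Simulate a core-attracted track starting at the attraction center.

    Proposed steps that would land (grid depth <= 0) or leave the grid are
    re-drawn up to ``max_redraws`` times, after which the shark holds
    position for that step. Identical (spec, params, grid, seed) inputs give
    bit-identical output.
    """
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    clat, clon = params.attraction_center
    if depth_at(grid, clat, clon) <= 0:
        raise ValueError("attraction center is on land")

    rng = component_rng(seed, f"movement:{spec.shark_id}")
    dt_h = step_min / 60.0
    n = int(round(duration_days * 24 * 60 / step_min)) + 1
    max_step_km = params.max_speed_kmh * dt_h

    x = np.zeros(n)
    y = np.zeros(n)
    eta = np.zeros(2)
    excursion_left_h = 0.0
    excursion_dir = np.zeros(2)
    p_excur = params.excursion_rate_per_day * dt_h / 24.0

    for i in range(1, n):
        if excursion_left_h <= 0 and p_excur > 0 and rng.random() < p_excur:
            excursion_left_h = rng.exponential(params.excursion_mean_h)
            theta = rng.uniform(0, 2 * np.pi)
            excursion_dir = np.array([np.cos(theta), np.sin(theta)])

        pos = np.array([x[i - 1], y[i - 1]])
        if excursion_left_h > 0:
            drift = excursion_dir * params.mean_speed_kmh * dt_h
            excursion_left_h -= dt_h
        else:
            drift = -params.attraction_per_h * dt_h * pos

        new = pos
        for _ in range(max_redraws):
            eta_try = params.noise_corr * eta + params.noise_km * rng.standard_normal(2)
            step = drift + eta_try
            norm = np.hypot(*step)
            if norm > max_step_km:
                step = step * (max_step_km / norm)
            cand = pos + step
            la, lo = local_frame_to_lonlat(cand[0], cand[1], clat, clon)
            if grid.covers(la, lo) and depth_at(grid, la, lo) > 0:
                new = cand
                eta = eta_try
                break
            if params.noise_km == 0:
                break  # deterministic proposal; redrawing cannot help
        x[i], y[i] = new

    lat, lon = local_frame_to_lonlat(x, y, clat, clon)
    surf_rng = component_rng(seed, f"surfacing:{spec.shark_id}")
    at_surface = surf_rng.random(n) < params.surfacing_prob
    times = pd.date_range(spec.tagged_at, periods=n, freq=pd.Timedelta(minutes=step_min))
    return TruePath(spec.shark_id, times, lat, lon, at_surface)


def interpolate_position(path: TruePath, when) -> tuple[float, float]:
    """Linearly interpolated (lat, lon) of the path at an arbitrary time."""
    t = pd.Timestamp(when)
    ts = path.times.asi8 / 1e9
    q = t.value / 1e9
    la = float(np.interp(q, ts, path.lat))
    lo = float(np.interp(q, ts, path.lon))
    return la, lo
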