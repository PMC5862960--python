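"""Argos satellite fix simulation.

Fin-mounted satellite transmitters only reach the Argos constellation when
the fin breaks the surface during a satellite pass; in mid-ocean regions
coverage averages just a few minutes per hour (6-12 min/h is typical of the
central Pacific). Each fix carries a location class (LC) whose positional
error differs by orders of magnitude: the published RMS errors are <=150 m
(LC 3), 150-300 m (LC 2) and 350-1000 m (LC 1); LCs 0/A/B carry no published
error and are modelled with larger configurable RMS; LC Z yields no usable
position and is emitted with NaN coordinates for downstream removal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sharkmove.geo import KM_PER_DEG_LAT
from sharkmove.simulate.movement import TruePath
from sharkmove.simulate.rng import component_rng

#: Argos-typical location-class mix (configurable).
DEFAULT_LC_DISTRIBUTION = {"3": 0.1, "2": 0.15, "1": 0.15, "0": 0.2, "A": 0.2, "B": 0.2}

#: RMS positional error per class, meters. 3/2/1 follow the published upper
#: bounds; 0/A/B have no published error and default to progressively larger
#: values; Z never yields a position.
DEFAULT_LC_ERROR_RMS_M = {
    "3": 150.0,
    "2": 300.0,
    "1": 1000.0,
    "0": 2000.0,
    "A": 4000.0,
    "B": 8000.0,
    "Z": float("nan"),
    "G": 30.0,  # Fastloc-GPS quality
}


def simulate_argos_fixes(
    path: TruePath,
    coverage_min_per_hour: tuple[float, float] = (6.0, 12.0),
    lc_distribution: dict[str, float] | None = None,
    lc_error_rms_m: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an Argos fix table from a true path with surfacing flags.

    For each clock hour of the track one satellite-coverage window is drawn
    (duration uniform in ``coverage_min_per_hour``, placed uniformly within
    the hour); every path step at which the shark is at the surface inside a
    coverage window yields one fix. Fix positions are the true position plus
    isotropic Gaussian noise with the per-class RMS radial error.

    Returns a DataFrame (time, lat, lon, lc) sorted by time. Raises if the
    error model lacks a class present in the class distribution.
    """
    lc_distribution = dict(DEFAULT_LC_DISTRIBUTION if lc_distribution is None else lc_distribution)
    lc_error_rms_m = dict(DEFAULT_LC_ERROR_RMS_M if lc_error_rms_m is None else lc_error_rms_m)
    missing = [c for c in lc_distribution if c != "Z" and c not in lc_error_rms_m]
    if missing:
        raise ValueError(f"error model missing location class(es): {missing}")

    classes = list(lc_distribution)
    probs = np.array([lc_distribution[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    rng = component_rng(seed, f"argos:{path.shark_id}")
    if len(path) == 0 or not path.at_surface.any():
        return pd.DataFrame(columns=["time", "lat", "lon", "lc"])

    # one coverage window per clock hour spanned by the path
    hours = pd.date_range(path.times[0].floor("h"), path.times[-1].floor("h"), freq="h")
    cov_min = rng.uniform(*coverage_min_per_hour, size=len(hours))
    cov_off = rng.uniform(0.0, 60.0 - cov_min)
    win_start = hours + pd.to_timedelta(cov_off, unit="m")
    win_end = win_start + pd.to_timedelta(cov_min, unit="m")

    ts = path.times.asi8
    s = np.searchsorted(win_start.asi8, ts, side="right") - 1
    in_window = (s >= 0) & (ts < win_end.asi8[np.clip(s, 0, None)])
    idx = np.flatnonzero(path.at_surface & in_window)
    if idx.size == 0:
        return pd.DataFrame(columns=["time", "lat", "lon", "lc"])

    lcs = rng.choice(classes, size=idx.size, p=probs)
    lat = path.lat[idx].astype(float).copy()
    lon = path.lon[idx].astype(float).copy()
    coslat = np.cos(np.radians(lat))
    for c in np.unique(lcs):
        m = lcs == c
        if c == "Z":
            lat[m] = np.nan
            lon[m] = np.nan
            continue
        sigma_km = lc_error_rms_m[c] / 1000.0 / np.sqrt(2.0)  # per-axis; radial RMS = rms
        dx = rng.normal(0.0, sigma_km, m.sum())
        dy = rng.normal(0.0, sigma_km, m.sum())
        lat[m] += dy / KM_PER_DEG_LAT
        lon[m] += dx / (KM_PER_DEG_LAT * coslat[m])

    return pd.DataFrame(
        {"time": path.times[idx], "lat": lat, "lon": lon, "lc": lcs}
    ).reset_index(drop=True)
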