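"""Great-circle geometry helpers.

All spherical distances use a mean Earth radius of 6371.0 km so that the
swim-speed filter threshold (km/h) and simulator step lengths share one
distance convention.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: km per degree of latitude on the 6371-km sphere (2*pi*R/360).
KM_PER_DEG_LAT = np.pi * EARTH_RADIUS_KM / 180.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between (lat1, lon1) and (lat2, lon2).

    Accepts scalars or numpy arrays (broadcast); coordinates in degrees.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def local_frame_to_lonlat(x_km, y_km, lat0: float, lon0: float):
    """Convert local east/north offsets (km) around (lat0, lon0) to lon/lat.

    Equirectangular approximation — adequate for the island-scale (<~200 km)
    offsets the movement simulator produces.
    """
    lat = np.asarray(y_km, dtype=float) / KM_PER_DEG_LAT + lat0
    lon = np.asarray(x_km, dtype=float) / (KM_PER_DEG_LAT * np.cos(np.radians(lat0))) + lon0
    return lat, lon


def lonlat_to_local_frame(lat, lon, lat0: float, lon0: float):
    """Inverse of :func:`local_frame_to_lonlat`; returns (x_km, y_km)."""
    y = (np.asarray(lat, dtype=float) - lat0) * KM_PER_DEG_LAT
    x = (np.asarray(lon, dtype=float) - lon0) * KM_PER_DEG_LAT * np.cos(np.radians(lat0))
    return x, y
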