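"""UTM projection on the WGS84 ellipsoid.

Forward/inverse transverse Mercator via the sixth-order Krueger series in the
third flattening (the same expansion used by modern geodesy libraries); the
truncation error is sub-millimetre within a UTM zone, so round-trips are exact
to well under the 1-m tolerance the track pipeline requires.

Hawaii falls in UTM zone 4, the package default.
"""

from __future__ import annotations

import warnings

import numpy as np

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_E0 = 500000.0  # false easting

_n = _F / (2.0 - _F)
_n2, _n3, _n4, _n5, _n6 = (_n ** i for i in range(2, 7))

# rectifying radius
_ABAR = _A / (1 + _n) * (1 + _n2 / 4 + _n4 / 64 + _n6 / 256)

_ALPHA = np.array([
    _n / 2 - 2 * _n2 / 3 + 5 * _n3 / 16 + 41 * _n4 / 180 - 127 * _n5 / 288 + 7891 * _n6 / 37800,
    13 * _n2 / 48 - 3 * _n3 / 5 + 557 * _n4 / 1440 + 281 * _n5 / 630 - 1983433 * _n6 / 1935360,
    61 * _n3 / 240 - 103 * _n4 / 140 + 15061 * _n5 / 26880 + 167603 * _n6 / 181440,
    49561 * _n4 / 161280 - 179 * _n5 / 168 + 6601661 * _n6 / 7257600,
    34729 * _n5 / 80640 - 3418889 * _n6 / 1995840,
    212378941 * _n6 / 319334400,
])

_BETA = np.array([
    _n / 2 - 2 * _n2 / 3 + 37 * _n3 / 96 - _n4 / 360 - 81 * _n5 / 512 + 96199 * _n6 / 604800,
    _n2 / 48 + _n3 / 15 - 437 * _n4 / 1440 + 46 * _n5 / 105 - 1118711 * _n6 / 3870720,
    17 * _n3 / 480 - 37 * _n4 / 840 - 209 * _n5 / 4480 + 5569 * _n6 / 90720,
    4397 * _n4 / 161280 - 11 * _n5 / 504 - 830251 * _n6 / 7257600,
    4583 * _n5 / 161280 - 108847 * _n6 / 3991680,
    20648693 * _n6 / 638668800,
])

_DELTA = np.array([
    2 * _n - 2 * _n2 / 3 - 2 * _n3 + 116 * _n4 / 45 + 26 * _n5 / 45 - 2854 * _n6 / 675,
    7 * _n2 / 3 - 8 * _n3 / 5 - 227 * _n4 / 45 + 2704 * _n5 / 315 + 2323 * _n6 / 945,
    56 * _n3 / 15 - 136 * _n4 / 35 - 1262 * _n5 / 105 + 73814 * _n6 / 2835,
    4279 * _n4 / 630 - 332 * _n5 / 35 - 399572 * _n6 / 14175,
    4174 * _n5 / 315 - 144838 * _n6 / 6237,
    601676 * _n6 / 22275,
])

_J = np.arange(1, 7)


def utm_central_meridian(zone: int) -> float:
    """Central meridian (degrees east) of a UTM zone (1-60)."""
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return -183.0 + 6.0 * zone


def lonlat_to_utm(lat, lon, zone: int = 4):
    """Project geographic coordinates to UTM easting/northing (meters).

    Warns if longitudes stray more than ~10 degrees from the zone's central
    meridian (the series stays accurate but the projection distorts).
    Raises for latitudes beyond +/-84 degrees (outside the UTM domain).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 84.0):
        raise ValueError("latitude beyond +/-84 degrees is outside the UTM domain")
    lon0 = utm_central_meridian(zone)
    dlon = (lon - lon0 + 180.0) % 360.0 - 180.0
    if np.any(np.abs(dlon) > 10.0):
        warnings.warn(
            f"longitude more than 10 deg from zone {zone} central meridian; "
            "consider a different zone",
            stacklevel=2,
        )
    phi = np.radians(lat)
    lam = np.radians(dlon)

    es = 2.0 * np.sqrt(_n) / (1.0 + _n)
    t = np.sinh(np.arctanh(np.sin(phi)) - es * np.arctanh(es * np.sin(phi)))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arctanh(np.sin(lam) / np.sqrt(1.0 + t ** 2))

    xi2 = 2.0 * np.multiply.outer(_J, xi_p)
    eta2 = 2.0 * np.multiply.outer(_J, eta_p)
    al = _ALPHA.reshape((6,) + (1,) * xi_p.ndim)
    xi = xi_p + np.sum(al * np.sin(xi2) * np.cosh(eta2), axis=0)
    eta = eta_p + np.sum(al * np.cos(xi2) * np.sinh(eta2), axis=0)

    easting = _E0 + _K0 * _ABAR * eta
    northing = _K0 * _ABAR * xi
    northing = np.where(lat < 0, northing + 10000000.0, northing)
    return easting, northing


def utm_to_lonlat(easting, northing, zone: int = 4, southern: bool = False):
    """Inverse UTM projection; returns (lat, lon) in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if southern:
        northing = northing - 10000000.0
    xi = northing / (_K0 * _ABAR)
    eta = (easting - _E0) / (_K0 * _ABAR)

    xi2 = 2.0 * np.multiply.outer(_J, xi)
    eta2 = 2.0 * np.multiply.outer(_J, eta)
    be = _BETA.reshape((6,) + (1,) * xi.ndim)
    xi_p = xi - np.sum(be * np.sin(xi2) * np.cosh(eta2), axis=0)
    eta_p = eta - np.sum(be * np.cos(xi2) * np.sinh(eta2), axis=0)

    chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))
    de = _DELTA.reshape((6,) + (1,) * np.asarray(chi).ndim)
    phi = chi + np.sum(de * np.sin(2.0 * np.multiply.outer(_J, chi)), axis=0)
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    lat = np.degrees(phi)
    lon = utm_central_meridian(zone) + np.degrees(lam)
    return lat, lon
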