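"""Spherical geodesy helpers shared by all pipeline stages.

Distances use a spherical Earth of radius 6,371 km, which is accurate to a few
metres over the receiver-to-receiver scales (1-125 km) this package works at.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any((lon <= -180.0) | (lon > 180.0)):
        raise ValueError("longitude out of range (-180, 180]")


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between points in decimal degrees.

    Vectorised over numpy-broadcastable inputs; symmetric and non-negative.
    """
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    p1, l1, p2, l2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
    if np.isscalar(lat1) and np.isscalar(lat2) and np.isscalar(lon1) and np.isscalar(lon2):
        return float(d)
    return d


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing (radians clockwise from north)."""
    p1, l1, p2, l2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dlam = l2 - l1
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return np.arctan2(y, x)


def azimuthal_equidistant(lat, lon, lat0: float, lon0: float):
    """Project lon/lat (degrees) to planar x/y metres about (lat0, lon0).

    Azimuthal equidistant: radial distances from the centre are exact, which is
    what kernel bandwidths and contour areas care about over a <1 degree bay.
    """
    d = haversine_m(lat0, lon0, lat, lon)
    theta = initial_bearing_rad(lat0, lon0, lat, lon)
    return d * np.sin(theta), d * np.cos(theta)


def inverse_azimuthal_equidistant(x, y, lat0: float, lon0: float):
    """Inverse of :func:`azimuthal_equidistant` (returns lat, lon degrees)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_M
    p0 = np.radians(lat0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.arcsin(np.cos(c) * np.sin(p0) + np.where(rho > 0, y * np.sin(c) / np.maximum(rho, 1e-300), 0.0) * np.cos(p0))
        lon = np.radians(lon0) + np.arctan2(
            x * np.sin(c), rho * np.cos(p0) * np.cos(c) - y * np.sin(p0) * np.sin(c)
        )
    lat = np.where(rho == 0.0, p0, lat)
    lon = np.where(rho == 0.0, np.radians(lon0), lon)
    return np.degrees(lat), np.degrees(lon)


def destination_point(lat, lon, bearing_rad, distance_m):
    """Point reached from (lat, lon) moving distance_m on the given bearing."""
    p1 = np.radians(np.asarray(lat, dtype=float))
    l1 = np.radians(np.asarray(lon, dtype=float))
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M
    p2 = np.arcsin(np.sin(p1) * np.cos(delta) + np.cos(p1) * np.sin(delta) * np.cos(bearing_rad))
    l2 = l1 + np.arctan2(
        np.sin(bearing_rad) * np.sin(delta) * np.cos(p1),
        np.cos(delta) - np.sin(p1) * np.sin(p2),
    )
    lon2 = (np.degrees(l2) + 540.0) % 360.0 - 180.0
    return np.degrees(p2), lon2
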