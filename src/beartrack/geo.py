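"""Spherical geometry: great-circle distances, bearings, and a local
azimuthal-equidistant projection.

All routines work on WGS84 longitude/latitude in decimal degrees and treat the
Earth as a sphere of radius 6371.0 km, which is accurate to well under 0.5% at
the sub-1000-km scales of coastal telemetry tracks.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_km",
    "initial_bearing_rad",
    "wrap_angle",
    "LocalProjection",
]


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km between points in degrees.

    Accepts scalars or array-likes (broadcast); symmetric and non-negative.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Initial bearing (radians, clockwise from north) from point 1 to point 2."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    b = np.arctan2(y, x)
    if b.ndim == 0:
        return float(b)
    return b


def wrap_angle(theta):
    """Wrap an angle (radians) to (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    w = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    if w.ndim == 0:
        return float(w)
    return w


class LocalProjection:
    """Azimuthal-equidistant projection on the sphere, centred on a point.

    Forward maps (lon, lat) degrees to planar (x, y) in km; inverse maps back.
    Distances from the centre are exact; distortion elsewhere is negligible
    within a few hundred km, which is the working envelope for single track
    segments.
    """

    def __init__(self, center_lon: float, center_lat: float):
        self.center_lon = float(center_lon)
        self.center_lat = float(center_lat)
        self._lam0 = np.radians(self.center_lon)
        self._phi0 = np.radians(self.center_lat)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        cosc = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam)
        c = np.arccos(np.clip(cosc, -1.0, 1.0))
        # k = c / sin(c), -> 1 as c -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(self._phi0) * np.sin(phi) - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        rho = np.hypot(x, y)
        c = rho
        sinc = np.sin(c)
        cosc = np.cos(c)
        safe_rho = np.where(rho > 1e-12, rho, 1.0)
        phi = np.arcsin(
            np.clip(cosc * np.sin(self._phi0) + y * sinc * np.cos(self._phi0) / safe_rho, -1.0, 1.0)
        )
        lam = self._lam0 + np.arctan2(
            x * sinc, safe_rho * cosc * np.cos(self._phi0) - y * sinc * np.sin(self._phi0)
        )
        phi = np.where(rho > 1e-12, phi, self._phi0)
        lam = np.where(rho > 1e-12, lam, self._lam0)
        lon = np.degrees(lam)
        lat = np.degrees(phi)
        # normalise longitude to (-180, 180]
        lon = -((-lon + 180.0) % 360.0 - 180.0)
        if np.ndim(lon) == 0:
            return float(lon), float(lat)
        return lon, lat
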