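"""Spherical geometry: great-circle distance, great-circle interpolation, and a
local equal-area map projection.

All distances are kilometres on a sphere of radius 6371.0088 km (IUGG mean
Earth radius). The projection is the Lambert azimuthal equal-area projection,
which preserves area — and therefore the probability-mass interpretation of
kernel-density isopleths — and is exact in closed form on the sphere.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: kilometres per degree of arc on the sphere (111.195 km)
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between (lon1, lat1) and (lon2, lat2).

    Accepts scalars or broadcastable arrays of degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _to_unit(lon, lat):
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.stack([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1)


def _from_unit(v):
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    lat = np.degrees(np.arcsin(np.clip(z, -1.0, 1.0)))
    lon = np.degrees(np.arctan2(y, x))
    return lon, lat


def great_circle_interpolate(lon1, lat1, lon2, lat2, frac):
    """Point(s) a fraction ``frac`` of the way along the great circle from
    point 1 to point 2 (spherical linear interpolation). ``frac`` may be an
    array; 0 returns point 1, 1 returns point 2."""
    a = _to_unit(lon1, lat1)
    b = _to_unit(lon2, lat2)
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    f = np.asarray(frac, dtype=float)[..., None]
    if omega < 1e-12:
        v = a * (1.0 - f) + b * f
    else:
        v = (np.sin((1.0 - f) * omega) * a + np.sin(f * omega) * b) / np.sin(omega)
        v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return _from_unit(v)


class LocalEqualArea:
    """Lambert azimuthal equal-area projection centred at (center_lon,
    center_lat), planar coordinates in km. Exact sphere formulas; the
    round-trip error is at floating-point level well beyond 2000 km."""

    def __init__(self, center_lon: float, center_lat: float):
        self.center_lon = float(center_lon)
        self.center_lat = float(center_lat)
        self._lam0 = np.radians(self.center_lon)
        self._phi0 = np.radians(self.center_lat)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        c = 1.0 + np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam)
        # antipode (c == 0) is not representable; clip to avoid 0-division
        k = np.sqrt(2.0 / np.maximum(c, 1e-12))
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (np.cos(self._phi0) * np.sin(phi)
                                   - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        rho = np.hypot(x, y)
        cc = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho > 1e-15,
                np.arcsin(np.clip(np.cos(cc) * np.sin(self._phi0)
                                  + y * np.sin(cc) * np.cos(self._phi0) / np.where(rho > 1e-15, rho, 1.0),
                                  -1.0, 1.0)),
                self._phi0,
            )
            lam = np.where(
                rho > 1e-15,
                self._lam0 + np.arctan2(
                    x * np.sin(cc),
                    rho * np.cos(self._phi0) * np.cos(cc) - y * np.sin(self._phi0) * np.sin(cc),
                ),
                self._lam0,
            )
        return np.degrees(lam), np.degrees(phi)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"LocalEqualArea(center_lon={self.center_lon}, center_lat={self.center_lat})"
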