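"""Spherical-Earth geometry helpers shared across the package.

All distances use a spherical Earth of radius 6371.0 km and the haversine
formula. Local planar coordinates use an equirectangular projection about a
reference latitude, which is accurate to well under 1% over the few-hundred-km
scales handled here.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: metres per degree of latitude on the sphere
M_PER_DEG_LAT = EARTH_RADIUS_KM * 1000.0 * np.pi / 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def equirectangular_xy_km(lon, lat, lon0: float, lat0: float):
    """Project lon/lat (degrees) to planar x/y in km about (lon0, lat0)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    kx = EARTH_RADIUS_KM * np.pi / 180.0 * np.cos(np.radians(lat0))
    ky = EARTH_RADIUS_KM * np.pi / 180.0
    return (lon - lon0) * kx, (lat - lat0) * ky


def track_length_km(lons, lats) -> float:
    """Sum of consecutive great-circle legs along a path."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 2:
        return 0.0
    return float(np.sum(haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])))
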