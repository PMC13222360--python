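"""Spherical geometry primitives shared across the package.

All coordinates are WGS84 decimal degrees and all distances are great-circle
distances on a sphere of radius 6371.0 km.  No map projection is used
anywhere in the package: working on the sphere keeps every distance
(site fidelity, flown path length, nearest-neighbour route separation)
internally consistent along a flyway that spans ~40 degrees of latitude.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(a, b) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees.

    Symmetric, zero iff the points coincide. Accepts scalars or array-likes
    broadcastable against each other.
    """
    lat1, lon1 = np.radians(np.asarray(a, dtype=float)[..., 0]), np.radians(
        np.asarray(a, dtype=float)[..., 1]
    )
    lat2, lon2 = np.radians(np.asarray(b, dtype=float)[..., 0]), np.radians(
        np.asarray(b, dtype=float)[..., 1]
    )
    return _haversine_rad(lat1, lon1, lat2, lon2)


def haversine_arrays_km(lat1, lon1, lat2, lon2):
    """Vectorised haversine on separate degree arrays (broadcasting)."""
    return _haversine_rad(
        np.radians(np.asarray(lat1, dtype=float)),
        np.radians(np.asarray(lon1, dtype=float)),
        np.radians(np.asarray(lat2, dtype=float)),
        np.radians(np.asarray(lon2, dtype=float)),
    )


def _haversine_rad(lat1, lon1, lat2, lon2):
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    if np.ndim(d) == 0:
        return float(d)
    return d


def step_distances_km(lat, lon):
    """Consecutive-fix great-circle distances; length n-1."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return haversine_arrays_km(lat[:-1], lon[:-1], lat[1:], lon[1:])


def initial_bearing_deg(a, b) -> float:
    """Initial bearing (degrees clockwise from north) of the great circle a->b."""
    lat1, lon1 = np.radians(float(a[0])), np.radians(float(a[1]))
    lat2, lon2 = np.radians(float(b[0])), np.radians(float(b[1]))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return float(np.degrees(np.arctan2(x, y)) % 360.0)


def destination_point(a, bearing_deg: float, distance_km: float):
    """Point reached from ``a`` travelling ``distance_km`` on ``bearing_deg``."""
    lat1, lon1 = np.radians(float(a[0])), np.radians(float(a[1]))
    brg = np.radians(bearing_deg)
    delta = distance_km / EARTH_RADIUS_KM
    lat2 = np.arcsin(
        np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(brg)
    )
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    lon2 = (lon2 + np.pi) % (2 * np.pi) - np.pi
    return float(np.degrees(lat2)), float(np.degrees(lon2))


def _to_unit_vectors(lat_deg, lon_deg):
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1
    )


def _from_unit_vectors(v):
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lat, lon


def great_circle_points(a, b, fractions):
    """Points along the great circle a->b at the given arc fractions (slerp).

    ``fractions`` in [0, 1]; returns (lat, lon) degree arrays.
    """
    fractions = np.asarray(fractions, dtype=float)
    va = _to_unit_vectors(a[0], a[1])
    vb = _to_unit_vectors(b[0], b[1])
    omega = np.arccos(np.clip(np.dot(va, vb), -1.0, 1.0))
    if omega < 1e-12:
        lat = np.full(fractions.shape, float(a[0]))
        lon = np.full(fractions.shape, float(a[1]))
        return lat, lon
    so = np.sin(omega)
    w1 = np.sin((1.0 - fractions) * omega) / so
    w2 = np.sin(fractions * omega) / so
    v = w1[..., None] * va + w2[..., None] * vb
    return _from_unit_vectors(v)
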