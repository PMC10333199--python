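"""Spherical geodesy primitives.

All distances are great-circle ("orthodrome") distances on a sphere of
radius 6371.0 km; at the 30--150 km decision thresholds used throughout the
pipeline the sub-0.5% departure from the WGS84 ellipsoid is irrelevant.
Coordinates are WGS84 decimal degrees, longitudes in [-180, 180).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def gc_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km (haversine). Accepts scalars or arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def initial_bearing(lat1, lon1, lat2, lon2) -> float:
    """Initial great-circle bearing from point 1 to point 2.

    Returns degrees clockwise from true north in [0, 360).
    Raises ValueError for coincident points (bearing undefined).
    """
    if np.isclose(lat1, lat2) and np.isclose(normalize_lon(lon1), normalize_lon(lon2)):
        raise ValueError("bearing undefined for coincident points")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlon = np.radians(lon2 - lon1)
    x = np.sin(dlon) * np.cos(p2)
    y = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlon)
    return float(np.degrees(np.arctan2(x, y)) % 360.0)


def _to_unit_xyz(lat, lon):
    lat, lon = np.radians(np.asarray(lat, float)), np.radians(np.asarray(lon, float))
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def _from_unit_xyz(v):
    v = np.asarray(v, float)
    lat = np.degrees(np.arctan2(v[..., 2], np.hypot(v[..., 0], v[..., 1])))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lat, normalize_lon(lon)


def gc_interpolate(lat1, lon1, lat2, lon2, frac):
    """Points along the great circle from p1 to p2 at fraction(s) ``frac``.

    Spherical linear interpolation; frac may be a scalar or array in [0, 1].
    Returns (lat, lon) arrays.
    """
    a = _to_unit_xyz(lat1, lon1)
    b = _to_unit_xyz(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    f = np.asarray(frac, float)
    if omega < 1e-12:
        lat = np.broadcast_to(lat1, f.shape).copy() if f.ndim else float(lat1)
        lon = np.broadcast_to(lon1, f.shape).copy() if f.ndim else float(lon1)
        return lat, lon
    so = np.sin(omega)
    v = (np.sin((1.0 - f)[..., None] * omega) * a + np.sin(f[..., None] * omega) * b) / so
    return _from_unit_xyz(v)


def _xtrack_dist_to_segment(p, a, b) -> float:
    """Great-circle distance (km) from unit vector p to the arc a--b."""
    ab = np.cross(a, b)
    n = np.linalg.norm(ab)
    if n < 1e-15:  # degenerate segment
        return float(np.arccos(np.clip(np.dot(p, a), -1, 1))) * EARTH_RADIUS_KM
    ab /= n
    # foot of perpendicular great circle
    f = p - np.dot(p, ab) * ab
    fn = np.linalg.norm(f)
    if fn > 1e-15:
        f /= fn
        # is the foot within the arc? compare angular spans
        ang_ab = np.arccos(np.clip(np.dot(a, b), -1, 1))
        if (np.arccos(np.clip(np.dot(a, f), -1, 1)) <= ang_ab + 1e-12
                and np.arccos(np.clip(np.dot(f, b), -1, 1)) <= ang_ab + 1e-12):
            return float(np.arccos(np.clip(np.dot(p, f), -1, 1))) * EARTH_RADIUS_KM
    return EARTH_RADIUS_KM * float(min(np.arccos(np.clip(np.dot(p, a), -1, 1)),
                                       np.arccos(np.clip(np.dot(p, b), -1, 1))))


def distance_to_ring_km(lat, lon, ring_coords) -> float:
    """Min great-circle distance from a point to a closed/open coordinate ring.

    ``ring_coords`` is a sequence of (lon, lat) pairs (GeoJSON axis order).
    """
    p = _to_unit_xyz(lat, lon)
    coords = np.asarray(ring_coords, float)
    verts = _to_unit_xyz(coords[:, 1], coords[:, 0])
    best = np.inf
    for i in range(len(verts) - 1):
        best = min(best, _xtrack_dist_to_segment(p, verts[i], verts[i + 1]))
    if len(verts) == 1:
        best = float(np.arccos(np.clip(np.dot(p, verts[0]), -1, 1))) * EARTH_RADIUS_KM
    return float(best)
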