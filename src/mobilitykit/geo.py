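"""Spherical geometry helpers shared by the GPS pipeline and the simulator.

All distances are great-circle distances on a sphere of radius 6,371 km.
Hull/ellipse computations elsewhere use :func:`project_aeqd`, a local
azimuthal-equidistant projection: distances from the projection center are
exact, and distortion between points is negligible (<0.5%) at the city scale
where life-space metrics live.
"""

from __future__ import annotations

import math

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between coordinate pairs (degrees).

    Accepts scalars or numpy arrays (broadcast); symmetric; zero iff the
    points coincide.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for antipodal-ish inputs
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Forward azimuth (radians, clockwise from north) from point 1 to point 2."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def project_aeqd(lat, lon, center_lat, center_lon):
    """Project degrees to a local azimuthal-equidistant plane (meters).

    Returns (x, y) with x east and y north of the center. Distance from the
    origin to any projected point equals the great-circle distance exactly.
    """
    d = haversine_m(center_lat, center_lon, lat, lon)
    az = initial_bearing_rad(center_lat, center_lon, lat, lon)
    return np.asarray(d) * np.sin(az), np.asarray(d) * np.cos(az)


def unproject_aeqd(x, y, center_lat, center_lon):
    """Inverse of :func:`project_aeqd`: local plane meters back to degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.hypot(x, y)
    az = np.arctan2(x, y)
    lat0 = np.radians(center_lat)
    lon0 = np.radians(center_lon)
    ang = d / EARTH_RADIUS_M
    lat = np.arcsin(np.sin(lat0) * np.cos(ang) + np.cos(lat0) * np.sin(ang) * np.cos(az))
    lon = lon0 + np.arctan2(
        np.sin(az) * np.sin(ang) * np.cos(lat0),
        np.cos(ang) - np.sin(lat0) * np.sin(lat),
    )
    return np.degrees(lat), np.degrees(lon)


def haversine_scalar_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Scalar fast path of :func:`haversine_m` (identical formula)."""
    rad = math.radians
    la1, la2 = rad(lat1), rad(lat2)
    a = math.sin((la2 - la1) / 2.0) ** 2 \
        + math.cos(la1) * math.cos(la2) * math.sin(rad(lon2 - lon1) / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(math.sqrt(min(max(a, 0.0), 1.0)))


def max_pairwise_distance_m(lat, lon):
    """Largest great-circle distance between any two points of a set.

    Duplicates are collapsed and the convex hull of locally projected
    coordinates keeps the pairwise scan small; exact for the point sets the
    pipeline sees.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    pts = np.unique(np.column_stack([lat, lon]), axis=0)
    lat, lon = pts[:, 0], pts[:, 1]
    n = lat.size
    if n < 2:
        return 0.0
    if n > 12:
        from scipy.spatial import ConvexHull, QhullError

        x, y = project_aeqd(lat, lon, lat.mean(), lon.mean())
        try:
            hull = ConvexHull(np.column_stack([x, y]))
            idx = hull.vertices
            lat, lon = lat[idx], lon[idx]
        except QhullError:
            pass  # collinear/degenerate: fall through to full scan
    d = haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    return float(d.max())
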