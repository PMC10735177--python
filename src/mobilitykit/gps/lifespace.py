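"""Daily life-space metrics: farthest distance from home, minimum convex
hull, standard deviational ellipse.

Points are projected onto a local azimuthal-equidistant plane centered at
the participant's home, so distances from home are exact great-circle
distances and hull area/perimeter carry meter units.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from ..geo import project_aeqd
from .types import GpsTrack, LifeSpaceSummary


def _sde(x: np.ndarray, y: np.ndarray):
    """Standard deviational ellipse: center = mean point, axes = 1-SD
    eigen-axes of the n-denominator coordinate covariance, theta = major-axis
    orientation in radians counterclockwise from east."""
    cx, cy = float(np.mean(x)), float(np.mean(y))
    xc, yc = x - cx, y - cy
    cov = np.array([[np.mean(xc * xc), np.mean(xc * yc)],
                    [np.mean(xc * yc), np.mean(yc * yc)]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major = float(np.sqrt(max(evals[1], 0.0)))
    minor = float(np.sqrt(max(evals[0], 0.0)))
    vx, vy = evecs[:, 1]
    theta = float(np.arctan2(vy, vx)) % np.pi
    return (cx, cy), major, minor, theta


def lifespace_metrics(track: GpsTrack, home_lat: float, home_lon: float) -> LifeSpaceSummary:
    """Compute the daily life-space summary from a cleaned track.

    The minimum convex hull (MCH) is the smallest convex polygon containing
    all fixes; its area uses the shoelace formula via shapely. Degenerate
    point sets (fewer than 3 distinct non-collinear points) report zero area
    and, as the continuous limit, the length of the collinear extent as the
    perimeter, with ``degenerate_hull`` set.
    """
    n = len(track)
    if n == 0:
        raise ValueError("lifespace_metrics needs at least one fix")
    x, y = project_aeqd(track.lat, track.lon, home_lat, home_lon)
    x = np.atleast_1d(x)
    y = np.atleast_1d(y)
    max_dist = float(np.hypot(x, y).max())

    hull = MultiPoint(np.column_stack([x, y])).convex_hull
    if isinstance(hull, Polygon):
        area = float(hull.area)
        perim = float(hull.exterior.length)
        degenerate = False
        # sliver guard: a "polygon" of collinear-to-rounding points
        if perim > 0 and area / perim ** 2 < 1e-12:
            xy = np.asarray(hull.exterior.coords)
            d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
            area, perim, degenerate = 0.0, float(d.max()), True
    elif isinstance(hull, LineString):
        area = 0.0
        perim = float(hull.length)
        degenerate = True
    else:  # single Point
        area = 0.0
        perim = 0.0
        degenerate = True

    center, major, minor, theta = _sde(x, y)
    return LifeSpaceSummary(max_dist, area, perim, center, major, minor, theta,
                            n, degenerate)
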