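"""Speed-based plausibility filtering of raw GPS tracks."""

from __future__ import annotations

import numpy as np

from ..geo import haversine_m
from .types import GpsTrack, TripDetectionParams


def derived_speeds_kmh(track: GpsTrack) -> np.ndarray:
    """Point-to-point speeds (km/h) from consecutive fixes.

    The first point inherits the speed of the second so that every fix has a
    speed; a single-point track gets speed 0.
    """
    n = len(track)
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.zeros(1)
    d = haversine_m(track.lat[:-1], track.lon[:-1], track.lat[1:], track.lon[1:])
    dt = np.diff(track.t)
    v = np.empty(n)
    v[1:] = d / dt * 3.6
    v[0] = v[1]
    return v


def clean_track(track: GpsTrack, params: TripDetectionParams = TripDetectionParams()) -> GpsTrack:
    """Drop fixes moving faster than ``max_speed_kmh``.

    The speed of a fix is its logged speed when the device provides one,
    otherwise the speed derived from the haversine distance and time gap to
    the previous *retained* fix — so a single bad fix does not poison its
    successor. A single point is always retained (no speed is computable).
    """
    n = len(track)
    if n <= 1:
        return track
    if track.speed_kmh is not None:
        keep = track.speed_kmh <= params.max_speed_kmh
        return track.slice(keep)

    keep = np.zeros(n, dtype=bool)
    keep[0] = True
    prev = 0
    for i in range(1, n):
        dt = track.t[i] - track.t[prev]
        v = haversine_m(track.lat[prev], track.lon[prev], track.lat[i], track.lon[i]) / dt * 3.6
        if v <= params.max_speed_kmh:
            keep[i] = True
            prev = i
    return track.slice(keep)
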