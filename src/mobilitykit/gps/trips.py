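"""Trip summaries: duration, 90th-percentile speed, travel mode."""

from __future__ import annotations

import numpy as np

from .cleaning import derived_speeds_kmh
from .types import GpsTrack, Segment, Trip, TripDetectionParams, TripSummary


def segment_point_speeds_kmh(track: GpsTrack, seg: Segment) -> np.ndarray:
    """Speeds of a segment's member fixes (km/h): logged if available, else
    derived from consecutive member fixes."""
    sub = track.slice(slice(seg.i0, seg.i1 + 1))
    if sub.speed_kmh is not None:
        return sub.speed_kmh
    return derived_speeds_kmh(sub)


def classify_mode(p90_speed_kmh: float, params: TripDetectionParams) -> str:
    """Passive (motorized) iff the trip's 90th-percentile speed reaches the
    threshold (default 25 km/h), else active."""
    return "passive" if p90_speed_kmh >= params.passive_speed_threshold_kmh else "active"


def summarize_trips(track: GpsTrack, segments: list,
                    params: TripDetectionParams = TripDetectionParams()) -> TripSummary:
    """Promote move segments to trips and aggregate the daily totals.

    Daily trip frequency is the number of move segments; daily trip duration
    is the sum of their durations in minutes, also split by travel mode.
    """
    trips = []
    for seg in segments:
        if seg.kind != "move":
            continue
        speeds = segment_point_speeds_kmh(track, seg)
        p90 = float(np.percentile(speeds, params.passive_speed_percentile)) if speeds.size else 0.0
        trips.append(Trip(seg, seg.duration_s / 60.0, p90, classify_mode(p90, params)))
    total = sum(tr.duration_min for tr in trips)
    active = sum(tr.duration_min for tr in trips if tr.mode == "active")
    passive = total - active
    return TripSummary(trips, len(trips), total, active, passive)
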