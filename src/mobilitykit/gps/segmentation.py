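"""Stop/move segmentation of cleaned GPS tracks.

A Montoliu-style greedy stay-point detector: a candidate stop grows forward
from an anchor point for as long as every member fix stays within
``stop_radius_m`` of the running median position; a candidate whose time span
reaches ``stop_min_duration_s`` is committed as a stop. Gaps longer than
``stop_gap_break_s`` always split segments. Runs of fixes between stops
become moves when they last longer than ``move_min_duration_s`` and span at
least ``move_min_span_m`` between their farthest points; shorter or tighter
runs are merged into a flanking stop.

Because "stopped" means "within 75 m of the stop anchor", committed stops are
then boundary-adjusted against their final median: member fixes farther than
the radius are released to the neighbouring move, and neighbouring fixes
inside the radius are absorbed. This makes a detected trip start/end at the
moment the participant crosses the stop radius, which is also how trip times
are defined in the synthetic ground truth.
"""

from __future__ import annotations

from bisect import insort

import numpy as np

from ..geo import haversine_m, haversine_scalar_m, max_pairwise_distance_m
from .types import GpsTrack, Segment, TripDetectionParams

_MAX_ADJUST_ITER = 25


def _grow_candidate(lat, lon, t, start: int, end: int, radius: float) -> int:
    """Greatest j such that the candidate [start..j] is valid, i.e. every
    member is within ``radius`` of the running median after each addition.

    Uses a conservative drift bound to avoid re-checking all members at every
    step; when the bound cannot certify validity a full vectorized re-check
    decides exactly, so the result equals the naive all-points check.
    """
    lats_sorted = [lat[start]]
    lons_sorted = [lon[start]]
    # reference median and max member distance to it, refreshed on full checks
    ref = (lat[start], lon[start])
    max_ref = 0.0
    j = start
    while j + 1 <= end:
        k = j + 1
        insort(lats_sorted, lat[k])
        insort(lons_sorted, lon[k])
        m = len(lats_sorted)
        mid = m // 2
        if m % 2:
            med = (lats_sorted[mid], lons_sorted[mid])
        else:
            med = ((lats_sorted[mid - 1] + lats_sorted[mid]) / 2.0,
                   (lons_sorted[mid - 1] + lons_sorted[mid]) / 2.0)
        d_new_ref = haversine_scalar_m(lat[k], lon[k], ref[0], ref[1])
        max_ref = max(max_ref, d_new_ref)
        drift = haversine_scalar_m(med[0], med[1], ref[0], ref[1])
        if drift + max_ref > radius:
            # certificate failed: decide exactly
            dists = haversine_m(lat[start:k + 1], lon[start:k + 1], med[0], med[1])
            dmax = float(np.max(dists))
            if dmax > radius:
                return j
            ref = med
            max_ref = dmax
        j = k
    return j


def _detect_stop_ranges(lat, lon, t, c0: int, c1: int, params: TripDetectionParams):
    """Committed stop index ranges [(i0, i1), ...] within chunk [c0..c1]."""
    stops = []
    i = c0
    while i <= c1:
        j = _grow_candidate(lat, lon, t, i, c1, params.stop_radius_m)
        if t[j] - t[i] >= params.stop_min_duration_s:
            stops.append((i, j))
            i = j + 1
        else:
            i += 1
    return stops


def _median_of(lat, lon, i0, i1):
    return float(np.median(lat[i0:i1 + 1])), float(np.median(lon[i0:i1 + 1]))


def _adjust_stop_boundaries(lat, lon, stops, c0, c1, radius):
    """Trim stop edges beyond the radius of the final median and absorb
    neighbouring fixes inside it; merge stops whose ranges meet.

    Iterated to a fixed point (bounded); deterministic: stops are processed
    in time order, trims before absorptions.
    """
    stops = list(stops)
    for _ in range(_MAX_ADJUST_ITER):
        changed = False
        meds = [_median_of(lat, lon, i0, i1) for i0, i1 in stops]
        # trim edges farther than radius from the stop's own median
        for k, (i0, i1) in enumerate(stops):
            mlat, mlon = meds[k]
            while i0 < i1 and haversine_scalar_m(lat[i0], lon[i0], mlat, mlon) > radius:
                i0 += 1
                changed = True
            while i1 > i0 and haversine_scalar_m(lat[i1], lon[i1], mlat, mlon) > radius:
                i1 -= 1
                changed = True
            stops[k] = (i0, i1)
        # absorb neighbouring unassigned fixes inside the radius
        for k, (i0, i1) in enumerate(stops):
            mlat, mlon = meds[k]
            lo = stops[k - 1][1] + 1 if k > 0 else c0
            hi = stops[k + 1][0] - 1 if k + 1 < len(stops) else c1
            while i0 - 1 >= lo and haversine_scalar_m(lat[i0 - 1], lon[i0 - 1], mlat, mlon) <= radius:
                i0 -= 1
                changed = True
            while i1 + 1 <= hi and haversine_scalar_m(lat[i1 + 1], lon[i1 + 1], mlat, mlon) <= radius:
                i1 += 1
                changed = True
            stops[k] = (i0, i1)
        # merge stops that now touch
        merged = []
        for rng in stops:
            if merged and rng[0] <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], rng[1]))
                changed = True
            else:
                merged.append(rng)
        stops = merged
        if not changed:
            break
    return stops


def _make_segment(kind, lat, lon, t, i0, i1):
    if kind == "stop":
        clat, clon = _median_of(lat, lon, i0, i1)
    else:
        clat, clon = float(np.mean(lat[i0:i1 + 1])), float(np.mean(lon[i0:i1 + 1]))
    span = max_pairwise_distance_m(lat[i0:i1 + 1], lon[i0:i1 + 1])
    return Segment(kind, int(i0), int(i1), float(t[i0]), float(t[i1]), clat, clon, span)


def detect_segments(track: GpsTrack, params: TripDetectionParams = TripDetectionParams()):
    """Segment a cleaned track into time-ordered, non-overlapping stops and
    moves. Returns a list of :class:`Segment`.

    Fewer than 2 points yields an empty segmentation. Runs that qualify
    neither as stop nor as move and have no flanking stop in their gap-free
    chunk are left out of the segmentation.
    """
    n = len(track)
    if n < 2:
        return []
    lat, lon, t = track.lat, track.lon, track.t

    # gaps longer than the break threshold split the track outright
    gap_idx = np.nonzero(np.diff(t) > params.stop_gap_break_s)[0]
    chunk_bounds = [0] + [int(g) + 1 for g in gap_idx] + [n]

    segments = []
    for c0, c1 in zip(chunk_bounds[:-1], [b - 1 for b in chunk_bounds[1:]]):
        if c1 <= c0:
            continue
        stops = _detect_stop_ranges(lat, lon, t, c0, c1, params)
        stops = _adjust_stop_boundaries(lat, lon, stops, c0, c1, params.stop_radius_m)

        # classify the unassigned runs between/around stops
        pieces = []  # (kind, i0, i1) in time order
        cursor = c0
        for (s0, s1) in stops:
            if cursor <= s0 - 1:
                pieces.append(["run", cursor, s0 - 1])
            pieces.append(["stop", s0, s1])
            cursor = s1 + 1
        if cursor <= c1:
            pieces.append(["run", cursor, c1])

        for k, piece in enumerate(pieces):
            if piece[0] != "run":
                continue
            i0, i1 = piece[1], piece[2]
            dur = t[i1] - t[i0]
            span = max_pairwise_distance_m(lat[i0:i1 + 1], lon[i0:i1 + 1])
            if dur > params.move_min_duration_s and span >= params.move_min_span_m:
                piece[0] = "move"
            else:
                # merge into a flanking stop: prefer the preceding one
                if k > 0 and pieces[k - 1][0] == "stop":
                    pieces[k - 1][2] = i1
                    piece[0] = "dead"
                elif k + 1 < len(pieces) and pieces[k + 1][0] == "stop":
                    pieces[k + 1][1] = i0
                    piece[0] = "dead"
                else:
                    piece[0] = "dead"  # no flank: excluded from segmentation
        # coalesce stops brought adjacent by run-merging
        final = []
        for piece in pieces:
            if piece[0] == "dead":
                continue
            if final and piece[0] == "stop" and final[-1][0] == "stop" \
                    and piece[1] <= final[-1][2] + 1:
                final[-1][2] = piece[2]
            else:
                final.append(piece)
        for kind, i0, i1 in final:
            segments.append(_make_segment(kind, lat, lon, t, i0, i1))
    return segments
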