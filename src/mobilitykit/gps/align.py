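"""Temporal alignment of two devices' tracks for a fair comparison."""

from __future__ import annotations

from dataclasses import dataclass

from .types import GpsTrack, TripDetectionParams


@dataclass
class AlignedPair:
    a: GpsTrack
    b: GpsTrack
    overlap_h: float
    valid: bool  # joint coverage reaches the minimum wear threshold


def align_devices(a: GpsTrack, b: GpsTrack,
                  params: TripDetectionParams = TripDetectionParams()) -> AlignedPair:
    """Trim both tracks to the intersection of their covered time ranges.

    Days whose joint coverage falls short of ``min_joint_wear_h`` (default
    8 h) are flagged invalid rather than raising; an empty intersection gives
    two empty tracks and ``valid=False``.
    """
    if len(a) == 0 or len(b) == 0:
        return AlignedPair(a.slice(slice(0, 0)), b.slice(slice(0, 0)), 0.0, False)
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    if t1 <= t0:
        return AlignedPair(a.slice(slice(0, 0)), b.slice(slice(0, 0)), 0.0, False)
    a2 = a.time_window(t0, t1)
    b2 = b.time_window(t0, t1)
    overlap_h = (t1 - t0) / 3600.0
    return AlignedPair(a2, b2, overlap_h, overlap_h >= params.min_joint_wear_h)
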