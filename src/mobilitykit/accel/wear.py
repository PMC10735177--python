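"""Non-wear detection on 60 s epoch counts (90/2/30 zero-run rule)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import WearParams


def _runs(mask: np.ndarray):
    """(start, stop) half-open index pairs of True runs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_nonwear(counts: np.ndarray, params: WearParams = WearParams()) -> np.ndarray:
    """Boolean wear flag per epoch (True = worn).

    An epoch belongs to a non-wear block when it lies inside a stretch of
    ≥``nonwear_window_min`` epochs consisting of zero counts and *allowed*
    interruptions: nonzero runs no longer than ``allowance_min`` epochs with
    at least ``flank_min`` consecutive zero epochs immediately before and
    after. Nonzero runs at the series boundary are never allowed (no flank
    exists there). Everything else is wear.
    """
    c = np.asarray(counts, dtype=float)
    n = c.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    zero = c == 0

    # an epoch is "good" if zero, or inside an allowed interruption
    good = zero.copy()
    for s, e in _runs(~zero):
        if e - s > params.allowance_min:
            continue
        zeros_before = 0
        i = s - 1
        while i >= 0 and zero[i]:
            zeros_before += 1
            i -= 1
        zeros_after = 0
        i = e
        while i < n and zero[i]:
            zeros_after += 1
            i += 1
        if zeros_before >= params.flank_min and zeros_after >= params.flank_min:
            good[s:e] = True

    nonwear = np.zeros(n, dtype=bool)
    for s, e in _runs(good):
        if e - s >= params.nonwear_window_min:
            nonwear[s:e] = True
    return ~nonwear


@dataclass
class DayValidity:
    wear_min: float
    valid: bool


def day_validity(wear: np.ndarray, params: WearParams = WearParams(),
                 epoch_s: float = 60.0) -> DayValidity:
    """A day is valid when total wear time reaches ``min_valid_day_h``."""
    wear_min = float(np.sum(wear)) * epoch_s / 60.0
    return DayValidity(wear_min, wear_min >= params.min_valid_day_h * 60.0)
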