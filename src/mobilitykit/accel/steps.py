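"""Step counting from wrist acceleration by peak detection."""

from __future__ import annotations

import numpy as np
from scipy import signal

_STEP_BAND_HZ = (0.5, 5.0)
_MIN_PEAK_FLOOR_G = 0.05  # below this, fluctuation is treated as sensor noise


def count_steps(stream, t0: float | None = None, t1: float | None = None,
                min_interval_s: float = 0.3) -> int:
    """Steps within [t0, t1] (defaults: the whole stream).

    The vector magnitude is band-passed to the human-cadence band
    (0.5–5 Hz); peaks above an adaptive threshold — 30% of the 95th
    percentile of the band-passed amplitude, floored at 0.05 g — separated
    by at least ``min_interval_s`` are counted, one per step. The relative
    threshold makes the count invariant to signal amplitude scaling for any
    walk whose amplitude sits clearly above the noise floor.
    """
    times = stream.times
    lo = 0 if t0 is None else int(np.searchsorted(times, t0, side="left"))
    hi = len(times) if t1 is None else int(np.searchsorted(times, t1, side="right"))
    if hi - lo < int(stream.rate_hz):  # under a second of data
        return 0
    vm = np.linalg.norm(stream.data[lo:hi], axis=1)
    high = min(_STEP_BAND_HZ[1], 0.45 * stream.rate_hz)
    sos = signal.butter(3, (_STEP_BAND_HZ[0], high), btype="bandpass",
                        fs=stream.rate_hz, output="sos")
    bp = signal.sosfiltfilt(sos, vm)
    height = max(_MIN_PEAK_FLOOR_G, 0.3 * float(np.percentile(np.abs(bp), 95)))
    peaks, _ = signal.find_peaks(bp, height=height,
                                 distance=max(1, int(min_interval_s * stream.rate_hz)))
    return int(peaks.size)
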