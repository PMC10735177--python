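"""Rate conversion of raw accelerometer streams."""

from __future__ import annotations

import numpy as np

from .types import AccelStream


def resample(stream: AccelStream, target_rate_hz: float) -> AccelStream:
    """Linear interpolation of each axis onto a uniform grid at
    ``target_rate_hz`` spanning the original duration (preserved to within
    one sample period). Identity when the rates already match."""
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    if target_rate_hz == stream.rate_hz:
        return stream
    n = len(stream)
    if n == 0:
        return AccelStream(target_rate_hz, np.empty((0, 3)), stream.placement,
                           stream.start_t, stream.long_axis)
    duration = (n - 1) / stream.rate_hz
    n_out = int(np.floor(duration * target_rate_hz)) + 1
    t_src = np.arange(n) / stream.rate_hz
    t_out = np.arange(n_out) / target_rate_hz
    out = np.empty((n_out, 3))
    for ax in range(3):
        out[:, ax] = np.interp(t_out, t_src, stream.data[:, ax])
    return AccelStream(target_rate_hz, out, stream.placement, stream.start_t,
                       stream.long_axis)
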