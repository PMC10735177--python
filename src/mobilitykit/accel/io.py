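"""CSV readers/writers for raw accelerometer streams and epoch tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import AccelStream, EpochSeries


def read_accel_csv(path, rate_hz: float | None = None, placement: str = "wrist",
                   long_axis: int = 0) -> AccelStream:
    """Read a raw stream from CSV with columns ``t, ax, ay, az`` (t in epoch
    seconds) or ``i, ax, ay, az`` (sample index; requires ``rate_hz``).
    When ``t`` is present and ``rate_hz`` is None the rate is inferred from
    the median sampling interval."""
    df = pd.read_csv(path)
    data = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if "t" in df:
        t = df["t"].to_numpy(dtype=float)
        if rate_hz is None:
            if len(t) < 2:
                raise ValueError("cannot infer rate from fewer than 2 samples")
            rate_hz = 1.0 / float(np.median(np.diff(t)))
        start_t = float(t[0]) if len(t) else 0.0
    else:
        if rate_hz is None:
            raise ValueError("sample-index CSV requires rate_hz")
        start_t = 0.0
    return AccelStream(round(rate_hz, 6), data, placement, start_t, long_axis)


def write_accel_csv(stream: AccelStream, path) -> None:
    pd.DataFrame({"t": stream.times,
                  "ax": stream.data[:, 0],
                  "ay": stream.data[:, 1],
                  "az": stream.data[:, 2]}).to_csv(path, index=False)


def write_epoch_csv(epochs: EpochSeries, path) -> None:
    epochs.to_frame().to_csv(path, index=False)
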