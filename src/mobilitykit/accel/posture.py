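"""Thigh-inclination posture classification (sitting/lying vs standing).

A low-pass filter isolates the gravity component; the thigh inclination is
the angle between the longitudinal (hip-to-knee) axis and vertical. With the
thigh vertical (standing) gravity loads the longitudinal axis and the
inclination is small; seated or lying, the thigh is near horizontal and the
inclination approaches 90°. Epochs with appreciable movement (activity
counts at or above the movement threshold) are stepping and inherit the
standing class.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .counts import COUNTS_RATE_HZ, compute_counts
from .resample import resample
from .types import AccelStream, PostureParams, EPOCH_S


def thigh_inclination_deg(stream: AccelStream,
                          params: PostureParams = PostureParams()) -> np.ndarray:
    """Per-sample thigh inclination from vertical, degrees in [0, 90]."""
    sos = signal.butter(2, params.gravity_lowpass_hz, btype="lowpass",
                        fs=stream.rate_hz, output="sos")
    zi = signal.sosfilt_zi(sos)[:, :, None] * stream.data[0][None, None, :]
    grav, _ = signal.sosfilt(sos, stream.data, axis=0, zi=zi)
    norm = np.linalg.norm(grav, axis=1)
    norm[norm == 0] = np.nan
    cos_incl = np.abs(grav[:, stream.long_axis]) / norm
    return np.degrees(np.arccos(np.clip(cos_incl, -1.0, 1.0)))


def classify_posture(stream: AccelStream,
                     params: PostureParams = PostureParams(),
                     epoch_s: float = EPOCH_S) -> np.ndarray:
    """Posture label per epoch for a thigh-worn stream.

    Low-movement epochs are "standing" when the mean inclination is below
    the standing angle threshold (default 45° from vertical) and
    "sitting_lying" otherwise; high-movement (stepping) epochs are
    "standing". Epochs whose gravity vector vanishes are "unknown".
    """
    if stream.placement != "thigh":
        raise ValueError("posture classification requires a thigh-worn stream; "
                         f"got placement={stream.placement!r}")
    incl = thigh_inclination_deg(stream, params)
    work = stream if stream.rate_hz == COUNTS_RATE_HZ else resample(stream, COUNTS_RATE_HZ)
    epochs = compute_counts(work, epoch_s=epoch_s)
    n_ep = epochs.n_epochs
    per_ep = int(epoch_s * stream.rate_hz)
    labels = np.full(n_ep, "unknown", dtype=object)
    for k in range(n_ep):
        seg = incl[k * per_ep:(k + 1) * per_ep]
        seg = seg[~np.isnan(seg)]
        if seg.size == 0:
            continue
        if epochs.vm[k] >= params.movement_threshold_counts:
            labels[k] = "standing"
        else:
            labels[k] = "standing" if float(np.mean(seg)) < params.standing_angle_deg \
                else "sitting_lying"
    return labels


def trim_task_window(start_t: float, end_t: float,
                     trim_s: float = PostureParams().task_trim_s):
    """Drop the first and last ``trim_s`` seconds of a labeled task window
    (default 45 s) to exclude transitions and clock error at the edges."""
    t0, t1 = start_t + trim_s, end_t - trim_s
    if t1 <= t0:
        raise ValueError("task window shorter than twice the trim")
    return t0, t1
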