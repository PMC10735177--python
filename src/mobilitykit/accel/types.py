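"""Containers and parameter blocks for the accelerometry pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

EPOCH_S = 60.0
GRAVITY_G = 1.0


@dataclass
class AccelStream:
    """Uniformly sampled tri-axial acceleration in g.

    ``data`` is (n, 3); sample i is at time ``start_t + i / rate_hz``.
    ``placement`` is "wrist" or "thigh"; for thigh wear ``long_axis`` is the
    column index of the longitudinal (hip-to-knee) axis.
    """

    rate_hz: float
    data: np.ndarray
    placement: str = "wrist"
    start_t: float = 0.0
    long_axis: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("data must be (n, 3)")
        if self.placement not in ("wrist", "thigh"):
            raise ValueError(f"unknown placement {self.placement!r}")

    def __len__(self):
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return max(len(self) - 1, 0) / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_t + np.arange(len(self)) / self.rate_hz

    def vector_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=1)


@dataclass
class EpochSeries:
    """Per-60 s epoch summaries: per-axis counts, vector magnitude, and the
    wear / intensity / posture labels derived from them."""

    start_t: float
    counts: np.ndarray  # (n_epochs, 3) integer counts
    vm: np.ndarray  # Euclidean norm of the per-axis counts
    wear: Optional[np.ndarray] = None  # bool
    intensity: Optional[np.ndarray] = None  # "sedentary"|"non-sedentary", wear only
    posture: Optional[np.ndarray] = None  # "sitting_lying"|"standing"|"unknown"
    epoch_s: float = EPOCH_S
    partial_last: bool = False  # last epoch covers less than epoch_s

    @property
    def n_epochs(self) -> int:
        return len(self.vm)

    @property
    def times(self) -> np.ndarray:
        return self.start_t + np.arange(self.n_epochs) * self.epoch_s

    def to_frame(self) -> pd.DataFrame:
        d = {"t": self.times, "counts_x": self.counts[:, 0],
             "counts_y": self.counts[:, 1], "counts_z": self.counts[:, 2],
             "vm": self.vm}
        for name in ("wear", "intensity", "posture"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        return pd.DataFrame(d)


@dataclass(frozen=True)
class IntensityParams:
    """Wrist VM cut-point separating sedentary from non-sedentary epochs."""

    sedentary_cutoff: float = 2860.0

    def __post_init__(self):
        if self.sedentary_cutoff <= 0:
            raise ValueError("sedentary_cutoff must be positive")


@dataclass(frozen=True)
class WearParams:
    """Non-wear rule: a window of ≥``nonwear_window_min`` minutes of zero
    counts is non-wear, tolerating interruptions of up to ``allowance_min``
    nonzero minutes each flanked by ≥``flank_min`` minutes of zeros."""

    nonwear_window_min: int = 90
    allowance_min: int = 2
    flank_min: int = 30
    min_valid_day_h: float = 8.0

    def __post_init__(self):
        if not (0 < self.allowance_min < self.nonwear_window_min):
            raise ValueError("allowance must be positive and below the window")
        if self.flank_min <= 0 or self.min_valid_day_h <= 0:
            raise ValueError("flank and valid-day thresholds must be positive")


@dataclass(frozen=True)
class PostureParams:
    gravity_lowpass_hz: float = 0.5
    standing_angle_deg: float = 45.0
    # VM counts/epoch above which the wearer is stepping rather than
    # stationary; must exceed fidgeting (~hundreds) and undercut walking
    # (~10,000+)
    movement_threshold_counts: float = 2000.0
    task_trim_s: float = 45.0

    def __post_init__(self):
        if not (0 < self.standing_angle_deg < 90):
            raise ValueError("standing_angle_deg must be in (0, 90)")
        if self.gravity_lowpass_hz <= 0:
            raise ValueError("gravity_lowpass_hz must be positive")
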