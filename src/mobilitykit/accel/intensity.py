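"""Sedentary vs non-sedentary classification from VM counts per minute."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import IntensityParams


def classify_intensity(vm: np.ndarray, params: IntensityParams = IntensityParams(),
                       wear: np.ndarray | None = None) -> np.ndarray:
    """Label each epoch: sedentary iff VM counts fall *below* the cut-point
    (default 2,860/min; a VM of exactly 2,860 is non-sedentary). Non-wear
    epochs, when a wear mask is given, are labeled "nonwear"."""
    vm = np.asarray(vm, dtype=float)
    labels = np.where(vm < params.sedentary_cutoff, "sedentary", "non-sedentary").astype(object)
    if wear is not None:
        labels[~np.asarray(wear, dtype=bool)] = "nonwear"
    return labels


@dataclass
class IntensityMinutes:
    sedentary_min: float
    non_sedentary_min: float


def intensity_minutes(labels: np.ndarray, epoch_s: float = 60.0) -> IntensityMinutes:
    """Minutes per intensity class over the labeled epochs (wear only)."""
    labels = np.asarray(labels, dtype=object)
    f = epoch_s / 60.0
    return IntensityMinutes(float(np.sum(labels == "sedentary")) * f,
                            float(np.sum(labels == "non-sedentary")) * f)
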