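"""Device-agreement statistics for paired measurements.

Implements the standard method-comparison toolkit: Bland–Altman bias with
95% limits of agreement, percent agreement of a test device against a
reference, Spearman rank correlation, and paired difference tests with an
automatic parametric/non-parametric gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

ALPHA = 0.05


@dataclass
class PairedMeasurements:
    """Same-unit values of one measure from two methods, paired by
    participant-day or task. ``a`` is the reference method."""

    a: np.ndarray
    b: np.ndarray
    measure: str = ""
    unit: str = ""

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired values must be equal-length 1-D arrays")
        if np.isnan(self.a).any() or np.isnan(self.b).any():
            raise ValueError("missing pairs are not allowed; drop them first")

    def __len__(self):
        return len(self.a)

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


def bland_altman(pairs: PairedMeasurements) -> BlandAltman:
    """Mean difference (bias) and 95% limits of agreement bias ± 1.96·SD of
    the paired differences (sample SD, n−1). Also returns the per-pair
    (mean, difference) coordinates for plotting."""
    if len(pairs) < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs (SD undefined)")
    d = pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd,
                       (pairs.a + pairs.b) / 2.0, d)


def bland_altman_plot(res: BlandAltman, ax=None, title: str = ""):
    """Mean-difference scatter with bias and limit-of-agreement lines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(res.means, res.diffs, s=18, alpha=0.7)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("Mean of methods")
    ax.set_ylabel("Difference (reference − test)")
    if title:
        ax.set_title(title)
    return ax


@dataclass
class PercentAgreement:
    raw_mean_pct: float  # mean of (test/reference)·100; can exceed 100
    symmetric_pct: float  # mean of 100 − |ratio·100 − 100|; folds over-reporting
    n_used: int
    n_excluded: int


def percent_agreement(pairs: PairedMeasurements) -> PercentAgreement:
    """Per-pair (test/reference)×100, averaged.

    Reported two ways: the raw mean ratio, which exceeds 100 when the test
    device over-reports, and a symmetrized agreement that folds deviations on
    either side (100 − |ratio − 100|, floored at 0). Pairs with a zero
    reference are excluded with a warning."""
    ref, test = pairs.a, pairs.b
    ok = ref > 0
    n_exc = int(np.sum(~ok))
    if n_exc:
        warnings.warn(f"percent_agreement: excluded {n_exc} pair(s) with "
                      "non-positive reference value")
    if not ok.any():
        raise ValueError("no pairs with positive reference value")
    ratio = test[ok] / ref[ok] * 100.0
    sym = np.maximum(100.0 - np.abs(ratio - 100.0), 0.0)
    return PercentAgreement(float(np.mean(ratio)), float(np.mean(sym)),
                            int(ok.sum()), n_exc)


@dataclass
class PairedTest:
    method: str  # "t" | "wilcoxon" | "none"
    statistic: float
    p_value: float
    significant: bool


def paired_tests(pairs: PairedMeasurements, normality: str = "auto",
                 alpha: float = ALPHA) -> PairedTest:
    """Paired t-test for normally distributed differences, Wilcoxon
    signed-rank otherwise. ``normality='auto'`` gates on a Shapiro–Wilk test
    of the differences at α=0.05; all-zero differences are reported as
    no-difference (p = 1)."""
    d = pairs.differences
    if len(d) < 2:
        raise ValueError("paired tests need at least 2 pairs")
    if np.all(d == 0):
        return PairedTest("none", 0.0, 1.0, False)
    if normality == "auto":
        # Shapiro is undefined for constant input; constant nonzero shift is
        # as non-normal as it gets -> Wilcoxon
        if np.ptp(d) == 0:
            use_t = False
        else:
            use_t = stats.shapiro(d).pvalue >= alpha
    elif normality == "t":
        use_t = True
    elif normality == "wilcoxon":
        use_t = False
    else:
        raise ValueError("normality must be auto|t|wilcoxon")
    if use_t:
        res = stats.ttest_rel(pairs.a, pairs.b)
        return PairedTest("t", float(res.statistic), float(res.pvalue),
                          bool(res.pvalue < alpha))
    res = stats.wilcoxon(pairs.a, pairs.b)
    return PairedTest("wilcoxon", float(res.statistic), float(res.pvalue),
                      bool(res.pvalue < alpha))


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    defined: bool


def spearman_rho(pairs: PairedMeasurements) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties; flagged
    undefined (rho = nan) when either series is constant."""
    if len(pairs) < 3:
        raise ValueError("spearman_rho needs at least 3 pairs")
    if np.ptp(pairs.a) == 0 or np.ptp(pairs.b) == 0:
        return SpearmanResult(float("nan"), float("nan"), False)
    res = stats.spearmanr(pairs.a, pairs.b)
    return SpearmanResult(float(res.statistic), float(res.pvalue), True)


@dataclass
class AgreementResult:
    """Full agreement summary for one measure and one device pair."""

    measure: str
    n: int
    mean_a: float
    mean_b: float
    bland_altman: BlandAltman
    pct: PercentAgreement
    test: PairedTest
    spearman: Optional[SpearmanResult]


def agreement_summary(pairs: PairedMeasurements,
                      normality: str = "auto") -> AgreementResult:
    """All agreement statistics for one measure at once."""
    sp = spearman_rho(pairs) if len(pairs) >= 3 else None
    try:
        pct = percent_agreement(pairs)
    except ValueError:
        pct = PercentAgreement(float("nan"), float("nan"), 0, len(pairs))
    return AgreementResult(pairs.measure, len(pairs), float(np.mean(pairs.a)),
                           float(np.mean(pairs.b)), bland_altman(pairs), pct,
                           paired_tests(pairs, normality), sp)
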