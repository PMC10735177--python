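import numpy as np
import pytest
from scipy import stats

from mobilitykit.agreement import (PairedMeasurements, bland_altman,
                                   paired_tests, percent_agreement,
                                   spearman_rho, agreement_summary)


def _pm(a, b):
    return PairedMeasurements(np.asarray(a, float), np.asarray(b, float))


# -------------------------------------------------------------- Bland-Altman
def test_identical_methods_zero_bias_zero_loa():
    res = bland_altman(_pm([1, 2, 3], [1, 2, 3]))
    assert res.bias == 0.0
    assert res.loa_low == res.loa_high == 0.0


def test_closed_form_differences_plus_minus_one():
    # differences {1, -1}: mean 0, sample SD sqrt(2)
    res = bland_altman(_pm([2.0, 1.0], [1.0, 2.0]))
    assert res.bias == pytest.approx(0.0, abs=1e-12)
    assert res.loa_high == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-12)
    assert res.loa_low == pytest.approx(-1.96 * np.sqrt(2.0), abs=1e-12)


def test_constant_shift_moves_bias_not_width(rng):
    a = rng.normal(10, 2, 50)
    b = a + rng.normal(0, 1, 50)
    r0 = bland_altman(_pm(a, b))
    r1 = bland_altman(_pm(a + 5.0, b))
    assert r1.bias == pytest.approx(r0.bias + 5.0)
    assert (r1.loa_high - r1.loa_low) == pytest.approx(r0.loa_high - r0.loa_low)


def test_loa_covers_95pct_of_normal_differences(rng):
    a = rng.normal(0, 1, 10_000)
    b = np.zeros_like(a)
    res = bland_altman(_pm(a, b))
    inside = np.mean((res.diffs >= res.loa_low) & (res.diffs <= res.loa_high))
    assert inside == pytest.approx(0.95, abs=0.01)


def test_single_pair_rejected():
    with pytest.raises(ValueError):
        bland_altman(_pm([1.0], [1.0]))


# --------------------------------------------------------- percent agreement
def test_equal_methods_100_percent():
    res = percent_agreement(_pm([5, 8, 2], [5, 8, 2]))
    assert res.raw_mean_pct == pytest.approx(100.0)
    assert res.symmetric_pct == pytest.approx(100.0)


def test_underreporting_ratio():
    a = np.array([10.0, 20.0, 50.0])
    res = percent_agreement(_pm(a, 0.8 * a))
    assert res.raw_mean_pct == pytest.approx(80.0)
    assert res.symmetric_pct == pytest.approx(80.0)


def test_over_and_under_fold_symmetrically():
    res = percent_agreement(_pm([10.0, 10.0], [9.0, 11.0]))
    assert res.raw_mean_pct == pytest.approx(100.0)
    assert res.symmetric_pct == pytest.approx(90.0)


def test_scale_invariance(rng):
    a = rng.uniform(1, 10, 30)
    b = rng.uniform(1, 10, 30)
    r1 = percent_agreement(_pm(a, b))
    r2 = percent_agreement(_pm(7.3 * a, 7.3 * b))
    assert r1.raw_mean_pct == pytest.approx(r2.raw_mean_pct)
    assert r1.symmetric_pct == pytest.approx(r2.symmetric_pct)


def test_zero_reference_excluded_with_warning():
    with pytest.warns(UserWarning):
        res = percent_agreement(_pm([0.0, 10.0], [5.0, 10.0]))
    assert res.n_used == 1
    assert res.n_excluded == 1


# --------------------------------------------------------------- paired tests
def test_identical_pairs_report_no_difference():
    res = paired_tests(_pm([1, 2, 3], [1, 2, 3]))
    assert res.method == "none"
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert not res.significant


def test_type_one_error_near_alpha():
    r = np.random.default_rng(99)
    rejections = 0
    reps = 400
    for _ in range(reps):
        a = r.normal(0, 1, 100)
        b = a + r.normal(0, 1, 100)
        if paired_tests(_pm(a, b)).significant:
            rejections += 1
    assert rejections / reps == pytest.approx(0.05, abs=0.03)


def test_power_against_constant_shift():
    r = np.random.default_rng(7)
    rejections = 0
    for _ in range(100):
        a = r.normal(0, 1, 30)
        b = a + 1.0 + r.normal(0, 1, 30)  # 1 SD shift
        if paired_tests(_pm(a, b)).significant:
            rejections += 1
    assert rejections >= 90


def test_nonnormal_differences_use_wilcoxon(rng):
    a = rng.exponential(1.0, 200) ** 3
    b = np.zeros_like(a)
    res = paired_tests(_pm(a, b))
    assert res.method == "wilcoxon"


# ------------------------------------------------------------------ spearman
def test_monotone_transform_gives_rho_one(rng):
    a = rng.uniform(0, 10, 50)
    res = spearman_rho(_pm(a, np.exp(a)))
    assert res.rho == pytest.approx(1.0)
    res = spearman_rho(_pm(a, -a))
    assert res.rho == pytest.approx(-1.0)


def test_independent_series_rho_near_zero(rng):
    res = spearman_rho(_pm(rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000)))
    assert abs(res.rho) < 0.1


def test_constant_series_flagged_undefined():
    res = spearman_rho(_pm([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
    assert not res.defined
    assert np.isnan(res.rho)


# ------------------------------------------------------- permutation property
def test_statistics_invariant_to_pair_order(rng):
    a = rng.normal(5, 2, 40)
    b = a + rng.normal(0.5, 1, 40)
    perm = rng.permutation(40)
    s1 = agreement_summary(_pm(a, b))
    s2 = agreement_summary(_pm(a[perm], b[perm]))
    assert s1.bland_altman.bias == pytest.approx(s2.bland_altman.bias)
    assert s1.bland_altman.loa_high == pytest.approx(s2.bland_altman.loa_high)
    assert s1.pct.raw_mean_pct == pytest.approx(s2.pct.raw_mean_pct)
    assert s1.spearman.rho == pytest.approx(s2.spearman.rho)
    assert s1.test.p_value == pytest.approx(s2.test.p_value)
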