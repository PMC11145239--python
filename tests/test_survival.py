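"""Kaplan-Meier estimation, log-rank test, cutoff search, permutation guard.

Hand-worked product-limit and hypergeometric tallies serve as primary
oracles; lifelines provides an independent implementation cross-check.
"""

import math

import numpy as np
import pytest

from vascsig import (
    ConfigurationError,
    EstimationError,
    SearchError,
    km_estimate,
    logrank_test,
    null_calibration,
    optimize_cutoff,
)


# ------------------------------------------------------------------- KM


def test_km_uncensored_steps():
    curve = km_estimate([10, 20, 30, 40], [1, 1, 1, 1])
    np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
    assert curve.median_survival == 20


def test_km_hand_worked_with_censoring():
    # deaths at 10 and 20, censoring at 15:
    # S(10) = 1 - 1/3 = 2/3; at 15 censored (no drop); S(20) = 2/3 * (1 - 1/1) = 0
    curve = km_estimate([10, 15, 20], [1, 0, 1])
    np.testing.assert_allclose(curve.survival, [2 / 3, 2 / 3, 0.0], atol=1e-6)
    np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])
    assert curve.median_survival == 20


def test_km_all_censored_never_drops():
    curve = km_estimate([5, 10, 15], [0, 0, 0])
    np.testing.assert_allclose(curve.survival, [1.0, 1.0, 1.0])
    assert math.isnan(curve.median_survival)


def test_km_ties_deaths_before_censorings():
    # at t=10: 1 death and 1 censor among 3 at risk -> S = 1 - 1/3
    curve = km_estimate([10, 10, 20], [1, 0, 1])
    np.testing.assert_allclose(curve.survival, [2 / 3, 0.0], atol=1e-9)
    np.testing.assert_array_equal(curve.at_risk, [3, 1])


def test_km_equals_empirical_survival_without_censoring(rng):
    t = rng.exponential(100, size=50).round(1)
    curve = km_estimate(t, np.ones(50))
    for u, s in zip(curve.times, curve.survival):
        assert s == pytest.approx((t > u).mean(), abs=1e-12)


def test_km_matches_lifelines(rng):
    lifelines = pytest.importorskip("lifelines")
    t = rng.exponential(300, size=80).round()
    e = rng.integers(0, 2, size=80)
    if e.sum() == 0:
        e[0] = 1
    curve = km_estimate(t, e)
    kmf = lifelines.KaplanMeierFitter().fit(t, e)
    ours = dict(zip(curve.times, curve.survival))
    for u, s in kmf.survival_function_["KM_estimate"].items():
        if u in ours:
            assert ours[u] == pytest.approx(s, abs=1e-10)
    med = kmf.median_survival_time_
    if math.isinf(med):
        assert math.isnan(curve.median_survival)
    else:
        assert curve.median_survival == med


def test_km_no_valid_records_is_error():
    with pytest.raises(EstimationError):
        km_estimate([np.nan], [np.nan])


# -------------------------------------------------------------- log-rank


def test_logrank_identical_groups_is_null():
    t = [5, 10, 15, 20]
    e = [1, 1, 0, 1]
    res = logrank_test(t, e, t, e)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_hand_worked_tally():
    # group A: deaths at 1, 2, 3; group B: deaths at 4, 5, 6
    res = logrank_test([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
    # independent tally over the 6 event times
    ta = np.array([1.0, 2, 3])
    tb = np.array([4.0, 5, 6])
    t = np.sort(np.concatenate([ta, tb]))
    o_minus_e = v = 0.0
    for u in t:
        na = (ta >= u).sum()
        nb = (tb >= u).sum()
        n = na + nb
        d = 1
        da = 1 if u in ta else 0
        o_minus_e += da - d * na / n
        if n > 1:
            v += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    expected = o_minus_e**2 / v
    assert res.statistic == pytest.approx(expected, rel=1e-12)
    assert res.p_value < 0.05


def test_logrank_label_swap_invariance(rng):
    ta, tb = rng.exponential(100, 20), rng.exponential(200, 25)
    ea, eb = rng.integers(0, 2, 20), np.ones(25)
    r1 = logrank_test(ta, ea, tb, eb)
    r2 = logrank_test(tb, eb, ta, ea)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)


def test_logrank_invariant_under_monotone_time_transform(rng):
    ta, tb = rng.exponential(100, 15), rng.exponential(50, 15)
    ea = rng.integers(0, 2, 15)
    eb = rng.integers(0, 2, 15)
    ea[0] = eb[0] = 1
    r1 = logrank_test(ta, ea, tb, eb)
    r2 = logrank_test(np.sqrt(ta), ea, np.sqrt(tb), eb)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)


def test_logrank_matches_lifelines(rng):
    stats_mod = pytest.importorskip("lifelines.statistics")
    ta, tb = rng.exponential(100, 30).round(), rng.exponential(60, 40).round()
    ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 40)
    ea[0] = eb[0] = 1
    ours = logrank_test(ta, ea, tb, eb)
    ref = stats_mod.logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
    assert ours.p_value == pytest.approx(ref.p_value, rel=1e-6)


def test_logrank_zero_events_is_error():
    with pytest.raises(EstimationError):
        logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


# -------------------------------------------------------- cutoff search


def _break_cohort(rng, n=120, break_at=5, hr=3.0):
    scores = rng.integers(0, 11, size=n)
    lam = np.where(scores > break_at, hr / 400.0, 1 / 400.0)
    t = rng.exponential(1 / lam)
    c = rng.exponential(1500, size=n)
    return scores, np.minimum(t, c), (t <= c).astype(float)


def test_optimize_cutoff_matches_exhaustive_scan(rng):
    scores, t, e = _break_cohort(rng)
    res = optimize_cutoff(scores, t, e, min_group_frac=0.1)
    # independent brute-force loop
    best = None
    n = len(scores)
    for c in range(int(scores.min()), int(scores.max())):
        high = scores > c
        if high.sum() < 0.1 * n or (~high).sum() < 0.1 * n:
            continue
        p = logrank_test(t[high], e[high], t[~high], e[~high]).p_value
        if best is None or p < best[0]:
            best = (p, c)
    assert (res.p_value, res.chosen_cutoff) == best
    assert res.all_candidate_p[res.chosen_cutoff] == res.p_value


def test_optimize_cutoff_reported_p_equals_rerun(rng):
    scores, t, e = _break_cohort(rng)
    res = optimize_cutoff(scores, t, e)
    high = scores > res.chosen_cutoff
    rerun = logrank_test(t[high], e[high], t[~high], e[~high])
    assert res.p_value == rerun.p_value
    assert res.statistic == rerun.statistic


def test_optimize_cutoff_equal_scores_is_error(rng):
    with pytest.raises(SearchError):
        optimize_cutoff([3, 3, 3], [1.0, 2.0, 3.0], [1, 1, 1])


def test_high_score_group_has_shorter_median_survival(rng):
    worse = 0
    reps = 100
    for _ in range(reps):
        scores, t, e = _break_cohort(rng, hr=2.0)
        high = scores > 5
        mh = km_estimate(t[high], e[high]).median_survival
        ml = km_estimate(t[~high], e[~high]).median_survival
        if not (math.isnan(mh) or math.isnan(ml)) and mh <= ml:
            worse += 1
    assert worse / reps > 0.9


def test_null_calibration_orders_and_validates(rng):
    scores = rng.integers(0, 11, size=80)
    t = rng.exponential(400, 80)
    e = np.ones(80)
    res = null_calibration(scores, t, e, n_permutations=100, seed=1)
    assert res.adjusted_p >= res.observed_min_p
    assert 0 < res.adjusted_p <= 1
    with pytest.raises(ConfigurationError):
        null_calibration(scores, t, e, n_permutations=10)
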