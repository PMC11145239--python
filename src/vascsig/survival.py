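"""Kaplan-Meier estimation, two-group log-rank test, and score-cutoff search.

The product-limit estimator and the log-rank test are implemented directly
on sorted event tables (deaths precede censorings at tied times). The cutoff
search scans every integer score threshold whose two groups are large enough
and keeps the one with the smallest log-rank p-value — a maximally selected
statistic, whose optimism can be quantified with a permutation calibration
(:func:`null_calibration`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError, EstimationError, SearchError


@dataclass
class KMCurve:
    """Product-limit survival curve over the distinct observed times."""

    times: np.ndarray  # distinct observed times, increasing
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray  # n at risk just before each time
    n_events: np.ndarray  # deaths at each time
    n_censored: np.ndarray  # censorings at each time
    median_survival: float  # nan when S never reaches 0.5

    @property
    def event_times(self) -> np.ndarray:
        return self.times[self.n_events > 0]

    @property
    def censor_times(self) -> np.ndarray:
        return np.repeat(self.times, self.n_censored)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "n_censored": self.n_censored,
            }
        )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


@dataclass
class CutoffResult:
    chosen_cutoff: int
    p_value: float
    statistic: float
    group_sizes: tuple[int, int]  # (n above cutoff, n at/below cutoff)
    median_survival_per_group: tuple[float, float]  # (above, at/below)
    all_candidate_p: dict[int, float] = field(default_factory=dict)


@dataclass
class NullCalibrationResult:
    observed_min_p: float
    adjusted_p: float
    n_permutations: int
    permutation_min_p: np.ndarray


def _clean(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.shape != e.shape:
        raise DataError("times and events must have equal length")
    valid = np.isfinite(t) & np.isfinite(e)
    t, e = t[valid], e[valid]
    if t.size and t.min() < 0:
        raise DataError("negative survival time")
    if t.size and (set(np.unique(e)) - {0.0, 1.0}):
        raise DataError("event flags must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``S(t) = prod over event times t_i <= t of (1 - d_i / n_i)``. The median
    is the smallest observed time with S(t) <= 0.5, NaN if S never gets
    there. Records with missing time or event flag are dropped before
    estimation; at tied times deaths are processed before censorings.
    """
    t, e = _clean(times, events)
    if t.size == 0:
        raise EstimationError("no valid survival records")
    uniq = np.unique(t)
    d = np.array([np.sum((t == u) & (e == 1)) for u in uniq])
    c = np.array([np.sum((t == u) & (e == 0)) for u in uniq])
    removed = np.concatenate([[0], np.cumsum(d + c)[:-1]])
    n_at_risk = t.size - removed
    with np.errstate(invalid="ignore"):
        factors = np.where(d > 0, 1.0 - d / n_at_risk, 1.0)
    surv = np.cumprod(factors)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(uniq[below[0]]) if below.size else math.nan
    return KMCurve(
        times=uniq,
        survival=surv,
        at_risk=n_at_risk,
        n_events=d,
        n_censored=c,
        median_survival=median,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test with chi-square (1 df) reference.

    At each distinct event time, the observed deaths in group A are compared
    with the hypergeometric expectation given the margins; the squared summed
    deviation over the summed variance is the statistic.
    """
    ta, ea = _clean(times_a, events_a)
    tb, eb = _clean(times_b, events_b)
    if ta.size == 0 or tb.size == 0:
        raise EstimationError("both groups need at least one valid record")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])
    if e.sum() == 0:
        raise EstimationError("no events in either group; log-rank undefined")

    event_times = np.unique(t[e == 1])
    # at-risk counts just before each event time (>= comparisons)
    n_a = (ta[np.newaxis, :] >= event_times[:, np.newaxis]).sum(axis=1)
    n_tot = (t[np.newaxis, :] >= event_times[:, np.newaxis]).sum(axis=1)
    d_a = ((ta[np.newaxis, :] == event_times[:, np.newaxis]) & (ea == 1)).sum(axis=1)
    d_tot = ((t[np.newaxis, :] == event_times[:, np.newaxis]) & (e == 1)).sum(axis=1)

    expected = d_tot * n_a / n_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (
            d_tot
            * (n_a / n_tot)
            * (1.0 - n_a / n_tot)
            * (n_tot - d_tot)
            / np.maximum(n_tot - 1.0, 1.0)
        )
    var = np.where(n_tot > 1, var, 0.0)
    v_sum = var.sum()
    if v_sum <= 0:
        raise EstimationError("log-rank variance is zero; groups not comparable")
    statistic = float((d_a - expected).sum() ** 2 / v_sum)
    p_value = float(stats.chi2.sf(statistic, df=1))
    return LogrankResult(statistic=statistic, p_value=p_value)


def optimize_cutoff(
    scores,
    times,
    events,
    min_group_frac: float = 0.1,
) -> CutoffResult:
    """Find the integer score cutoff with the smallest log-rank p-value.

    Every cutoff c is evaluated by splitting into score > c vs score <= c;
    admissible cutoffs leave each group with at least ``min_group_frac`` of
    the valid records. Ties in p are broken toward the smaller cutoff.
    Records with missing time/event are excluded before the scan.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if not (s.shape == t.shape == e.shape):
        raise DataError("scores, times, events must have equal length")
    valid = np.isfinite(t) & np.isfinite(e) & np.isfinite(s)
    s, t, e = s[valid], t[valid], e[valid]
    if np.unique(s).size < 2:
        raise SearchError("need at least 2 distinct score values")
    n = s.size
    min_size = min_group_frac * n
    lo, hi = int(math.floor(s.min())), int(math.ceil(s.max()))

    candidates: dict[int, float] = {}
    best: tuple[float, int] | None = None
    best_stat = math.nan
    for c in range(lo, hi):
        high = s > c
        n_high, n_low = int(high.sum()), int((~high).sum())
        if n_high < min_size or n_low < min_size or n_high == 0 or n_low == 0:
            continue
        try:
            res = logrank_test(t[high], e[high], t[~high], e[~high])
        except EstimationError:
            continue
        candidates[c] = res.p_value
        if best is None or res.p_value < best[0]:
            best = (res.p_value, c)
            best_stat = res.statistic
    if best is None:
        raise SearchError(
            "no admissible cutoff (all splits violate the minimum group size)"
        )
    p_value, chosen = best
    high = s > chosen
    med_high = km_estimate(t[high], e[high]).median_survival
    med_low = km_estimate(t[~high], e[~high]).median_survival
    return CutoffResult(
        chosen_cutoff=chosen,
        p_value=p_value,
        statistic=best_stat,
        group_sizes=(int(high.sum()), int((~high).sum())),
        median_survival_per_group=(med_high, med_low),
        all_candidate_p=candidates,
    )


def null_calibration(
    scores,
    times,
    events,
    n_permutations: int = 1000,
    min_group_frac: float = 0.1,
    seed: int | None = None,
) -> NullCalibrationResult:
    """Permutation-calibrate the optimized cutoff's minimum p-value.

    The cutoff search selects the best of many correlated tests, so its
    minimum p-value is optimistic. Permuting the survival records against the
    scores and repeating the search yields the null distribution of that
    minimum; the adjusted p-value is the (add-one) fraction of permutation
    minima at or below the observed minimum.
    """
    if n_permutations < 100:
        raise ConfigurationError("need at least 100 permutations")
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    observed = optimize_cutoff(s, t, e, min_group_frac=min_group_frac)
    rng = np.random.default_rng(seed)
    minima = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(t.size)
        try:
            res = optimize_cutoff(s, t[perm], e[perm], min_group_frac=min_group_frac)
            minima[i] = res.p_value
        except SearchError:
            minima[i] = 1.0
    adjusted = (1.0 + np.sum(minima <= observed.p_value)) / (n_permutations + 1.0)
    return NullCalibrationResult(
        observed_min_p=observed.p_value,
        adjusted_p=float(adjusted),
        n_permutations=n_permutations,
        permutation_min_p=minima,
    )
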