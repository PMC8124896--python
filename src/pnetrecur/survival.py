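"""Right-censored survival kernel: product-limit curves, medians, log-rank.

Implements the Kaplan–Meier product-limit estimator with Greenwood variance,
median survival with a Brookmeyer–Crowley style confidence interval on the
log(−log S) scale, and the k-sample log-rank test with hypergeometric
variance under ties.  These are written directly on numpy (no survival
library) because every other component of the package — in particular the
minimum-p cut-point scan, which calls the log-rank test once per candidate
threshold and once per permutation — builds on them.

Conventions: times are continuous months; ties between a censoring and an
event at the same time are resolved as censored-after-event, so a
censored-at-event-time observation remains in the risk set for that time's
factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "MedianEstimate",
    "LogRankResult",
    "km_fit",
    "km_median_ci",
    "logrank_test",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate on the grid of distinct event times.

    ``survival[i]`` is S(t) just after ``times[i]``; S is 1 before the first
    event time.  ``variance`` is the Greenwood variance of S at each grid
    time.
    """

    times: np.ndarray        # distinct event times, increasing
    at_risk: np.ndarray      # n at risk just before each event time
    events: np.ndarray       # events at each event time
    survival: np.ndarray     # S(t) after each event time
    variance: np.ndarray     # Greenwood Var[S(t)]
    label: str = ""
    n: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "variance": self.variance,
            }
        )


@dataclass(frozen=True)
class MedianEstimate:
    """Median survival time with 95% CI; ``None`` marks an undefined bound."""

    median: Optional[float]
    lower95: Optional[float]
    upper95: Optional[float]
    ci_method: str = "brookmeyer-crowley-loglog"


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray     # per-group observed events
    expected: np.ndarray     # per-group expected events


def _as_time_event(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape or t.size == 0:
        raise ValueError("times and events must be equal-length nonempty 1-d arrays")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    return t, e


def km_fit(times: Sequence[float], events: Sequence[bool], label: str = "") -> SurvivalCurve:
    """Kaplan–Meier product-limit fit.

    At each distinct event time t with n at risk and d events the survival
    estimate is multiplied by (1 − d/n); censored observations at t remain
    at risk for that factor.  Greenwood's formula supplies the variance:
    Var[S(t)] = S(t)^2 · Σ_{t_j ≤ t} d_j / (n_j (n_j − d_j)).
    """
    t, e = _as_time_event(times, events)
    n_total = t.size
    event_times = np.unique(t[e])
    at_risk = np.empty(event_times.size, dtype=np.int64)
    d = np.empty(event_times.size, dtype=np.int64)
    for i, ti in enumerate(event_times):
        at_risk[i] = np.sum(t >= ti)
        d[i] = np.sum((t == ti) & e)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / at_risk
        surv = np.cumprod(frac)
        # Greenwood sum; at n == d the variance term is infinite, S = 0.
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        gw = np.cumsum(terms)
        var = np.where(surv > 0, surv**2 * gw, 0.0)
    return SurvivalCurve(
        times=event_times,
        at_risk=at_risk,
        events=d,
        survival=surv,
        variance=var,
        label=label,
        n=n_total,
    )


def _loglog_z(surv: np.ndarray, var: np.ndarray, q: float = 0.5) -> np.ndarray:
    """Standardised distance of S(t) from q on the log(−log) scale."""
    z = np.full(surv.shape, np.inf)
    ok = (surv > 0) & (surv < 1) & (var > 0) & np.isfinite(var)
    s = surv[ok]
    se = np.sqrt(var[ok]) / (s * np.abs(np.log(s)))
    z[ok] = (np.log(-np.log(s)) - np.log(-np.log(q))) / se
    return z


def km_median_ci(curve: SurvivalCurve, alpha: float = 0.05) -> MedianEstimate:
    """Median survival with a Brookmeyer–Crowley confidence interval.

    The median is the smallest grid time with S(t) ≤ 0.5 (undefined if the
    curve never reaches 0.5).  The CI inverts the pointwise test of
    S(t) = 0.5 on the log(−log S) scale: every grid time whose standardised
    distance from 0.5 is below the normal quantile belongs to the interval.
    An upper bound extending past the last event time is reported undefined.
    """
    surv = curve.survival
    below = np.flatnonzero(surv <= 0.5)
    median = float(curve.times[below[0]]) if below.size else None

    zcrit = stats.norm.ppf(1 - alpha / 2)
    z = _loglog_z(surv, curve.variance)
    inside = np.abs(z) <= zcrit
    # S = 0 contributes to the region's interior only as its right edge;
    # S = 1 (no events yet) never does.
    if not np.any(inside) and median is None:
        return MedianEstimate(None, None, None)
    if np.any(inside):
        first = int(np.flatnonzero(inside)[0])
        last = int(np.flatnonzero(inside)[-1])
        lower = float(curve.times[first])
        upper = float(curve.times[last + 1]) if last + 1 < curve.times.size else None
    else:
        lower = upper = median
    if median is not None and lower is not None and median < lower:
        lower = median
    if median is not None and upper is not None and median > upper:
        upper = None
    return MedianEstimate(median, lower, upper)


def logrank_test(groups: Sequence[tuple]) -> LogRankResult:
    """k-sample log-rank test.

    ``groups`` is a sequence of ``(times, events)`` pairs.  At each distinct
    pooled event time the per-group event count is compared with its
    hypergeometric expectation given the risk sets; the variance-covariance
    of the observed-minus-expected vector uses the multivariate
    hypergeometric form, which handles tied events.  The statistic is the
    quadratic form over the first k−1 groups and is referred to a chi-square
    distribution with k−1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ts, es, labels = [], [], []
    for g, (times, events) in enumerate(groups):
        t, e = _as_time_event(times, events)
        ts.append(t)
        es.append(e)
        labels.append(np.full(t.size, g))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(labels)
    k = len(groups)
    if not np.any(e):
        raise ValueError("log-rank undefined: no events in any group")

    event_times = np.unique(t[e])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for ti in event_times:
        at_risk_mask = t >= ti
        n_j = np.array([np.sum(at_risk_mask & (g == grp)) for grp in range(k)], dtype=float)
        n_tot = n_j.sum()
        event_mask = (t == ti) & e
        d_j = np.array([np.sum(event_mask & (g == grp)) for grp in range(k)], dtype=float)
        d_tot = d_j.sum()
        observed += d_j
        expected += d_tot * n_j / n_tot
        if n_tot > 1:
            scale = d_tot * (n_tot - d_tot) / (n_tot - 1)
            p_j = n_j / n_tot
            cov += scale * (np.diag(p_j) - np.outer(p_j, p_j))

    u = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    if np.allclose(v, 0):
        statistic = 0.0
    else:
        statistic = float(u @ np.linalg.pinv(v) @ u)
        statistic = max(statistic, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return LogRankResult(statistic=statistic, df=df, p_value=p,
                         observed=observed, expected=expected)
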