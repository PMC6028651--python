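"""Kaplan-Meier estimation and the two-sample log-rank test.

The product-limit estimator treats patients censored exactly at an event
time as still at risk for that event. Confidence intervals are Greenwood
variance on the linear scale, clipped to [0, 1] — this reproduces interval
bounds like 100.0-100.0% or 0.0-40.2% that transformed intervals cannot.
The log-rank test is the standard 1-degree-of-freedom observed-vs-expected
comparison over the pooled risk sets.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import chi2

__all__ = [
    "KMCurve",
    "SurvivalRate",
    "LogRankResult",
    "km_estimate",
    "survival_rate_at",
    "logrank_test",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclasses.dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate after each distinct event time."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk at each event time
    n_events: np.ndarray  # events at each event time
    variance: np.ndarray  # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    max_followup: float  # largest observed time (event or censoring)
    n: int


@dataclasses.dataclass(frozen=True)
class SurvivalRate:
    rate: float
    ci: tuple[float, float]
    extrapolated: bool  # horizon lies beyond the last observed follow-up


@dataclasses.dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    observed: tuple[float, float]  # events per group
    expected: tuple[float, float]


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood-linear 95% CIs."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one patient")
    if len(times) != len(events):
        raise ValueError("times and events length differ")
    if (times < 0).any():
        raise ValueError("negative follow-up times")

    event_times = np.unique(times[events == 1])
    s = 1.0
    green = 0.0
    surv, at_risk, n_ev, var = [], [], [], []
    for t in event_times:
        n_t = int((times >= t).sum())
        d_t = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_t / n_t
        if n_t > d_t:
            green += d_t / (n_t * (n_t - d_t))
            var_t = s**2 * green
        else:
            var_t = 0.0  # curve reaches 0; Greenwood term degenerate
        surv.append(s)
        at_risk.append(n_t)
        n_ev.append(d_t)
        var.append(var_t)

    surv = np.asarray(surv)
    var = np.asarray(var)
    half = _Z95 * np.sqrt(var)
    return KMCurve(
        times=event_times,
        survival=surv,
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
        variance=var,
        ci_lower=np.clip(surv - half, 0.0, 1.0),
        ci_upper=np.clip(surv + half, 0.0, 1.0),
        max_followup=float(times.max()),
        n=len(times),
    )


def survival_rate_at(curve: KMCurve, horizon: float) -> SurvivalRate:
    """Right-continuous step evaluation of the curve at a time horizon."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    idx = np.searchsorted(curve.times, horizon, side="right") - 1
    if idx < 0:
        return SurvivalRate(1.0, (1.0, 1.0), extrapolated=False)
    return SurvivalRate(
        float(curve.survival[idx]),
        (float(curve.ci_lower[idx]), float(curve.ci_upper[idx])),
        extrapolated=horizon > curve.max_followup,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-sample log-rank test (1 df) over the pooled risk sets."""
    ta = np.asarray(times_a, dtype=np.float64)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=np.float64)
    eb = np.asarray(events_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group: no information")

    pooled = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_a = e_a = v = 0.0
    for t in pooled:
        n_a = float((ta >= t).sum())
        n_b = float((tb >= t).sum())
        n_t = n_a + n_b
        d_a = float(((ta == t) & (ea == 1)).sum())
        d_b = float(((tb == t) & (eb == 1)).sum())
        d_t = d_a + d_b
        o_a += d_a
        e_a += d_t * n_a / n_t
        if n_t > 1:
            v += d_t * (n_a / n_t) * (1.0 - n_a / n_t) * (n_t - d_t) / (n_t - 1.0)

    total_events = float(ea.sum() + eb.sum())
    if v <= 0:
        stat = 0.0
    else:
        stat = (o_a - e_a) ** 2 / v
    return LogRankResult(
        statistic=float(stat),
        p_value=float(chi2.sf(stat, df=1)) if stat > 0 else 1.0,
        observed=(float(o_a), float(total_events - o_a)),
        expected=(float(e_a), float(total_events - e_a)),
    )
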