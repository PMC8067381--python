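"""Product-limit survival estimation for time to conception.

Implements the Kaplan-Meier estimator with Greenwood standard errors, the
two-group log-rank test, and the trial's time-origin convention: survival
time runs from the *group's* first insemination day, so the fixed-time-AI
arm (almost all served on one day) can legitimately show a median
conception time of zero.

Cows that conceive contribute an event at ``conception_day - origin``;
cows that do not are right-censored at ``censor_day - origin`` (the end of
the 84-day breeding season).  Durations are floored at zero.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import chi2

from .herd import CowRecord

__all__ = [
    "SurvivalCurve",
    "TimePointEstimate",
    "LogRankResult",
    "group_time_origin",
    "kaplan_meier",
    "survival_from_records",
    "time_point_estimate",
    "median_survival",
    "log_rank_test",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate over the distinct event times of one group."""

    origin_day: float
    times: tuple[float, ...]
    n_at_risk: tuple[int, ...]
    n_events: tuple[int, ...]
    survival: tuple[float, ...]
    se: tuple[float, ...]
    censor_times: tuple[float, ...]

    def __post_init__(self) -> None:
        s = self.survival
        if any(b > a + 1e-12 for a, b in zip(s, s[1:])):
            raise ValueError("survival must be non-increasing")
        if s and not all(-1e-12 <= x <= 1.0 + 1e-12 for x in s):
            raise ValueError("survival must lie in [0, 1]")
        if any(d > n for d, n in zip(self.n_events, self.n_at_risk)):
            raise ValueError("events cannot exceed the risk set")


class TimePointEstimate(NamedTuple):
    cumulative_pregnancy: float
    se: float
    beyond_follow_up: bool = False


class LogRankResult(NamedTuple):
    chi_square: float
    p_value: float


def group_time_origin(records: Sequence[CowRecord]) -> float:
    """Group time origin: the earliest service day over the whole group."""
    days = [r.service_days[0] for r in records if r.service_days]
    if not days:
        raise ValueError("no cow in the group was ever served")
    return min(days)


def kaplan_meier(
    event_times: Sequence[float],
    event_flags: Sequence[bool],
    origin: float = 0.0,
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator with Greenwood standard errors.

    ``event_times`` are absolute days; durations are ``t - origin`` floored
    at zero.  Ties are aggregated; cows censored at an event time stay in
    the risk set for that time's events.  The SE where survival reaches
    exactly zero is reported as 0.
    """
    t = np.asarray(event_times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if t.size == 0:
        raise ValueError("no observations")
    if t.size != e.size:
        raise ValueError("event_times and event_flags lengths differ")
    if np.any(t < origin):
        raise ValueError("event times must be >= origin")
    dur = np.maximum(t - origin, 0.0)

    event_t = np.unique(dur[e])
    times: list[float] = []
    n_at_risk: list[int] = []
    n_events: list[int] = []
    surv: list[float] = []
    se: list[float] = []
    s = 1.0
    gw = 0.0  # running Greenwood sum d / (n (n - d))
    for ti in event_t:
        n = int(np.sum(dur >= ti))
        d = int(np.sum(e & (dur == ti)))
        s *= 1.0 - d / n
        gw += d / (n * (n - d)) if d < n else np.inf
        times.append(float(ti))
        n_at_risk.append(n)
        n_events.append(d)
        surv.append(s)
        se.append(0.0 if s == 0.0 else s * np.sqrt(gw))
    return SurvivalCurve(
        origin_day=float(origin),
        times=tuple(times),
        n_at_risk=tuple(n_at_risk),
        n_events=tuple(n_events),
        survival=tuple(surv),
        se=tuple(se),
        censor_times=tuple(np.sort(dur[~e]).tolist()),
    )


def survival_from_records(
    records: Sequence[CowRecord], origin: float | None = None
) -> SurvivalCurve:
    """Kaplan-Meier curve of time to conception for one treatment group."""
    if origin is None:
        origin = group_time_origin(records)
    times = [r.event_day for r in records]
    flags = [r.pregnant for r in records]
    return kaplan_meier(times, flags, origin)


def time_point_estimate(curve: SurvivalCurve, t: float) -> TimePointEstimate:
    """Cumulative pregnancy (1 - S) and its Greenwood SE at time ``t``.

    Uses the step function value at the last event time <= t.  Beyond the
    last follow-up time the last estimate is returned flagged.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    last_follow_up = max(
        max(curve.times, default=0.0), max(curve.censor_times, default=0.0)
    )
    idx = None
    for i, ti in enumerate(curve.times):
        if ti <= t:
            idx = i
        else:
            break
    if idx is None:
        return TimePointEstimate(0.0, 0.0, beyond_follow_up=t > last_follow_up)
    return TimePointEstimate(
        1.0 - curve.survival[idx], curve.se[idx], beyond_follow_up=t > last_follow_up
    )


def median_survival(curve: SurvivalCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None if survival never falls
    to one half."""
    for ti, s in zip(curve.times, curve.survival):
        if s <= 0.5:
            return ti
    return None


def log_rank_test(
    times_a: Sequence[float],
    flags_a: Sequence[bool],
    times_b: Sequence[float],
    flags_b: Sequence[bool],
    origin_a: float = 0.0,
    origin_b: float = 0.0,
) -> LogRankResult:
    """Two-group log-rank test on conception times.

    At each distinct pooled event time the expected events in group A are
    ``d * nA / n`` with the hypergeometric variance; the statistic is
    ``(sum(oA - eA))^2 / sum(V)`` referred to chi-square(1).  Symmetric
    under group relabelling.
    """
    da = np.maximum(np.asarray(times_a, float) - origin_a, 0.0)
    db = np.maximum(np.asarray(times_b, float) - origin_b, 0.0)
    ea = np.asarray(flags_a, bool)
    eb = np.asarray(flags_b, bool)
    if da.size == 0 or db.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("no events in either group")

    event_times = np.unique(np.concatenate([da[ea], db[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        na = int(np.sum(da >= ti))
        nb = int(np.sum(db >= ti))
        n = na + nb
        d = int(np.sum(ea & (da == ti))) + int(np.sum(eb & (db == ti)))
        oa = int(np.sum(ea & (da == ti)))
        if n == 0:
            continue
        e_a = d * na / n
        o_minus_e += oa - e_a
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var == 0.0:
        return LogRankResult(0.0, 1.0)
    stat = o_minus_e**2 / var
    return LogRankResult(float(stat), float(chi2.sf(stat, df=1)))
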