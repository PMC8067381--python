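"""Interval reproductive metrics and the log-rank power calculation.

Conventions: day 0 is the herd mating start date (MSD); "within N days"
means an event day strictly before N (half-open window [0, N), matching
three 21-day cycles for the 21/42/84-day windows).  The barren proportion
is defined through the Kaplan-Meier curve (1 - cumulative pregnancy at 84
days on the group time origin), which coincides with the raw non-pregnant
fraction when nothing is censored before the end of the season.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .herd import CowRecord
from .survival import survival_from_records, time_point_estimate

__all__ = [
    "GroupSummary",
    "interval_in_calf_rate",
    "submission_rate",
    "conception_rate_first_service",
    "services_per_conception",
    "barren_proportion",
    "summarize_group",
    "schoenfeld_sample_size",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    submission_rate_21: float
    in_calf_21: float
    in_calf_42: float
    in_calf_84: float
    conception_rate_first_service: float | None
    services_per_conception: float | None
    barren_proportion: float
    mean_calving_first_service: float | None
    mean_calving_conception: float | None
    median_msd_conception: float | None

    def __post_init__(self) -> None:
        if not self.in_calf_21 <= self.in_calf_42 <= self.in_calf_84 + 1e-12:
            raise ValueError("interval in-calf rates must be non-decreasing")
        if self.services_per_conception is not None and self.services_per_conception < 1:
            raise ValueError("services per conception cannot be below 1")


def _require(records: Sequence[CowRecord]) -> None:
    if not records:
        raise ValueError("metric undefined for an empty group")


def interval_in_calf_rate(records: Sequence[CowRecord], window_days: float) -> float:
    """Fraction of cows conceiving before ``window_days`` after the MSD."""
    _require(records)
    if window_days <= 0:
        raise ValueError("window must be > 0")
    hits = sum(1 for r in records if r.pregnant and r.conception_day < window_days)
    return hits / len(records)


def submission_rate(records: Sequence[CowRecord], window_days: float = 21.0) -> float:
    """Fraction of cows served at least once before ``window_days``."""
    _require(records)
    if window_days <= 0:
        raise ValueError("window must be > 0")
    hits = sum(1 for r in records if r.service_days and r.service_days[0] < window_days)
    return hits / len(records)


def conception_rate_first_service(records: Sequence[CowRecord]) -> float | None:
    """First-service conceptions over cows served at least once.

    Returns None (undefined) when no cow was ever served.
    """
    _require(records)
    served = [r for r in records if r.service_days]
    if not served:
        return None
    hits = sum(1 for r in served if r.pregnant and r.conception_day == r.service_days[0])
    return hits / len(served)


def services_per_conception(records: Sequence[CowRecord]) -> float | None:
    """Total AI services over total AI conceptions.

    Natural-service (bull) conceptions carry no service day and are
    excluded from both numerator and denominator.  Undefined (None) when
    there are no AI conceptions.
    """
    _require(records)
    n_services = sum(len(r.service_days) for r in records)
    n_conc = sum(
        1 for r in records if r.pregnant and r.conception_day in r.service_days
    )
    if n_conc == 0:
        return None
    return n_services / n_conc


def barren_proportion(records: Sequence[CowRecord], follow_up_days: float = 84.0) -> float:
    """1 - Kaplan-Meier cumulative pregnancy at the end of the season."""
    _require(records)
    curve = survival_from_records(records)
    return 1.0 - time_point_estimate(curve, follow_up_days).cumulative_pregnancy


def summarize_group(records: Sequence[CowRecord]) -> GroupSummary:
    """All group-level reproductive statistics in one bundle."""
    _require(records)
    served = [r for r in records if r.service_days]
    conceived = [r for r in records if r.pregnant]
    return GroupSummary(
        n=len(records),
        submission_rate_21=submission_rate(records, 21.0),
        in_calf_21=interval_in_calf_rate(records, 21.0),
        in_calf_42=interval_in_calf_rate(records, 42.0),
        in_calf_84=interval_in_calf_rate(records, 84.0),
        conception_rate_first_service=conception_rate_first_service(records),
        services_per_conception=services_per_conception(records),
        barren_proportion=barren_proportion(records),
        mean_calving_first_service=(
            float(np.mean([r.cbsi_days + r.service_days[0] for r in served]))
            if served else None
        ),
        mean_calving_conception=(
            float(np.mean([r.cbsi_days + r.conception_day for r in conceived]))
            if conceived else None
        ),
        median_msd_conception=(
            float(np.median([r.conception_day for r in conceived]))
            if conceived else None
        ),
    )


def schoenfeld_sample_size(
    hazard_ratio: float,
    alpha_two_sided: float = 0.05,
    power: float = 0.8,
    event_probability: float = 1.0,
) -> int:
    """Cows required per group for a two-group log-rank comparison.

    Schoenfeld's formula: required events
    ``D = 4 (z_{1-alpha/2} + z_{power})^2 / ln(HR)^2``; the per-group count
    is ``ceil(D / (2 * event_probability))``.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be > 0")
    if hazard_ratio == 1:
        raise ValueError("hazard ratio of 1 gives an unbounded sample size")
    for name, v in (("alpha", alpha_two_sided), ("power", power),
                    ("event_probability", event_probability)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    z = norm.ppf(1 - alpha_two_sided / 2) + norm.ppf(power)
    events = 4 * z**2 / math.log(hazard_ratio) ** 2
    return math.ceil(events / (2 * event_probability))
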