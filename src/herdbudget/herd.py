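"""Synthetic breeding-season generator for seasonal-calving dairy herds.

Generates cow-level datasets with the statistical structure of a two-arm
pre-breeding treatment comparison: cows not seen in estrus before the herd
mating start date (MSD, day 0) receive either a single prostaglandin
injection with insemination on observed estrus (``PGOD``) or a modified
Ovsynch protocol with fixed-time AI at day 10.25 (``MOFT``).  Every
downstream stage (survival metrics, partial budget, sensitivity, Monte
Carlo) is testable against these datasets without access to trial data.

The breeding process per cow is a renewal model over estrus cycles:

* PGOD cows respond to prostaglandin with probability ``p_first_response``
  and are served on observed estrus on a day drawn uniformly from the
  response window (days 2-7).  Non-responders resume natural cycling: a
  first estrus uniform over ``first_estrus_window`` followed by returns at
  truncated-normal cycle intervals, each detected with ``p_detect_return``.
* MOFT cows show estrus after device removal with probability
  ``p_early_estrus`` (served on days 8-10); the remainder receive
  fixed-time AI at day 10.25.
* A latent fraction ``p_nonconceiver`` per group never conceives (chronic
  anestrus / cystic cows); these cows cycle and are served like any other.
  This class is what the two protocols differ on most, and is what caps the
  84-day in-calf rate below the per-service conception rates.
* Failed services are followed by returns every cycle until follow-up ends.
* Herds running a sweeper bull from ``natural_service_start_day`` switch
  off AI at that day; non-pregnant fertile cows then conceive with a small
  daily hazard and no service day is recorded.

All randomness flows through one :class:`numpy.random.Generator`, so a
given (config, dynamics, seed) triple is bit-reproducible.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, truncnorm

__all__ = [
    "PGOD",
    "MOFT",
    "HerdConfig",
    "GroupDynamics",
    "BreedingDynamics",
    "CowRecord",
    "EligibilityFlags",
    "allocate_treatment",
    "apply_eligibility_filters",
    "generate_herd",
    "simulate_breeding_events",
    "cycle_length_pmf",
]

logger = logging.getLogger(__name__)

PGOD = "PGOD"
MOFT = "MOFT"


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HerdConfig:
    """Herd-level structure of the synthetic breeding season.

    Defaults emulate a 190-cow autumn-calving cohort over three farms, with
    a calving-to-breeding-start interval (CBSI) of 71 (SD 22) days and an
    84-day breeding season.  Farm 1 runs AI for 42 days and a sweeper bull
    thereafter; the other farms AI throughout.
    """

    n_per_farm: tuple[int, ...] = (94, 27, 69)
    cbsi_mean_days: float = 71.0
    cbsi_sd_days: float = 22.0
    cbsi_min_days: float = 25.0
    parity_fractions: tuple[float, float, float] = (0.34, 0.13, 0.53)
    bcs_low_fraction: float = 0.17
    follow_up_days: int = 84
    natural_service_start_day: tuple[int | None, ...] = (42, None, None)
    group_sizes_override: tuple[int, int] | None = None  # (n_pgod, n_moft)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_farm):
            raise ValueError("cow counts must be >= 0")
        if not math.isclose(sum(self.parity_fractions), 1.0, abs_tol=1e-9):
            raise ValueError("parity fractions must sum to 1")
        if not all(0.0 <= f <= 1.0 for f in self.parity_fractions):
            raise ValueError("parity fractions must lie in [0, 1]")
        if not 0.0 <= self.bcs_low_fraction <= 1.0:
            raise ValueError("bcs_low_fraction must lie in [0, 1]")
        if self.cbsi_sd_days <= 0:
            raise ValueError("cbsi_sd_days must be > 0")
        if self.follow_up_days <= 0:
            raise ValueError("follow_up_days must be > 0")
        if len(self.natural_service_start_day) != len(self.n_per_farm):
            raise ValueError("need one natural_service_start_day per farm")
        if self.group_sizes_override is not None:
            if sum(self.group_sizes_override) != sum(self.n_per_farm):
                raise ValueError("group_sizes_override must sum to the herd size")


@dataclass(frozen=True)
class GroupDynamics:
    """Breeding-process parameters for one treatment group.

    ``conception_prob_first`` is on the observed per-enrolled-cow scale
    (first-service conceptions / cows enrolled); the conception probability
    of a fertile cow at first service is derived from it together with
    ``p_never_served`` and ``p_nonconceiver``.
    """

    first_service_window: tuple[int, int] = (2, 7)
    fixed_time_ai_day: float | None = None
    early_estrus_window: tuple[int, int] | None = None
    p_first_response: float = 0.0
    p_early_estrus: float = 0.0
    first_estrus_window: tuple[int, int] = (2, 30)
    p_detect_return: float = 0.90
    conception_prob_first: float = 0.52
    conception_prob_repeat: float = 0.48
    p_nonconceiver: float = 0.0
    p_never_served: float = 0.0
    cycle_length_mean: float = 19.5
    cycle_length_sd: float = 4.0
    cycle_length_bounds: tuple[int, int] = (18, 24)
    bull_daily_conception_hazard: float = 0.010

    def __post_init__(self) -> None:
        probs = (
            self.p_first_response, self.p_early_estrus, self.p_detect_return,
            self.conception_prob_first, self.conception_prob_repeat,
            self.p_nonconceiver, self.p_never_served,
            self.bull_daily_conception_hazard,
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        lo, hi = self.cycle_length_bounds
        if not lo <= self.cycle_length_mean <= hi:
            raise ValueError("cycle bounds must contain the cycle mean")
        if self.fertile_first_prob > 1.0:
            raise ValueError(
                "conception_prob_first inconsistent with never-served / "
                "non-conceiver fractions (implied fertile probability > 1)"
            )

    @property
    def fertile_first_prob(self) -> float:
        """First-service conception probability of a fertile, served cow."""
        denom = (1.0 - self.p_never_served) * (1.0 - self.p_nonconceiver)
        if denom <= 0:
            return 0.0
        return self.conception_prob_first / denom


def _default_pgod() -> GroupDynamics:
    return GroupDynamics(
        first_service_window=(2, 7),
        p_first_response=0.33,
        conception_prob_first=0.52,
        conception_prob_repeat=0.91,
        p_nonconceiver=0.19,
        p_never_served=0.0,
    )


def _default_moft() -> GroupDynamics:
    return GroupDynamics(
        fixed_time_ai_day=10.25,
        early_estrus_window=(8, 10),
        p_early_estrus=0.55,
        conception_prob_first=0.57,
        conception_prob_repeat=0.48,
        p_nonconceiver=0.0,
        p_never_served=0.04,
    )


@dataclass(frozen=True)
class BreedingDynamics:
    """Pair of per-group breeding dynamics (defaults calibrated to the
    trial's Kaplan-Meier time-point targets; see docs/methods.md)."""

    pgod: GroupDynamics = field(default_factory=_default_pgod)
    moft: GroupDynamics = field(default_factory=_default_moft)

    def for_group(self, treatment: str) -> GroupDynamics:
        if treatment == PGOD:
            return self.pgod
        if treatment == MOFT:
            return self.moft
        raise ValueError(f"unknown treatment group {treatment!r}")


@dataclass(frozen=True)
class CowRecord:
    """One enrolled cow.

    Day offsets are relative to the herd mating start date (day 0).
    ``conception_day`` equals one of ``service_days`` for AI conceptions,
    or any day on/after the farm's natural-service start for bull
    conceptions (which carry no service record).  ``censor_day`` is present
    exactly when ``conception_day`` is absent.
    """

    cow_id: str
    freeze_brand: int
    farm: str
    treatment: str
    parity_class: str  # {"1", "2", "3plus"}
    bcs_class: str  # {"le2.5", "ge2.75"}
    cbsi_days: int
    service_days: tuple[float, ...] = ()
    conception_day: float | None = None
    censor_day: float | None = None

    def __post_init__(self) -> None:
        days = self.service_days
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"{self.cow_id}: service days must be strictly ascending")
        if (self.conception_day is None) == (self.censor_day is None):
            raise ValueError(
                f"{self.cow_id}: exactly one of conception_day / censor_day required"
            )
        if self.cbsi_days < 0:
            raise ValueError(f"{self.cow_id}: cbsi_days must be >= 0")

    @property
    def event_day(self) -> float:
        """Conception day if pregnant, censor day otherwise."""
        return self.conception_day if self.conception_day is not None else self.censor_day

    @property
    def pregnant(self) -> bool:
        return self.conception_day is not None


@dataclass(frozen=True)
class EligibilityFlags:
    """Enrolment screening data for one cow."""

    calving_interval_days: float | None = None
    systemically_ill: bool = False
    abnormal_discharge: bool = False
    nulliparous: bool = False


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def allocate_treatment(freeze_brand: int) -> str:
    """Deterministic allocation by freeze-brand parity.

    Even brands receive the prostaglandin protocol (PGOD); odd brands the
    modified Ovsynch protocol (MOFT).
    """
    if isinstance(freeze_brand, bool) or not isinstance(freeze_brand, (int, np.integer)):
        raise ValueError(f"freeze brand must be a positive integer, got {freeze_brand!r}")
    if freeze_brand < 1:
        raise ValueError(f"freeze brand must be >= 1, got {freeze_brand}")
    return PGOD if freeze_brand % 2 == 0 else MOFT


def apply_eligibility_filters(
    records: Sequence[CowRecord],
    flags: Mapping[str, EligibilityFlags],
    max_calving_interval_days: float = 365.0,
) -> list[CowRecord]:
    """Apply enrolment exclusions: calving interval over the limit,
    systemic illness, abnormal vaginal discharge, nulliparity.

    Order is preserved; the number excluded is logged.  A record without
    flags raises, naming the cow.
    """
    kept: list[CowRecord] = []
    for rec in records:
        if rec.cow_id not in flags:
            raise ValueError(f"no eligibility flags supplied for cow {rec.cow_id!r}")
        f = flags[rec.cow_id]
        excluded = (
            f.systemically_ill
            or f.abnormal_discharge
            or f.nulliparous
            or (
                f.calving_interval_days is not None
                and f.calving_interval_days > max_calving_interval_days
            )
        )
        if not excluded:
            kept.append(rec)
    logger.info(
        "eligibility screen: %d of %d cows retained (%d excluded)",
        len(kept), len(records), len(records) - len(kept),
    )
    return kept


from functools import lru_cache


@lru_cache(maxsize=32)
def _cycle_pmf_cached(
    mean: float, sd: float, bounds: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo, hi = bounds
    ks = np.arange(lo, hi + 1)
    p = norm.cdf(ks + 0.5, mean, sd) - norm.cdf(ks - 0.5, mean, sd)
    p = p / p.sum()
    return ks, p, np.cumsum(p)


def cycle_length_pmf(
    mean: float = 19.5,
    sd: float = 4.0,
    bounds: tuple[int, int] = (18, 24),
) -> tuple[np.ndarray, np.ndarray]:
    """Probability mass of the whole-day inter-estrus interval.

    A normal(mean, sd) rounded to whole days and truncated to ``bounds``:
    pmf(k) is proportional to the normal mass of [k - 0.5, k + 0.5].
    """
    ks, p, _ = _cycle_pmf_cached(mean, sd, bounds)
    return ks, p


def _draw_cycle(dyn: GroupDynamics, rng: np.random.Generator) -> int:
    ks, _, cum = _cycle_pmf_cached(
        dyn.cycle_length_mean, dyn.cycle_length_sd, dyn.cycle_length_bounds
    )
    return int(ks[np.searchsorted(cum, rng.random())])


def _first_service_day(
    dyn: GroupDynamics, rng: np.random.Generator, ai_end: float
) -> float | None:
    """Day of the first AI service, or None if the cow is never served."""
    if dyn.fixed_time_ai_day is not None:  # modified Ovsynch arm
        if rng.random() < dyn.p_early_estrus:
            lo, hi = dyn.early_estrus_window
            day = float(rng.integers(lo, hi + 1))
        else:
            day = dyn.fixed_time_ai_day
        return day if day < ai_end else None
    # prostaglandin arm
    if rng.random() < dyn.p_first_response:
        lo, hi = dyn.first_service_window
        day = float(rng.integers(lo, hi + 1))
        return day if day < ai_end else None
    lo, hi = dyn.first_estrus_window
    estrus = float(rng.integers(lo, hi + 1))
    while estrus < ai_end:
        if rng.random() < dyn.p_detect_return:
            return estrus
        estrus += _draw_cycle(dyn, rng)
    return None


def simulate_breeding_events(
    record: CowRecord,
    dynamics: GroupDynamics,
    rng: np.random.Generator,
    *,
    follow_up_days: int = 84,
    natural_service_start_day: int | None = None,
) -> CowRecord:
    """Simulate one cow's services and conception over the breeding season.

    Returns a new record with ``service_days`` and either ``conception_day``
    or ``censor_day`` filled in.  The input record must have an empty
    service list.
    """
    if rng is None:
        raise ValueError("an initialised numpy Generator is required")
    if record.service_days:
        raise ValueError(f"{record.cow_id}: record already carries services")

    ai_end = float(
        natural_service_start_day if natural_service_start_day is not None else follow_up_days
    )
    fertile = rng.random() >= dynamics.p_nonconceiver
    never_served = rng.random() < dynamics.p_never_served

    services: list[float] = []
    conception: float | None = None

    if not never_served:
        day = _first_service_day(dynamics, rng, ai_end)
        if day is not None:
            services.append(day)
            if fertile and rng.random() < dynamics.fertile_first_prob:
                conception = day
            else:
                estrus = day + _draw_cycle(dynamics, rng)
                while estrus < min(ai_end, follow_up_days):
                    if rng.random() < dynamics.p_detect_return:
                        services.append(estrus)
                        if fertile and rng.random() < dynamics.conception_prob_repeat:
                            conception = estrus
                            break
                    estrus += _draw_cycle(dynamics, rng)

    if conception is None and natural_service_start_day is not None and fertile:
        for day in range(natural_service_start_day, follow_up_days):
            if rng.random() < dynamics.bull_daily_conception_hazard:
                conception = float(day)
                break

    return replace(
        record,
        service_days=tuple(services),
        conception_day=conception,
        censor_day=None if conception is not None else float(follow_up_days),
    )


def _treatment_sequence(
    n: int, override: tuple[int, int] | None, rng: np.random.Generator
) -> list[tuple[int, str]]:
    """(freeze_brand, treatment) pairs for n cows.

    Brands are issued sequentially from 1, so allocation by brand parity
    alternates the arms (~50:50).  With an override, arm labels with the
    exact requested counts are randomly interleaved and brands chosen with
    the matching parity, kept increasing.
    """
    if override is None:
        return [(brand, allocate_treatment(brand)) for brand in range(1, n + 1)]
    n_pgod, n_moft = override
    labels = np.array([PGOD] * n_pgod + [MOFT] * n_moft)
    labels = labels[rng.permutation(n)]
    pairs: list[tuple[int, str]] = []
    brand = 0
    for lab in labels:
        brand += 1
        if allocate_treatment(brand) != lab:
            brand += 1
        pairs.append((brand, str(lab)))
    return pairs


def generate_herd(
    config: HerdConfig | None = None,
    dynamics: BreedingDynamics | None = None,
) -> list[CowRecord]:
    """Generate a complete cow-level breeding-season dataset.

    One record per cow; farm sizes match the config exactly; treatment is
    assigned by brand parity on sequentially issued freeze brands.  CBSI is
    a truncated normal rounded to whole days.  Identical (config, dynamics)
    give bit-identical output.
    """
    config = config or HerdConfig()
    dynamics = dynamics or BreedingDynamics()
    rng = np.random.default_rng(config.seed)

    n_total = sum(config.n_per_farm)
    pairs = _treatment_sequence(n_total, config.group_sizes_override, rng)

    a = (config.cbsi_min_days - config.cbsi_mean_days) / config.cbsi_sd_days
    parity_labels = ("1", "2", "3plus")

    records: list[CowRecord] = []
    idx = 0
    for farm_i, n_farm in enumerate(config.n_per_farm):
        farm = str(farm_i + 1)
        ns_start = config.natural_service_start_day[farm_i]
        for _ in range(n_farm):
            brand, treatment = pairs[idx]
            idx += 1
            cbsi = int(round(truncnorm.ppf(
                rng.random(), a, np.inf,
                loc=config.cbsi_mean_days, scale=config.cbsi_sd_days,
            )))
            parity = parity_labels[rng.choice(3, p=config.parity_fractions)]
            bcs = "le2.5" if rng.random() < config.bcs_low_fraction else "ge2.75"
            base = CowRecord(
                cow_id=f"F{farm}-{brand:04d}",
                freeze_brand=brand,
                farm=farm,
                treatment=treatment,
                parity_class=parity,
                bcs_class=bcs,
                cbsi_days=cbsi,
                censor_day=float(config.follow_up_days),
            )
            records.append(
                simulate_breeding_events(
                    replace(base, censor_day=float(config.follow_up_days)),
                    dynamics.for_group(treatment),
                    rng,
                    follow_up_days=config.follow_up_days,
                    natural_service_start_day=ns_start,
                )
            )
    logger.info("generated %d cows over %d farms", len(records), len(config.n_per_farm))
    return records
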