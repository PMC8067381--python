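"""Partial-budget comparison of the modified Ovsynch protocol (MOFT)
against a single prostaglandin injection (PGOD), per cow treated.

The four-quadrant partial budget nets additional income (milk from a
shorter calving-conception interval, calf revenue), reduced costs (fewer
inseminations, fewer barren cows to replace) and extra costs (protocol
cost, extra lactation feed); no returns are foregone.  Four scenarios
cross the herd's dry-off policy (fixed calendar date vs per-cow variable
date) with whether the protocol improves the end-of-season barren rate.

Under a variable dry-off date a shorter calving-conception interval does
not lengthen the lactation, so the milk-income quadrant is omitted; the
extra feed cost of the longer lactation is charged in both policies (the
printed fixed-minus-variable net-benefit difference equals the *gross*
milk revenue, which pins this convention down).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Literal

__all__ = [
    "EconomicInputs",
    "ScenarioConfig",
    "BudgetResult",
    "SCENARIO_LETTERS",
    "scenario_from_letter",
    "milk_income",
    "calf_income_difference",
    "insemination_cost_saving",
    "replacement_cost_saving",
    "extra_feed_cost",
    "extra_treatment_cost",
    "net_benefit",
    "economic_field_names",
]


@dataclass(frozen=True)
class EconomicInputs:
    """Monetary and biological inputs of the partial budget (GBP).

    Defaults are the published expected values where the source prints
    them (barren-rate reduction, heifer and cull values, milk yield and
    price, protocol cost, services per conception, conception-window
    proportions, calf sex ratio).  The remaining defaults — AI cost, feed
    cost per litre and the four calf values — are synthetic
    reconstructions from UK 2020 market statistics, calibrated so the
    deterministic budget reproduces the published net benefits; treat them
    as placeholders to be replaced by farm-specific figures.
    """

    days_gain: float = 4.0
    daily_yield_l: float = 24.0
    milk_price_gbp_per_l: float = 0.28
    feed_cost_gbp_per_l: float = 0.119
    barren_reduction: float = 0.06
    heifer_cost_gbp: float = 1495.0
    cull_value_gbp: float = 631.0
    treatment_extra_cost_gbp: float = 18.0
    ai_cost_gbp: float = 20.0
    services_per_conception_pgod: float = 1.72
    services_per_conception_moft: float = 1.65
    conc_first42_pgod: float = 0.70
    conc_first42_moft: float = 0.77
    conc_second42_pgod: float = 0.10
    conc_second42_moft: float = 0.09
    calf_value_dairy_male: float = 30.0
    calf_value_dairy_female: float = 110.0
    calf_value_beefx_male: float = 230.0
    calf_value_beefx_female: float = 180.0
    male_fraction: float = 0.52

    def __post_init__(self) -> None:
        money = (
            self.heifer_cost_gbp, self.cull_value_gbp, self.ai_cost_gbp,
            self.treatment_extra_cost_gbp, self.calf_value_dairy_male,
            self.calf_value_dairy_female, self.calf_value_beefx_male,
            self.calf_value_beefx_female, self.milk_price_gbp_per_l,
            self.feed_cost_gbp_per_l,
        )
        if any(v < 0 for v in money):
            raise ValueError("monetary values must be >= 0")
        props = (
            self.barren_reduction, self.conc_first42_pgod, self.conc_first42_moft,
            self.conc_second42_pgod, self.conc_second42_moft, self.male_fraction,
        )
        if any(not 0 <= p <= 1 for p in props):
            raise ValueError("proportions must lie in [0, 1]")
        if self.conc_first42_pgod + self.conc_second42_pgod > 1 + 1e-12:
            raise ValueError("PGOD conception-window proportions exceed 1")
        if self.conc_first42_moft + self.conc_second42_moft > 1 + 1e-12:
            raise ValueError("MOFT conception-window proportions exceed 1")

    def dairy_calf_value(self) -> float:
        """Sex-weighted mean value of a dairy calf."""
        return (self.male_fraction * self.calf_value_dairy_male
                + (1 - self.male_fraction) * self.calf_value_dairy_female)

    def beefx_calf_value(self) -> float:
        """Sex-weighted mean value of a beef-cross calf."""
        return (self.male_fraction * self.calf_value_beefx_male
                + (1 - self.male_fraction) * self.calf_value_beefx_female)


@dataclass(frozen=True)
class ScenarioConfig:
    """Dry-off policy x barren-rate improvement."""

    dry_off: Literal["fixed", "variable"]
    barren_improvement: bool

    def __post_init__(self) -> None:
        if self.dry_off not in ("fixed", "variable"):
            raise ValueError("dry_off must be 'fixed' or 'variable'")


SCENARIO_LETTERS: dict[str, ScenarioConfig] = {
    "a": ScenarioConfig("fixed", True),
    "b": ScenarioConfig("fixed", False),
    "c": ScenarioConfig("variable", True),
    "d": ScenarioConfig("variable", False),
}


def scenario_from_letter(letter: str) -> ScenarioConfig:
    try:
        return SCENARIO_LETTERS[letter.lower()]
    except KeyError:
        raise ValueError(f"scenario must be one of a-d, got {letter!r}") from None


@dataclass(frozen=True)
class BudgetResult:
    """Component ledger of the partial budget, per cow treated (GBP)."""

    milk_income: float
    calf_income: float
    ai_saving: float
    replacement_saving: float
    treatment_cost: float
    feed_cost: float
    returns_foregone: float
    net_benefit: float

    def __post_init__(self) -> None:
        ledger = (
            self.milk_income + self.calf_income + self.ai_saving
            + self.replacement_saving - self.treatment_cost - self.feed_cost
            - self.returns_foregone
        )
        if not math.isclose(ledger, self.net_benefit, abs_tol=1e-9):
            raise ValueError("ledger identity violated")


def milk_income(inputs: EconomicInputs, scenario: ScenarioConfig) -> float:
    """Value of extra milk from extra lactating days (fixed dry-off only)."""
    if scenario.dry_off == "variable":
        return 0.0
    return inputs.days_gain * inputs.daily_yield_l * inputs.milk_price_gbp_per_l


def calf_income_difference(inputs: EconomicInputs, scenario: ScenarioConfig) -> float:
    """MOFT minus PGOD calf revenue, per cow treated.

    Per 100 treated cows each arm produces ``conc_first42 x 100`` dairy
    calves (first half of the season, conventional dairy semen) and
    ``conc_second42 x 100`` beef-cross calves (second half).  Without a
    barren-rate improvement the MOFT totals are rescaled to the PGOD total
    while keeping the MOFT breed mix, so only the mix is monetised.
    """
    v_dairy = inputs.dairy_calf_value()
    v_beef = inputs.beefx_calf_value()
    p_dairy = inputs.conc_first42_pgod * 100
    p_beef = inputs.conc_second42_pgod * 100
    m_dairy = inputs.conc_first42_moft * 100
    m_beef = inputs.conc_second42_moft * 100
    if min(p_dairy, p_beef, m_dairy, m_beef) < 0:
        raise ValueError("negative implied calf counts")
    if not scenario.barren_improvement:
        m_total = m_dairy + m_beef
        if m_total > 0:
            scale = (p_dairy + p_beef) / m_total
            m_dairy *= scale
            m_beef *= scale
    moft_rev = m_dairy * v_dairy + m_beef * v_beef
    pgod_rev = p_dairy * v_dairy + p_beef * v_beef
    return (moft_rev - pgod_rev) / 100.0


def insemination_cost_saving(inputs: EconomicInputs) -> float:
    """Saving from fewer inseminations per conception."""
    return (
        inputs.services_per_conception_pgod - inputs.services_per_conception_moft
    ) * inputs.ai_cost_gbp


def replacement_cost_saving(inputs: EconomicInputs, scenario: ScenarioConfig) -> float:
    """Avoided net replacement cost from the barren-rate reduction."""
    if not scenario.barren_improvement:
        return 0.0
    return inputs.barren_reduction * (inputs.heifer_cost_gbp - inputs.cull_value_gbp)


def extra_feed_cost(inputs: EconomicInputs) -> float:
    """Feed for the extra lactating days, charged under both dry-off
    policies."""
    return inputs.days_gain * inputs.daily_yield_l * inputs.feed_cost_gbp_per_l


def extra_treatment_cost(inputs: EconomicInputs) -> float:
    """Cost of the MOFT protocol over the PGOD protocol."""
    return inputs.treatment_extra_cost_gbp


def net_benefit(inputs: EconomicInputs, scenario: ScenarioConfig) -> BudgetResult:
    """Assemble the full component ledger for one scenario."""
    milk = milk_income(inputs, scenario)
    calf = calf_income_difference(inputs, scenario)
    ai = insemination_cost_saving(inputs)
    repl = replacement_cost_saving(inputs, scenario)
    treat = extra_treatment_cost(inputs)
    feed = extra_feed_cost(inputs)
    return BudgetResult(
        milk_income=milk,
        calf_income=calf,
        ai_saving=ai,
        replacement_saving=repl,
        treatment_cost=treat,
        feed_cost=feed,
        returns_foregone=0.0,
        net_benefit=milk + calf + ai + repl - treat - feed,
    )


def economic_field_names() -> tuple[str, ...]:
    """Names of all tunable economic inputs, in declaration order."""
    return tuple(f.name for f in fields(EconomicInputs))
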