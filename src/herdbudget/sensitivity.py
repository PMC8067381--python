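"""One-way (tornado) sensitivity analysis of the partial budget.

Each input is swept from its low to its high value with every other input
held at its expected value; the swing is the absolute range of the net
benefit.  "Contribution to variation" follows the squared-swing
convention of spreadsheet tornado add-ins: swing_i^2 / sum(swing_j^2); a
plain-swing share is available for comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import pandas as pd

from .budget import EconomicInputs, ScenarioConfig, economic_field_names, net_benefit

__all__ = [
    "ParamRange",
    "TornadoEntry",
    "one_way_sweep",
    "contribution_to_variation",
    "tornado_report",
    "format_gbp",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamRange:
    """Low / expected / high values for one economic input."""

    name: str
    low: float
    expected: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.expected <= self.high:
            raise ValueError(
                f"{self.name}: require low <= expected <= high, "
                f"got ({self.low}, {self.expected}, {self.high})"
            )


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    nb_low: float
    nb_expected: float
    nb_high: float
    swing: float
    contribution_pct: float | None = None


def _evaluate(inputs: EconomicInputs, name: str, value: float,
              scenario: ScenarioConfig) -> float:
    valid = economic_field_names()
    if name not in valid:
        raise ValueError(
            f"unknown economic input {name!r}; valid names: {', '.join(valid)}"
        )
    return net_benefit(replace(inputs, **{name: value}), scenario).net_benefit


def one_way_sweep(
    ranges: Sequence[ParamRange],
    inputs: EconomicInputs,
    scenario: ScenarioConfig,
) -> list[TornadoEntry]:
    """Evaluate the net benefit at each range's low and high, all other
    inputs at expected; entries are returned sorted by descending swing,
    with contributions filled in."""
    valid = economic_field_names()
    for r in ranges:
        if r.name not in valid:
            raise ValueError(
                f"unknown economic input {r.name!r}; valid names: {', '.join(valid)}"
            )
    base = inputs
    for r in ranges:
        base = replace(base, **{r.name: r.expected})
    nb_expected = net_benefit(base, scenario).net_benefit
    entries = []
    for r in ranges:
        nb_low = _evaluate(base, r.name, r.low, scenario)
        nb_high = _evaluate(base, r.name, r.high, scenario)
        entries.append(TornadoEntry(
            name=r.name, nb_low=nb_low, nb_expected=nb_expected,
            nb_high=nb_high, swing=abs(nb_high - nb_low),
        ))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return contribution_to_variation(entries)


def contribution_to_variation(
    entries: Sequence[TornadoEntry],
    method: Literal["squared", "swing"] = "squared",
) -> list[TornadoEntry]:
    """Attach the percent of total variation to each entry.

    ``squared`` (default): 100 * swing_i^2 / sum swing_j^2.
    ``swing``: plain share of the summed swings.
    """
    if not entries:
        raise ValueError("at least one tornado entry is required")
    weights = [e.swing**2 if method == "squared" else e.swing for e in entries]
    total = sum(weights)
    if total == 0:
        logger.warning("all swings are zero; contributions undefined, set to 0")
        return [replace_entry(e, 0.0) for e in entries]
    return [replace_entry(e, 100.0 * w / total) for e, w in zip(entries, weights)]


def replace_entry(entry: TornadoEntry, contribution: float) -> TornadoEntry:
    return TornadoEntry(entry.name, entry.nb_low, entry.nb_expected,
                        entry.nb_high, entry.swing, contribution)


def format_gbp(value: float) -> str:
    """Money formatting with negatives in brackets, e.g. ``(24.83)``."""
    return f"({abs(value):.2f})" if value < 0 else f"{value:.2f}"


def tornado_report(
    entries: Sequence[TornadoEntry], scenario: ScenarioConfig
) -> pd.DataFrame:
    """Ordered tornado table (bar intervals per input) ready for CSV or
    plotting; negatives are also rendered in brackets in display columns."""
    rows = [{
        "input": e.name,
        "nb_low": e.nb_low,
        "nb_expected": e.nb_expected,
        "nb_high": e.nb_high,
        "swing": e.swing,
        "contribution_pct": e.contribution_pct,
        "nb_low_display": format_gbp(e.nb_low),
        "nb_high_display": format_gbp(e.nb_high),
    } for e in sorted(entries, key=lambda e: e.swing, reverse=True)]
    df = pd.DataFrame(rows, columns=[
        "input", "nb_low", "nb_expected", "nb_high", "swing",
        "contribution_pct", "nb_low_display", "nb_high_display",
    ])
    df.attrs["dry_off"] = scenario.dry_off
    df.attrs["barren_improvement"] = scenario.barren_improvement
    return df
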