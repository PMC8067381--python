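"""End-to-end analysis: simulate a breeding season, measure it, and feed
the measured effects into the economic model.

The pipeline mirrors the study's flow: generate (or load) cow-event data,
compute per-group survival and interval metrics, derive the budget inputs
the trial derived from its own data (days of calving-conception interval
gained, barren-rate reduction, conception-window proportions, services
per conception), then run the four-scenario budget, tornado and Monte
Carlo stages, writing CSVs and a run manifest.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .budget import EconomicInputs, SCENARIO_LETTERS, net_benefit
from .herd import MOFT, PGOD, BreedingDynamics, CowRecord, HerdConfig, generate_herd
from .io import (
    EconomicConfig, RunManifest, bundled_config_path, load_economic_config,
    write_cow_csv,
)
from .metrics import summarize_group
from .montecarlo import TriangularParam, run_monte_carlo
from .sensitivity import ParamRange, one_way_sweep, tornado_report
from .survival import survival_from_records, time_point_estimate

__all__ = ["derive_budget_inputs", "run_pipeline", "survival_curve_frame"]

logger = logging.getLogger(__name__)


def survival_curve_frame(records: Sequence[CowRecord]) -> pd.DataFrame:
    """Survival-curve CSV content (time, n_at_risk, n_events, survival, se)."""
    curve = survival_from_records(records)
    return pd.DataFrame({
        "time": curve.times,
        "n_at_risk": curve.n_at_risk,
        "n_events": curve.n_events,
        "survival": curve.survival,
        "se": curve.se,
    })


def derive_budget_inputs(
    pgod: Sequence[CowRecord],
    moft: Sequence[CowRecord],
    base: EconomicInputs,
    follow_up_days: float = 84.0,
) -> EconomicInputs:
    """Replace the trial-derived budget inputs with values measured from
    cow-event data: calving-conception days gained, barren-rate
    reduction, Kaplan-Meier conception-window proportions and services
    per conception."""
    sp, sm = summarize_group(pgod), summarize_group(moft)
    curves = {PGOD: survival_from_records(pgod), MOFT: survival_from_records(moft)}
    tp = {
        g: {
            t: time_point_estimate(curves[g], t).cumulative_pregnancy
            for t in (42.0, follow_up_days)
        }
        for g in (PGOD, MOFT)
    }
    updates: dict[str, float] = {
        "conc_first42_pgod": tp[PGOD][42.0],
        "conc_first42_moft": tp[MOFT][42.0],
        "conc_second42_pgod": tp[PGOD][follow_up_days] - tp[PGOD][42.0],
        "conc_second42_moft": tp[MOFT][follow_up_days] - tp[MOFT][42.0],
        "barren_reduction": max(sp.barren_proportion - sm.barren_proportion, 0.0),
    }
    if sp.mean_calving_conception is not None and sm.mean_calving_conception is not None:
        updates["days_gain"] = max(
            sp.mean_calving_conception - sm.mean_calving_conception, 0.0
        )
    if sp.services_per_conception is not None:
        updates["services_per_conception_pgod"] = sp.services_per_conception
    if sm.services_per_conception is not None:
        updates["services_per_conception_moft"] = sm.services_per_conception
    return replace(base, **updates)


def _align_ranges(
    ranges: Sequence[ParamRange], inputs: EconomicInputs
) -> list[ParamRange]:
    """Re-centre sweep ranges on the data-derived expected values and keep
    the conception-window proportions inside their feasible domain (the
    two windows of one group cannot sum past 1)."""
    caps = {
        "conc_second42_moft": 1.0 - inputs.conc_first42_moft,
        "conc_second42_pgod": 1.0 - inputs.conc_first42_pgod,
    }
    out = []
    for r in ranges:
        expected = float(getattr(inputs, r.name))
        low, high = min(r.low, expected), max(r.high, expected)
        cap = caps.get(r.name)
        if cap is not None:
            low, expected, high = (min(v, cap) for v in (low, expected, high))
        out.append(ParamRange(r.name, low, expected, high))
    return out


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    herd_config: HerdConfig | None = None,
    dynamics: BreedingDynamics | None = None,
    econ_config: EconomicConfig | None = None,
    scenarios: str = "abcd",
    n_iter: int = 10_000,
    derive_inputs: bool = True,
) -> dict[str, object]:
    """Simulate, measure, budget; write every stage's CSV plus a manifest.

    Returns the in-memory results keyed by stage.  Any stage failure
    aborts with the stage name in the exception message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    econ = econ_config or load_economic_config(bundled_config_path())
    herd_config = herd_config or HerdConfig(seed=seed)
    if herd_config.seed != seed:
        herd_config = replace(herd_config, seed=seed)
    results: dict[str, object] = {}
    outputs: list[Path] = []

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        records = generate_herd(herd_config, dynamics)
        cows_path = out / "cows.csv"
        write_cow_csv(records, cows_path)
        outputs.append(cows_path)
        results["records"] = records
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {err}") from err

    try:
        stage("metrics")
        groups = {
            g: [r for r in records if r.treatment == g] for g in (PGOD, MOFT)
        }
        summaries = {g: summarize_group(rs) for g, rs in groups.items()}
        summary_path = out / "group_summary.csv"
        pd.DataFrame(
            [{"group": g, **asdict(s)} for g, s in summaries.items()]
        ).to_csv(summary_path, index=False)
        outputs.append(summary_path)
        for g, rs in groups.items():
            p = out / f"survival_{g.lower()}.csv"
            survival_curve_frame(rs).to_csv(p, index=False)
            outputs.append(p)
        results["summaries"] = summaries
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'metrics' failed: {err}") from err

    try:
        stage("budget")
        inputs = econ.expected
        if derive_inputs:
            inputs = derive_budget_inputs(groups[PGOD], groups[MOFT], inputs,
                                          float(herd_config.follow_up_days))
        budgets = {
            letter: net_benefit(inputs, SCENARIO_LETTERS[letter])
            for letter in scenarios
        }
        rows = [{"scenario": letter, **asdict(b)} for letter, b in budgets.items()]
        budget_path = out / "budget.csv"
        pd.DataFrame(rows).to_csv(budget_path, index=False)
        outputs.append(budget_path)
        results["inputs"] = inputs
        results["budgets"] = budgets
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'budget' failed: {err}") from err

    try:
        stage("tornado")
        tornado = {}
        aligned = {
            letter: _align_ranges(econ.ranges_for_scenario(letter), inputs)
            for letter in scenarios
        }
        for letter in scenarios:
            entries = one_way_sweep(
                aligned[letter], inputs, SCENARIO_LETTERS[letter]
            )
            df = tornado_report(entries, SCENARIO_LETTERS[letter])
            p = out / f"tornado_{letter}.csv"
            df.to_csv(p, index=False)
            outputs.append(p)
            tornado[letter] = entries
        results["tornado"] = tornado
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'tornado' failed: {err}") from err

    try:
        stage("montecarlo")
        mc = {}
        for letter in scenarios:
            params = [
                TriangularParam(r.name, r.low, r.expected, r.high)
                for r in aligned[letter]
            ]
            mc[letter] = run_monte_carlo(
                params, inputs,
                SCENARIO_LETTERS[letter], n_iter=n_iter, seed=seed,
                scenario_label=letter,
            )
        mc_path = out / "mc_summary.csv"
        pd.DataFrame([asdict(s) for s in mc.values()]).to_csv(mc_path, index=False)
        outputs.append(mc_path)
        results["montecarlo"] = mc
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'montecarlo' failed: {err}") from err

    manifest = RunManifest.create(
        command=f"pipeline scenarios={scenarios} n_iter={n_iter}",
        seed=seed,
        output_paths=outputs,
    )
    manifest.write(out / "manifest.json")
    results["manifest"] = manifest
    return results
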