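"""Cow-event CSV dialect, configuration files and run manifests.

The cow-event CSV has one row per cow with columns ``cow_id,
freeze_brand, farm, treatment, parity_class, bcs_class, cbsi_days,
service_days, conception_day, censor_day``; service days are
semicolon-separated, missing values are empty strings, encoding UTF-8.
Round-trip identity read(write(x)) == x holds for any valid record set.
"""
from __future__ import annotations

import csv
import datetime as _dt
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .budget import EconomicInputs, economic_field_names
from .herd import BreedingDynamics, CowRecord, GroupDynamics, HerdConfig
from .montecarlo import TriangularParam
from .sensitivity import ParamRange

__all__ = [
    "COW_COLUMNS",
    "read_cow_csv",
    "write_cow_csv",
    "EconomicConfig",
    "load_economic_config",
    "load_herd_config",
    "RunManifest",
    "bundled_config_path",
]

logger = logging.getLogger(__name__)

COW_COLUMNS = (
    "cow_id", "freeze_brand", "farm", "treatment", "parity_class",
    "bcs_class", "cbsi_days", "service_days", "conception_day", "censor_day",
)

#: Appendix-style inputs that must be stated explicitly in --strict mode
#: (the bundled defaults for these are reconstructed placeholders).
STRICT_REQUIRED = (
    "ai_cost_gbp", "feed_cost_gbp_per_l", "calf_value_dairy_male",
    "calf_value_dairy_female", "calf_value_beefx_male", "calf_value_beefx_female",
)


def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    return f"{x:g}"


def write_cow_csv(records: Sequence[CowRecord], path: str | Path) -> None:
    """Write records in the cow-event dialect (UTF-8, header required)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COW_COLUMNS)
        for r in records:
            w.writerow([
                r.cow_id, r.freeze_brand, r.farm, r.treatment, r.parity_class,
                r.bcs_class, r.cbsi_days, ";".join(_fmt(d) for d in r.service_days),
                _fmt(r.conception_day), _fmt(r.censor_day),
            ])


def _num(s: str) -> float:
    v = float(s)
    return v


def read_cow_csv(
    path: str | Path,
    natural_service_start_days: Mapping[str, float] | None = None,
) -> list[CowRecord]:
    """Read and validate a cow-event CSV.

    Malformed rows are reported with their line number.  A conception day
    that matches no service day is accepted only as a natural-service
    (bull) conception: there must be no later service, and, when the
    farm's natural-service start day is supplied, the conception may not
    precede it.
    """
    path = Path(path)
    records: list[CowRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != COW_COLUMNS:
            raise ValueError(
                f"{path}: expected header {','.join(COW_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            line = reader.line_num
            try:
                services = tuple(
                    _num(tok) for tok in row["service_days"].split(";") if tok != ""
                )
                conception = _num(row["conception_day"]) if row["conception_day"] else None
                censor = _num(row["censor_day"]) if row["censor_day"] else None
                rec = CowRecord(
                    cow_id=row["cow_id"],
                    freeze_brand=int(row["freeze_brand"]),
                    farm=row["farm"],
                    treatment=row["treatment"],
                    parity_class=row["parity_class"],
                    bcs_class=row["bcs_class"],
                    cbsi_days=int(row["cbsi_days"]),
                    service_days=services,
                    conception_day=conception,
                    censor_day=censor,
                )
                if conception is not None and conception not in services:
                    if any(s > conception for s in services):
                        raise ValueError(
                            "conception day matches no service and is followed "
                            "by later services"
                        )
                    if natural_service_start_days is not None:
                        start = natural_service_start_days.get(rec.farm)
                        if start is None or conception < start:
                            raise ValueError(
                                "conception day matches no service and precedes "
                                "the farm's natural-service start"
                            )
            except (KeyError, ValueError) as err:
                raise ValueError(f"{path}:{line}: {err}") from None
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# economic configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EconomicConfig:
    """Parsed economic configuration.

    ``expected`` carries every input at its expected value; ``ranges``
    the low/expected/high sweep ranges; ``vary`` the per-scenario list of
    varied inputs; ``overrides`` scenario-specific distribution shapes.
    """

    expected: EconomicInputs
    ranges: dict[str, ParamRange]
    vary: dict[str, tuple[str, ...]]
    overrides: dict[str, dict[str, ParamRange]] = field(default_factory=dict)

    def _range(self, scenario_letter: str, name: str) -> ParamRange:
        over = self.overrides.get(scenario_letter, {})
        if name in over:
            return over[name]
        if name in self.ranges:
            return self.ranges[name]
        value = getattr(self.expected, name)
        return ParamRange(name, value, value, value)

    def ranges_for_scenario(self, letter: str) -> list[ParamRange]:
        return [self._range(letter, n) for n in self.vary.get(letter, ())]

    def triangulars_for_scenario(self, letter: str) -> list[TriangularParam]:
        return [
            TriangularParam(r.name, r.low, r.expected, r.high)
            for r in self.ranges_for_scenario(letter)
        ]


def _parse_range(name: str, node: object) -> tuple[float, ParamRange | None]:
    if isinstance(node, dict):
        if not {"low", "expected", "high"} <= set(node):
            raise ValueError(f"{name}: ranged inputs need low/expected/high")
        rng = ParamRange(name, float(node["low"]), float(node["expected"]),
                         float(node["high"]))
        return rng.expected, rng
    return float(node), None


def load_economic_config(path: str | Path, strict: bool = False) -> EconomicConfig:
    """Load an economic YAML config.

    Inputs may be scalars (expected value only) or ``{low, expected,
    high}`` mappings.  In strict mode every Appendix-style placeholder
    input must be present in the file; otherwise missing fields fall back
    to package defaults with a logged warning.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    raw_inputs: dict = doc.get("inputs", {})
    valid = set(economic_field_names())
    unknown = set(raw_inputs) - valid
    if unknown:
        raise ValueError(f"{path}: unknown economic inputs {sorted(unknown)}")

    missing_required = [k for k in STRICT_REQUIRED if k not in raw_inputs]
    if strict and missing_required:
        raise ValueError(
            f"{path}: strict mode requires explicit values for {missing_required}"
        )
    for k in missing_required:
        logger.warning("%s: %s not in config; using bundled placeholder default", path, k)

    expected_kwargs: dict[str, float] = {}
    ranges: dict[str, ParamRange] = {}
    for name, node in raw_inputs.items():
        exp, rng = _parse_range(name, node)
        expected_kwargs[name] = exp
        if rng is not None:
            ranges[name] = rng
    expected = EconomicInputs(**expected_kwargs)

    vary = {
        str(k): tuple(v) for k, v in (doc.get("scenarios") or {}).items()
    }
    for letter, names in vary.items():
        bad = set(names) - valid
        if bad:
            raise ValueError(f"{path}: scenario {letter} varies unknown inputs {sorted(bad)}")
    overrides: dict[str, dict[str, ParamRange]] = {}
    for letter, mapping in (doc.get("overrides") or {}).items():
        overrides[str(letter)] = {}
        for name, node in mapping.items():
            if name not in valid:
                raise ValueError(f"{path}: override for unknown input {name!r}")
            _, rng = _parse_range(name, node)
            if rng is None:
                raise ValueError(f"{path}: override {name} must give low/expected/high")
            overrides[str(letter)][name] = rng
    return EconomicConfig(expected=expected, ranges=ranges, vary=vary,
                          overrides=overrides)


def bundled_config_path(name: str = "economics.yaml") -> Path:
    """Path of a configuration file shipped with the package."""
    p = Path(__file__).parent / "data" / name
    if not p.exists():
        raise FileNotFoundError(name)
    return p


# ---------------------------------------------------------------------------
# herd configuration
# ---------------------------------------------------------------------------


def load_herd_config(path: str | Path) -> tuple[HerdConfig, BreedingDynamics]:
    """Load herd + dynamics YAML mirroring the dataclass field names."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    herd_kwargs = dict(doc.get("herd", {}))
    for key in ("n_per_farm", "parity_fractions", "natural_service_start_day",
                "group_sizes_override"):
        if key in herd_kwargs and herd_kwargs[key] is not None:
            herd_kwargs[key] = tuple(herd_kwargs[key])
    config = HerdConfig(**herd_kwargs)
    dyn_doc = doc.get("dynamics", {})

    def _group(name: str, default: GroupDynamics) -> GroupDynamics:
        kwargs = dict(dyn_doc.get(name, {}))
        for key in ("first_service_window", "early_estrus_window",
                    "first_estrus_window", "cycle_length_bounds"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        merged = {**{f.name: getattr(default, f.name) for f in fields(default)}, **kwargs}
        return GroupDynamics(**merged)

    defaults = BreedingDynamics()
    dynamics = BreedingDynamics(
        pgod=_group("pgod", defaults.pgod), moft=_group("moft", defaults.moft)
    )
    return config, dynamics


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunManifest:
    """Provenance record sufficient to re-run a CLI invocation
    bit-identically (timestamp aside)."""

    command: str
    seed: int | None
    config_paths: tuple[str, ...]
    output_paths: tuple[str, ...]
    versions: dict[str, str]
    timestamp: str

    @classmethod
    def create(
        cls,
        command: str,
        seed: int | None,
        config_paths: Sequence[str | Path] = (),
        output_paths: Sequence[str | Path] = (),
    ) -> "RunManifest":
        import numpy, pandas, scipy

        from . import __version__

        return cls(
            command=command,
            seed=seed,
            config_paths=tuple(str(p) for p in config_paths),
            output_paths=tuple(str(p) for p in output_paths),
            versions={
                "herdbudget": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
            },
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
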