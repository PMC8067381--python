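"""Triangular-distribution Monte-Carlo propagation through the partial
budget.

Each uncertain input carries a (minimum, mode, maximum) triangular
distribution; inputs are sampled independently, the budget is evaluated
per iteration, and the draw vector is summarised.  One master seed and a
fixed parameter order make runs bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .budget import EconomicInputs, ScenarioConfig, economic_field_names, net_benefit

__all__ = [
    "TriangularParam",
    "MCSummary",
    "sample_triangular",
    "triangular_cdf",
    "run_monte_carlo",
    "summarize_draws",
]


@dataclass(frozen=True)
class TriangularParam:
    """Triangular sampling spec for one economic input."""

    name: str
    minimum: float
    mode: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.minimum <= self.mode <= self.maximum:
            raise ValueError(
                f"{self.name}: require minimum <= mode <= maximum, "
                f"got ({self.minimum}, {self.mode}, {self.maximum})"
            )

    @property
    def mean(self) -> float:
        return (self.minimum + self.mode + self.maximum) / 3.0


@dataclass(frozen=True)
class MCSummary:
    """Summary of the simulated net-benefit distribution (GBP/cow)."""

    scenario: str
    n_iter: int
    mean: float
    sd: float
    q1: float
    q3: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.q1 > self.q3 + 1e-12:
            raise ValueError("first quartile cannot exceed third quartile")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def sample_triangular(param: TriangularParam, u: float | np.ndarray) -> float | np.ndarray:
    """Inverse-CDF transform of uniform variates to the triangular law.

    For u <= (mode-min)/(max-min):  min + sqrt(u (max-min)(mode-min));
    otherwise                       max - sqrt((1-u)(max-min)(max-mode)).
    A degenerate parameter (min == max) returns the constant.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr > 1)):
        raise ValueError("uniform variates must lie in [0, 1]")
    a, c, b = param.minimum, param.mode, param.maximum
    if a == b:
        out = np.full_like(u_arr, a)
        return float(out) if np.isscalar(u) else out
    fc = (c - a) / (b - a)
    left = a + np.sqrt(u_arr * (b - a) * (c - a))
    right = b - np.sqrt((1.0 - u_arr) * (b - a) * (b - c))
    out = np.where(u_arr <= fc, left, right)
    return float(out) if np.isscalar(u) else out


def triangular_cdf(param: TriangularParam, x: float | np.ndarray) -> np.ndarray:
    """Analytic triangular CDF (for goodness-of-fit checks)."""
    a, c, b = param.minimum, param.mode, param.maximum
    x = np.asarray(x, dtype=float)
    if a == b:
        return (x >= a).astype(float)
    out = np.zeros_like(x)
    if c > a:
        lo = (x > a) & (x <= c)
        out[lo] = (x[lo] - a) ** 2 / ((b - a) * (c - a))
    hi = (x > c) & (x < b)
    out[hi] = 1.0 - (b - x[hi]) ** 2 / ((b - a) * (b - c))
    out[x >= b] = 1.0
    return out


def summarize_draws(draws: np.ndarray, scenario: str = "", n_iter: int | None = None) -> MCSummary:
    """Mean, sample SD (n-1), interpolated quartiles and range of the draw
    vector."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarise an empty draw vector")
    return MCSummary(
        scenario=scenario,
        n_iter=n_iter if n_iter is not None else draws.size,
        mean=float(np.mean(draws)),
        sd=float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
        q1=float(np.percentile(draws, 25)),
        q3=float(np.percentile(draws, 75)),
        minimum=float(np.min(draws)),
        maximum=float(np.max(draws)),
    )


def run_monte_carlo(
    params: Sequence[TriangularParam],
    base_inputs: EconomicInputs,
    scenario: ScenarioConfig,
    n_iter: int = 10_000,
    seed: int = 0,
    scenario_label: str = "",
    return_draws: bool = False,
) -> MCSummary | tuple[MCSummary, np.ndarray]:
    """Propagate triangular input uncertainty through the budget.

    Per iteration each listed parameter is drawn independently (uniform
    variates consumed in declared parameter order), overwrites the base
    inputs, and the scenario's net benefit is evaluated.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    valid = economic_field_names()
    for p in params:
        if p.name not in valid:
            raise ValueError(
                f"unknown economic input {p.name!r}; valid names: {', '.join(valid)}"
            )
    rng = np.random.default_rng(seed)
    u = rng.random((n_iter, len(params)))
    cols = {
        p.name: np.asarray(sample_triangular(p, u[:, j]))
        for j, p in enumerate(params)
    }
    draws = np.empty(n_iter)
    for i in range(n_iter):
        inputs = replace(base_inputs, **{k: float(v[i]) for k, v in cols.items()})
        draws[i] = net_benefit(inputs, scenario).net_benefit
    summary = summarize_draws(draws, scenario=scenario_label, n_iter=n_iter)
    return (summary, draws) if return_draws else summary
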