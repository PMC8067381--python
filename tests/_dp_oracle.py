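"""Independent analytic oracle for the breeding-process generator.

Computes the exact conception-day distribution implied by a
:class:`herdbudget.GroupDynamics` by dynamic programming over a
quarter-day grid (brute-force convolution over estrus-cycle outcomes),
never by simulation.  Used to verify that the Monte-Carlo generator
recovers the distribution its parameters imply.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import norm

from herdbudget import GroupDynamics, HerdConfig, BreedingDynamics

Q = 4  # grid resolution: quarter days


def _cycle_pmf(dyn: GroupDynamics) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = dyn.cycle_length_bounds
    ks = np.arange(lo, hi + 1)
    p = norm.cdf(ks + 0.5, dyn.cycle_length_mean, dyn.cycle_length_sd) - \
        norm.cdf(ks - 0.5, dyn.cycle_length_mean, dyn.cycle_length_sd)
    return ks, p / p.sum()


def conception_day_distribution(
    dyn: GroupDynamics,
    follow_up_days: int = 84,
    natural_service_start_day: int | None = None,
) -> tuple[np.ndarray, float]:
    """(conception-day pmf on the quarter-day grid, P(first service < 21)).

    Index t of the pmf corresponds to day t / Q.  The pmf covers AI and
    natural-service conceptions of fertile cows; its total is
    P(conceive within follow-up).
    """
    n = follow_up_days * Q + 1
    ks, cp = _cycle_pmf(dyn)
    ai_end_day = (natural_service_start_day
                  if natural_service_start_day is not None else follow_up_days)
    ai_end = ai_end_day * Q
    pf = dyn.fertile_first_prob

    a = np.zeros(n)  # pre-first-service estrus event at t
    b = np.zeros(n)  # first service at t
    c = np.zeros(n)  # post-first-service estrus event at t, not pregnant
    conc = np.zeros(n)

    pn = dyn.p_never_served
    if dyn.fixed_time_ai_day is not None:
        lo, hi = dyn.early_estrus_window
        for d in range(lo, hi + 1):
            b[d * Q] += (1 - pn) * dyn.p_early_estrus / (hi - lo + 1)
        b[int(dyn.fixed_time_ai_day * Q)] += (1 - pn) * (1 - dyn.p_early_estrus)
    else:
        lo, hi = dyn.first_service_window
        for d in range(lo, hi + 1):
            b[d * Q] += (1 - pn) * dyn.p_first_response / (hi - lo + 1)
        lo, hi = dyn.first_estrus_window
        for d in range(lo, hi + 1):
            a[d * Q] += (1 - pn) * (1 - dyn.p_first_response) / (hi - lo + 1)

    def defer(arr: np.ndarray, t: int, mass: float) -> None:
        for k, pk in zip(ks, cp):
            t2 = t + k * Q
            if t2 < n:
                arr[t2] += mass * pk

    for t in range(n):
        if a[t] > 0 and t < ai_end:
            b[t] += a[t] * dyn.p_detect_return
            defer(a, t, a[t] * (1 - dyn.p_detect_return))
        if b[t] > 0 and t < ai_end:
            conc[t] += b[t] * pf
            defer(c, t, b[t] * (1 - pf))
        if c[t] > 0 and t < ai_end:
            hit = dyn.p_detect_return * dyn.conception_prob_repeat
            conc[t] += c[t] * hit
            defer(c, t, c[t] * (1 - hit))

    if natural_service_start_day is not None:
        remaining = 1.0 - conc.sum()
        h = dyn.bull_daily_conception_hazard
        for d in range(natural_service_start_day, follow_up_days):
            conc[d * Q] += remaining * h
            remaining *= 1 - h

    conc *= 1 - dyn.p_nonconceiver
    submission_21 = float(b[: 21 * Q].sum())
    return conc, submission_21


def group_expectations(
    dyn: GroupDynamics, config: HerdConfig, origin: float
) -> dict[str, float]:
    """Farm-mixture expectations of the group-level calibration metrics."""
    weights = np.asarray(config.n_per_farm, float)
    weights = weights / weights.sum()
    n = config.follow_up_days * Q + 1
    conc = np.zeros(n)
    sub = 0.0
    for w, ns in zip(weights, config.natural_service_start_day):
        ci, si = conception_day_distribution(dyn, config.follow_up_days, ns)
        conc += w * ci
        sub += w * si
    cum = np.cumsum(conc)

    def cdf_at(day: float) -> float:
        return float(cum[min(int(day * Q), n - 1)])

    first_service_conceptions = dyn.conception_prob_first  # per enrolled cow
    return {
        "km21": cdf_at(origin + 21),
        "km42": cdf_at(origin + 42),
        "km84": cdf_at(config.follow_up_days - 1e-9),
        "submission_21": sub,
        "in_calf_21": cdf_at(21 - 1e-9),
        "in_calf_42": cdf_at(42 - 1e-9),
        "in_calf_84": cdf_at(config.follow_up_days - 1e-9),
        "first_service_conception_per_cow": first_service_conceptions,
    }


def default_expectations(config: HerdConfig | None = None) -> dict[str, dict[str, float]]:
    """Expectations under the default calibrated dynamics; origins are the
    minimum possible first-service day per protocol."""
    config = config or HerdConfig()
    dyn = BreedingDynamics()
    return {
        "PGOD": group_expectations(dyn.pgod, config, origin=dyn.pgod.first_service_window[0]),
        "MOFT": group_expectations(dyn.moft, config, origin=dyn.moft.early_estrus_window[0]),
    }
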