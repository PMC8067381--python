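# Methods

## The problem being modelled

A seasonal (autumn) calving dairy herd sets a mating start date (MSD,
day 0) and needs every cow pregnant within an 84-day season. Cows without
an observed estrus in the weeks before MSD are treated at day 0 with one
of two protocols: a single prostaglandin injection followed by
insemination on observed estrus from day 2 (PGOD), or a modified Ovsynch
protocol (GnRH + progesterone device at day 0, prostaglandin day 7, device
removal day 8, GnRH day 9) with fixed-time AI at day 10.25, cows showing
estrus after device removal being served earlier, days 8–10 (MOFT). The
package quantifies the difference in conception timing and converts it
into money per cow treated.

## Breeding-process model

Each cow's season is a renewal process over estrus cycles:

* **First service.** PGOD: with probability `p_first_response` the cow
  responds to luteolysis and is served on a day uniform on {2,…,7};
  otherwise she resumes natural cycling, with a first estrus uniform on
  {2,…,30} and subsequent returns one cycle apart, each estrus detected
  with `p_detect_return`. MOFT: with probability `p_early_estrus` she is
  served on observed estrus on {8,9,10}, otherwise at the fixed-time AI,
  day 10.25. A fraction `p_never_served` is never inseminated.
* **Conception.** A latent fraction `p_nonconceiver` per group never
  conceives (chronic anovulatory/cystic cows); the remainder conceive at
  the first service with probability
  `conception_prob_first / ((1−p_never_served)(1−p_nonconceiver))` —
  i.e. `conception_prob_first` is specified on the observed
  per-enrolled-cow scale — and at each repeat service with
  `conception_prob_repeat`.
* **Returns.** Non-pregnant cows return every cycle; cycle length is a
  normal(19.5, 4.0) rounded to whole days and truncated to [18, 24].
* **Natural service.** A farm running a sweeper bull from day 42 stops AI
  at that day; each following day a non-pregnant fertile cow conceives
  with hazard 0.010, and bull conceptions carry no service record.
* **Censoring.** Anything after day 84 is censored; cows without a
  conception carry `censor_day = 84`.

The never-conceiver class is not decoration: a plain renewal model whose
per-service conception probabilities match the observed first-service
rates keeps conceiving late into the season and overshoots the observed
84-day in-calf rates by 10–15 points. The plateau in the data is exactly
the subpopulation the protocols are meant to rescue, and the two arms
differ most in how much of it they rescue (PGOD 0.19 vs MOFT 0.0 by
calibration below).

### Calibration of the defaults

The generator's defaults are the study conditions, fixed once. Published
group-level values are used directly: first-service conception 0.52/0.57
(per enrolled cow), the 90/100 arm split (via `group_sizes_override`),
farm sizes 94/27/69, CBSI ~ truncated normal(71, 22, min 25) rounded to
days, parity mix 0.34/0.13/0.53, low-BCS fraction 0.17, AI-to-bull
cut-over at day 42 on farm 1 only.

The unobserved process parameters were fitted — before any test was
written — by least squares of an *analytic* day-grid dynamic programme
(an independent convolution over cycle outcomes, no simulation) against
the six published Kaplan–Meier cumulative-pregnancy points
(PGOD 0.44/0.70/0.77, MOFT 0.63/0.77/0.86 at 21/42/84 d on the group
origin), then rounded:

| parameter | PGOD | MOFT |
|---|---|---|
| p_first_response | 0.33 | – |
| p_early_estrus | – | 0.55 |
| p_nonconceiver | 0.19 | 0.00 |
| conception_prob_repeat (fertile) | 0.91 | 0.48 |
| p_never_served | 0.00 | 0.04 |
| p_detect_return | 0.90 | 0.90 |
| cycle length | N(19.5, 4.0) on [18,24] | same |
| bull daily hazard | 0.010 | 0.010 |

The DP-implied deviations from the six targets are all ≤ 0.005. The tiny
bull hazard reflects the trial's own farm-1 data (in-calf rate moved only
79% → 80% between days 42 and 84). The same DP lives in
`tests/_dp_oracle.py` and is what the simulator is verified against, so
the generator is never judged by its own output.

One target is knowingly not met: a 21-day submission rate of 0.86 for
PGOD is arithmetically incompatible with a 21-day-origin cumulative
pregnancy of 0.44 at first-service conception 0.52 (0.86 × 0.52 = 0.447
before any later service counts); the model sits near 0.73. The
Kaplan–Meier targets were given priority.

## Survival conventions

Time zero is per treatment group: the group's earliest insemination day
(day 2 for PGOD, day 8 for MOFT under the defaults). This is what lets a
fixed-time arm show a median conception time of 0. Windows are half-open
("within 21 days" = day < 21, three 21-day cycles for 21/42/84). Ties are
aggregated; cows censored at an event time remain at risk for it; the
Greenwood standard error at S = 0 is reported as 0; the log-rank statistic
uses the hypergeometric variance with no continuity correction and a
χ²(1) reference. The barren proportion is 1 − KM cumulative pregnancy at
84 d, which equals the raw non-pregnant fraction when nothing is censored
mid-season.

## Economic model

Per cow treated, MOFT vs PGOD:

* milk income = days_gain × daily_yield × milk price under a **fixed**
  dry-off date, 0 under a **variable** one (the lactation does not
  lengthen when dry-off tracks the next calving);
* calf income from the conception-window mix: per 100 cows each arm
  produces `conc_first42 × 100` dairy calves and `conc_second42 × 100`
  beef-cross calves, valued sex-weighted (male fraction 0.52); without a
  barren-rate improvement the MOFT totals are rescaled to the PGOD total
  so only the breed/sex mix is monetised;
* AI saving = (1.72 − 1.65) × cost per insemination;
* replacement saving = barren-rate reduction × (heifer cost − cull value),
  0 when no improvement is assumed;
* extra costs: protocol cost difference, and feed for the extra lactating
  days — charged under *both* dry-off policies. The published
  fixed-minus-variable net-benefit difference (53.42 − 26.54 = 26.88)
  equals the *gross* milk revenue 4 × 24 × 0.28 exactly, which is only
  consistent with feed being charged in both; the strongly negative
  variable/no-improvement Monte-Carlo mean confirms it.

No returns are foregone; no discounting; single-season horizon. The model
is affine in every single input, and the ledger identity
(net = incomes + savings − costs) is enforced in the result type.

## Reconstructed inputs (synthetic)

The source publishes ranges for six key inputs (barren-rate reduction
2/6/10%, heifer cost 1136/1495/1854, milk 15/24/33 L/d, price
0.20/0.28/0.36 £/L, cull value 534/631/728, protocol cost 12/18/24) and
expected values for the services-per-conception and conception-window
inputs, but not the AI cost, feed cost per litre, the four calf values, or
the distribution shapes of the scenario-specific uncertain inputs. These
were reconstructed once, at design time, by closed-form algebra against
the published aggregate results (deterministic net benefits, the
Monte-Carlo means exceeding them in fixed-dry-off scenarios, and plausible
UK 2020 market levels):

* AI £20/service (range 10–30); feed £0.119/L (0.07/0.119/0.145 — the
  left skew is what lifts the variable-dry-off MC means above their
  deterministic values);
* calf values: dairy male/female £30/£110, beef-cross £230/£180;
* lactation-day gain triangular (2, 4, 9) — right-skewed, the source of
  the fixed-dry-off MC means exceeding £53.42;
* beef-calf proportion (`conc_second42_moft`): (0.05, 0.09, 0.13) under a
  barren improvement, and a right-triangular (0.085, 0.09, 0.23) under
  the no-improvement scenarios, where it is the dominant driver; the
  maximum is capped so the two conception windows never sum past 1.

These are labelled synthetic in the bundled `economics.yaml` and are
exactly the fields `--strict` mode refuses to default.

## Monte Carlo and sensitivity

Inputs are sampled independently (no correlation structure) by inverse-CDF
triangular transform; uniforms are consumed in declared parameter order
from one seeded generator, so runs are bit-reproducible. Summaries use the
n−1 standard deviation and linearly interpolated (type-7) quartiles.
Tornado contributions use the squared-swing share (the spreadsheet-add-in
convention); a plain-swing share is available. Scenario-specific variable
sets: milk variables are dropped under variable dry-off, barren-related
variables when no improvement is assumed.

## Problem sizes and numerics

Calibration-recovery tests run at 10,000 cows per arm (farm mix
preserved), where the binomial standard error (~0.005) is small against
the published SEs; Monte-Carlo tests use the study's 10,000 iterations;
the library cross-check uses 200 random censored datasets of n ≤ 30.
Monetary arithmetic is double precision with rounding to pennies only for
display. Degenerate cases are defined rather than silent: empty groups
raise, ratios with zero denominators return `None`, a time-point query
beyond follow-up returns the last estimate with a flag, and a degenerate
triangular returns its constant.

## What passing tests do and do not show

The generator reproduces the *group-level* statistical structure of a
real trial: arm sizes, service timing, conception-window rates, censoring
and the survival contrasts. It does not model farm-to-farm heterogeneity
in dynamics (the real farms differed a lot), within-cow covariate effects
(parity, body condition and CBSI are generated but do not influence
conception), endocrine mechanisms, seasonal trends, or loss to follow-up.
Economic conclusions inherit every reconstructed input above; the package
reproduces the published analysis structure, not farm-specific truth.
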