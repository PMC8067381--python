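# Full economic configuration for the MOFT-vs-PGOD partial budget.
#
# Published rows: barren-rate reduction, replacement-heifer cost, daily milk
# yield, milk price, cull value and protocol cost carry the published
# low/expected/high ranges; services per conception, the conception-window
# proportions and the calf sex ratio carry published expected values.
#
# SYNTHETIC RECONSTRUCTION: the AI cost, feed cost per litre, the four calf
# values, the lactation-day-gain range and the skewed beef-calf-proportion
# ranges under the no-barren-improvement scenarios were not published.  They
# were reconstructed from UK 2020 market statistics and the printed model
# identities (see docs/methods.md) and should be replaced with farm-specific
# figures for real use.
inputs:
  days_gain: {low: 2, expected: 4, high: 9}
  daily_yield_l: {low: 15, expected: 24, high: 33}
  milk_price_gbp_per_l: {low: 0.20, expected: 0.28, high: 0.36}
  feed_cost_gbp_per_l: {low: 0.07, expected: 0.119, high: 0.145}
  barren_reduction: {low: 0.02, expected: 0.06, high: 0.10}
  heifer_cost_gbp: {low: 1136, expected: 1495, high: 1854}
  cull_value_gbp: {low: 534, expected: 631, high: 728}
  treatment_extra_cost_gbp: {low: 12, expected: 18, high: 24}
  ai_cost_gbp: {low: 10, expected: 20, high: 30}
  conc_second42_moft: {low: 0.05, expected: 0.09, high: 0.13}
  services_per_conception_pgod: 1.72
  services_per_conception_moft: 1.65
  conc_first42_pgod: 0.70
  conc_first42_moft: 0.77
  conc_second42_pgod: 0.10
  calf_value_dairy_male: 30
  calf_value_dairy_female: 110
  calf_value_beefx_male: 230
  calf_value_beefx_female: 180
  male_fraction: 0.52

# Inputs varied per scenario (a: fixed dry-off + barren improvement,
# b: fixed + none, c: variable + improvement, d: variable + none).  Milk
# variables are dropped under a variable dry-off date; barren-related
# variables are dropped when no improvement is assumed.
scenarios:
  a: [barren_reduction, heifer_cost_gbp, cull_value_gbp, days_gain,
      daily_yield_l, milk_price_gbp_per_l, feed_cost_gbp_per_l,
      treatment_extra_cost_gbp, ai_cost_gbp, conc_second42_moft]
  b: [days_gain, daily_yield_l, milk_price_gbp_per_l, feed_cost_gbp_per_l,
      treatment_extra_cost_gbp, ai_cost_gbp, conc_second42_moft]
  c: [barren_reduction, heifer_cost_gbp, cull_value_gbp,
      feed_cost_gbp_per_l, treatment_extra_cost_gbp, ai_cost_gbp,
      conc_second42_moft]
  d: [feed_cost_gbp_per_l, treatment_extra_cost_gbp, ai_cost_gbp,
      conc_second42_moft]

# Scenario-specific distribution shapes: without a barren-rate improvement
# the beef-calf proportion of the late season is far more uncertain and
# right-skewed (it is the dominant driver of scenario d).
overrides:
  b:
    conc_second42_moft: {low: 0.085, expected: 0.09, high: 0.23}
  d:
    conc_second42_moft: {low: 0.085, expected: 0.09, high: 0.23}
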