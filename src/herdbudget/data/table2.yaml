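# Published key input variables only (sensitivity ranges plus expected
# scalars).  The unpublished placeholder inputs (AI cost, feed cost per
# litre, calf values) are absent on purpose: loading this file outside
# strict mode falls back to the package defaults with a warning.
inputs:
  barren_reduction: {low: 0.02, expected: 0.06, high: 0.10}
  heifer_cost_gbp: {low: 1136, expected: 1495, high: 1854}
  daily_yield_l: {low: 15, expected: 24, high: 33}
  milk_price_gbp_per_l: {low: 0.20, expected: 0.28, high: 0.36}
  cull_value_gbp: {low: 534, expected: 631, high: 728}
  treatment_extra_cost_gbp: {low: 12, expected: 18, high: 24}
  days_gain: 4
  services_per_conception_pgod: 1.72
  services_per_conception_moft: 1.65
  conc_first42_pgod: 0.70
  conc_first42_moft: 0.77
  conc_second42_pgod: 0.10
  conc_second42_moft: 0.09
  male_fraction: 0.52
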