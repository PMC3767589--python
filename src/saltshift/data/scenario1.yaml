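# Two-year voluntary sodium-content agreement: a 10% content reduction on the
# 80% of sodium coming from processed food, phased in as 4% of total intake in
# each of the first two years (8% cumulative), then held with no further cuts.
name: scenario1
start_year: 2013
horizon: 10
annual_reduction_fractions: [0.04, 0.04]
sbp_effect:
  slope_high: 1.87
  slope_low: 1.17
  elderly_age_threshold: 65
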