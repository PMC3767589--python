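# Sustained reduction strategy: 4% of baseline intake per year for ten years,
# reaching a 40% cumulative reduction in sodium consumption.
name: scenario2
start_year: 2013
horizon: 10
annual_reduction_fractions: [0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.04]
sbp_effect:
  slope_high: 1.87
  slope_low: 1.17
  elderly_age_threshold: 65
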