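# Default run configuration: published base-case inputs and anchors.
parameters:
  lambda_normal: 0.003
  lambda_ifg: 0.024
  lambda_ifgigt: 0.039
  rr_undiag: 1.77
  rr_diag: 2.11
  incidence_growth: 1.0

calibration:
  diagnosed_share_of_dm: 0.718061674008811   # 16.3 / 22.7
  prevalence_dm_2007: 0.129
  prevalence_ifg_any_2007: 0.267
  prevalence_ifg_igt_2007: 0.083
  anchors:
    years: [2007, 2010, 2015, 2020, 2025, 2030]
    prevalence_millions: [27.8, 33.1, 41.2, 48.7, 55.3, 60.7]
    prevalence_rates: [0.129, 0.148, 0.175, 0.197, 0.215, 0.227]
    cumulative_incidence_millions: [2.3, 6.8, 17.9, 29.1, 40.3, 51.7]

scenarios:
  - {name: none}
  - {name: high_risk, targeted_effectiveness: 0.125}
  - {name: moderate_risk, targeted_effectiveness: 0.125}
  - {name: population, population_effectiveness: 0.02}
  - {name: combined, targeted_effectiveness: 0.125, population_effectiveness: 0.02}

end_year: 2030

sensitivity:
  targeted_grid: [0.0625, 0.125, 0.25]
  population_grid: [0.01, 0.02, 0.04]
  background_rate_increase_pp: 3.5

emulator:
  grid_size: 5
  spread: 2.0
  n_samples: 10000
  seed: 0

output_dir: results
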