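# Default end-to-end pipeline configuration (desk-scale).
population:
  n: 2000                  # generated survey-like records
  lab_observed_fraction: 0.423514
  impute: true
  n_chains: 5

simulation:
  horizon_years: 10
  population_size: 10000   # simulated agents (records resampled to this size)
  discount_rate: 0.03
  replicates: 1

calibration:
  tolerance: 0.02
  max_iter: 50

interventions:
  selected: ["1.4", "2.11", "2.13", "3.1", "3.2", "6.2", "6.3", "6.4", "7.3"]
  final_reach: 0.64
  ramp: linear_over_horizon

economics:
  gdp_per_capita: 3664.0
  mode: panel              # panel: deltas configured from the published burden panel
                           # simulated: deltas taken from the scenario runs

psa:
  n_draws: 500
  cost_cv: 0.2             # coefficient of variation for unit costs
  seed_offset: 104729

seed: 20200318
output_dir: results
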