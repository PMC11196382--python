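# Default pipeline configuration. Every switch defaults to the convention
# under which the bundled published-table fixtures are reproduced.
inputs:
  importance: bundled        # path to an IV matrix CSV, or "bundled"
  census: bundled            # path to a census CSV, or "bundled"
  soil_traits: null          # path to a soil-trait CSV, or null to simulate
conventions:
  breadth_mode: paper-replication   # or consistent-normalized
  se_convention: population         # or sample
  overlap_threshold: 0.50
  overlap_inclusive: true
  censored_policy: pessimistic      # bound "<N" cells count as plausible size N
  min_iv_pct: null                  # optional display filter for IV reports
assessment:
  mature_individuals: null   # null: use the latest census year's adult count
  continuing_decline: null   # null: use the overall decline flag
  extreme_fluctuation: true
  n_populations: 3
  psesp_mature_cutoff: 5000
  psesp_population_cutoff: 5
simulation:
  soil_traits:
    n_samples: 60
    om_effect: 1.0
    ph_effect: -0.4
    nuisance_sd: 0.05
    noise_sd: 0.5
ordination:
  n_perm: 999
  standardize: zscore
seed: 0
output_dir: report_bundle
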