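# Example configuration: every value shown is the package default.
# Sections map onto PriorConfig (priors), FitConfig (fit),
# SyntheticDesign (design, with nested TrueParams under design.params)
# and the elasticity settings.

priors:
  r_max_mean: 0.304         # informative intrinsic-growth prior (per year)
  r_max_sd: 0.08
  b_bounds: [-2.0, 2.0]     # truncation of the density-dependence terms
  hyper_mean_sd: 10.0       # vague Normal(0, sd) on hyper-means
  hyper_sd_scale: 5.0       # half-Normal(0, scale) on between-unit SDs
  sigma_proj_scale: 5.0
  sigma_obs_scale: 5.0
  init_se_floor: 0.001
  init_fallback_sd: 0.5

fit:
  chains: 3
  iterations: 40000         # post-burn-in sweeps per chain
  burn_in: 16000            # adaptive warm-up sweeps
  thinning: 20              # keep every 20th draw -> 2000 per chain
  seed: 0
  rhat_threshold: 1.1

design:
  n_units: 55
  n_years: 20
  first_year: 1999
  survey_count_probs: [0.10, 0.12, 0.18, 0.30, 0.20, 0.10]  # counts 2..7, median 5
  survey_cv: 0.2
  response_rate_mean: 0.741
  response_rate_range: [0.508, 0.803]
  harvest_rate_range: [0.035, 0.113]
  tag_class_split: [0.5, 0.3, 0.2]        # bull, cow, calf
  class_success: [0.45, 0.40, 0.25]
  log_n0_range: [4.6, 8.7]                # low/high reference units: 100-6000 moose
  mean_area_km2: 9409.0
  days_per_hunter: 6.0
  canid_ar: [0.5, 0.25]                   # AR(1) phi, innovation SD (log scale)
  deer_ar: [0.5, 0.35]
  poisson_counts: true
  floor: 1.0
  params:                                 # generative population-level truth
    r_max: 0.487
    mu_b: -0.058
    sigma_b: 0.015
    mu_beta_canids: -0.195
    sigma_beta_canids: 0.06
    mu_beta_cN: 0.023
    sigma_beta_cN: 0.008
    mu_beta_deer: -0.022
    sigma_beta_deer: 0.012
    beta_bears: -0.013
    sigma_proj: 0.08
    mu_alpha: -0.445
    sigma_alpha: 0.15
    theta_days: 0.734
    theta_snow: 0.028
    sigma_theta_days: 0.08
    sigma_theta_snow: 0.01
    sigma_obs: 0.15

elasticity:
  deltas: [0.01, 0.05, 0.10]
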