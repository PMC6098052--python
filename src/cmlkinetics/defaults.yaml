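# All numeric defaults of the package live here, never in code.

units:
  days_per_month: 30.44

filters:
  min_timepoints: 5
  early_window_months: 4.5
  min_early_measurements: 2
  first_measurement_max_month: 0.5
  min_followup_months: 18.0
  max_gap_months: 24.0
  prediction_followup_months: 60.0
  prediction_tolerance_months: 3.0

robustness:
  high_ratio_threshold_percent: 10.0
  mode: none            # none | halve | omit  (measurements above threshold)

biexp:
  exp_base: e           # e | 10 : base of the exponentials in the decline model
  n_starts: 10
  max_iter: 300
  bootstrap:
    n_boot: 1000
    level: 0.95
    grid_start_months: 0.0
    grid_stop_months: 60.0
    grid_step_months: 1.0
    max_refit_failure_rate: 0.2

population:
  # fixed effects per arm (percent scale intercepts, per-month slopes)
  imatinib:  {A: 37.375, alpha: 0.674, B: 0.196, beta: 0.039}
  dasatinib: {A: 37.375, alpha: 1.168, B: 0.196, beta: 0.048}
  # between-patient SDs: lognormal for A, alpha, B; additive normal for beta
  omega: {log_A: 0.4, log_alpha: 0.3, log_B: 0.6, beta: 0.015}
  sigma_res: 0.25       # residual SD on the LRATIO (log10) scale
  ql_percent: 0.0032    # quantification limit (MR4.5 scale)
  dropout_hazard: 0.0   # per-visit probability of ending follow-up
  max_param_redraws: 10000

schedule:
  # monitoring design: every 3 months to month 24, then every 6 months
  dense_step_months: 3.0
  dense_until_months: 24.0
  sparse_step_months: 6.0
  end_months: 60.0

mechanistic:
  base:
    n_stem: 5000
    a_min: 0.002
    a_max: 1.0
    bin_factor: 1.4          # per-step affinity gain in A and loss divisor in Omega
    cycle_hours_normal: 49.0
    cycle_hours_leukemic: 24.0
    step_hours: 1.0
    f_omega: {min: 0.4, max: 0.4, half_frac: 0.1, hill: 2.0}   # normal activation vs N_Omega
    f_alpha: {min: 0.01, max: 3.0, half_frac: 1.0, hill: 4.0}  # deactivation vs N_A
    f_omega_leuk: 2.0        # unregulated leukemic activation amplitude
    pb_amplification: 1024.0
    pb_lifespan_days: 10.0
    burn_in_steps: 12000
    kill_in_quiescence: false
  sim:
    horizon_months: 60.0
    sample_step_months: 1.0
    replicates: 3
    pb_floor_percent: 1.0e-05   # simulated ratios below this are treated as censored

screen:
  # full-scale five-parameter grid (10 x 16 x 13 x 10 x 13 = 270,400)
  default_grid:
    lratio_init:  {start: 0.8,   stop: 2.0,  num: 10, scale: linear}
    r_deg:        {start: 0.03,  stop: 0.3,  num: 16, scale: log}
    r_trans:      {start: 5.0e-4, stop: 0.05, num: 13, scale: log}
    f_omega_cml:  {start: 0.05,  stop: 1.0,  num: 10, scale: log}
    f_alpha_cml:  {start: 1.0,   stop: 2.0,  num: 13, scale: log}
  coarse_grid:
    lratio_init:  {start: 1.2,   stop: 2.0,  num: 3, scale: linear}
    r_deg:        {start: 0.05,  stop: 0.3,  num: 3, scale: log}
    r_trans:      {start: 1.0e-3, stop: 0.025, num: 3, scale: log}
    f_omega_cml:  {start: 0.1,   stop: 1.0,  num: 3, scale: log}
    f_alpha_cml:  {start: 1.0,   stop: 2.0,  num: 3, scale: log}

matching:
  containment_step_months: 1.0
  tau_list_months: [24.0, 36.0, 48.0]
  full_tau_months: 60.0
  classify_time_months: 60.0
  universe: union           # union | table

crossval:
  n_boot_band: 300          # reduced bootstrap size for the per-tau bands
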