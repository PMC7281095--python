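schema: 1
geometry:
  W_um: 1000
  h_um: 100
  L_cc_um: 5000
fluids:
  mu_R_cP: 1.0
  mu_T_cP: 2.95
  label_R: 1x PBS
  label_T: blood (Hct 50%, PBS)
protocol:
  period_s: 240
  duty: 0.5
  Q_R_mLh: 0.5
  Q_T_on_mLh: 0.5
  n_periods: 3
  dt_s: 0.5
compliance:
  lambda_on_s: 3.16
  lambda_off_s: 5.9
analysis:
  window_off_s: 60.0
  window_on_s: 20.0
  steady_frac: 0.25
  conv_tol: 0.01
  ts_s: 60.0
  Q_min_mLh: 0.1
calibration:
  slope_mm_s_per_mLh: 2.0732
  diluent: 1x PBS
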