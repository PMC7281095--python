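schema: 1
seed: 1
fluids:
  mu_T_cP: 2.95
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
aggregation:
  amplitude_gray: 10.0
  tau_s: 20.0
  gate_velocity_mm_s: 0.05
  flow_brightness_gray_per_mm_s: 2.0
  i_base_gray: 80.0
noise:
  beta_rel: 0.01
  intensity_gray: 0.1
  velocity_mm_s: 0.02
calibration:
  slope_mm_s_per_mLh: 2.0732
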