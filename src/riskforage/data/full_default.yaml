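# Default two-location model parameters (rates per second, dt = 1 s).
# Predator switching uses the 0.01/s timescale of the habitat process; see
# docs/methods.md for the rationale.
kind: full
model:
  gamma_AP: 0.01
  gamma_PA: 0.01
  gamma_GB: 0.01
  gamma_BG: 0.01
  lambda_oi_plus: 0.5
  lambda_oi_minus: 0.1
  lambda_od_plus: 0.9
  lambda_od_minus: 0.1
  rho_rG: 0.8
  rho_pG: 0.2
  rho_rB: 0.2
  rho_pB: 0.8
  r_feed_rich: 2.0
  r_feed_poor: 1.0
  r_rest: 0.0
  r_transit: -0.1
  r_assess: -0.1
  r_freeze: -0.1
  r_escape: -1.0
  r_pred: -100.0
  delta_by_action:
    feed: 0.05
    transit: 0.05
    escape: 0.05
    assess: 0.02
    freeze: 0.01
    rest: 0.0
  c_d: 0.0
  alpha: 0.1
  dt: 1.0
  d_beta: 0.01
  tau_set: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
  escape_effective: true
solver:
  tol: 1.0e-8
  max_iter: 10000
  grid_mode: bilinear
  interruptible: false
protocol:
  # 2 min predator absent, 2 min present, 2 min absent; habitat free-running
  segments: [[120.0, false], [120.0, true], [120.0, false]]
  n_trials: 1000
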