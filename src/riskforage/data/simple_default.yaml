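# Default single-location (terminating) model: per-step probabilities.
kind: simple
model:
  p_arrive: 0.01
  p_catch: 0.1
  r_feed: 1.0
  r_catch: -100.0
  c_d: 0.0
  lambda_oi_plus: 0.5
  lambda_oi_minus: 0.1
  lambda_od_plus: 0.9
  lambda_od_minus: 0.1
  d_beta: 0.01
  tau_set: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
protocol:
  n_trials: 1000
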