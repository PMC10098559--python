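# Study-protocol defaults: paradigm timing, preprocessing, wrapper cost and
# search budget. Values here are the package defaults spelled out; passing
# this file is equivalent to passing nothing.
paradigm:
  n_channels: 36
  fs_acquire: 12.5
  fs_target: 10.0
  n_trials_per_class: 10
  classes: ["MA", "baseline"]
  cue_s: 2.0
  task_s: 10.0
  rest_s_range: [15.0, 17.0]
  pre_rest_s: 60.0
  post_rest_s: 60.0
noise:
  drift_per_min: 0.01
  mayer_freq: 0.1
  mayer_amp: 0.2
  resp_freq: 0.25
  resp_amp: 0.1
  cardiac_freq: 1.0
  cardiac_amp: 0.1
  white_sd: 0.2
amplitude: 1.0
filter:
  lp_cutoff: 0.1
  hp_cutoff: 0.01
  order: 3
  zero_phase: true
cost:
  alpha: 0.99
  beta: 0.01
  k: 5
  holdout_fraction: 0.2
  binarize_threshold: 0.5
  empty_mask_cost: 1.0
search:
  t_max: 100
  pop_size: 10
  n_runs: 10
# per-algorithm parameters
pso: {inertia: 0.9, inertia_end: 0.4, a1: 2.0, a2: 2.0, vmax: 0.5}
cso: {alpha_step: 1.0, levy_lambda: 1.5, pa: 0.25}
fa: {beta0: 1.0, gamma: 1.0, alpha_rand: 1.0}
ba: {fmin: 0.0, fmax: 2.0, loudness0: 2.0, loudness_decay: 0.9, pulse_growth: 0.9, pulse0: 0.5}
fpo: {p_switch: 0.8, levy_lambda: 1.5, step_scale: 1.0}
woa: {b: 1.0}
gwo: {}
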