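subject: explicit
optimizer_variants:
- dynamic: true
  e_ratio: 0.2
- dynamic: true
  e_ratio: 0.4
- dynamic: false
  e_ratio: 0.2
- dynamic: false
  e_ratio: 0.4
n_iterations: 100
n_repetitions: 100
n_initial: 3
input_bounds:
- -15.0
- 15.0
noise_sd: 0.1
y_obj: 1.0
master_seed: 0
osc_coefficient: 13.0
shared_initial_across_reps: false
noise_feedback: false
grid_size: 301
alpha: 0.05
fit_alpha: false
alpha_max: 0.95
noise_variance_bounds:
- 1.0e-06
- 1.0
optimizer_options: {}
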