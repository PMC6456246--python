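# Reference study conditions: 100 networks per cell on the 11 x 10
# balance-density grid at n = 100, one million steps per run.
# This is a multi-day single-CPU computation; see desk_sweep.yaml for a
# scaled-down version that finishes in minutes.
n: 100
balance_values: [-1.0, -0.8, -0.6, -0.4, -0.2, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
density_values: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
symmetry_values: [0.0]
ensemble_size: 100
master_seed: 1
t_max: 1000000
lyapunov:
  eps: 1.0e-08
  transient: 1000
  horizon: 10000
corr_window: 10000
corr_transient: 1000
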