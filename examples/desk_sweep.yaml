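# Desk-scale sweep: coarse grid, 10 networks per cell, 1e5-step horizon.
# Run with:  rnndyn sweep --config examples/desk_sweep.yaml --out results/desk
n: 100
balance_values: [-0.8, -0.4, -0.2, 0.0, 0.2, 0.8]
density_values: [0.2, 0.5, 0.9]
symmetry_values: [0.0]
ensemble_size: 10
master_seed: 1
t_max: 100000
lyapunov:
  eps: 1.0e-08
  transient: 1000
  horizon: 10000
corr_window: 10000
corr_transient: 1000
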