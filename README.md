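# rnndyn

Dynamics of random recurrent sigmoid networks under weight-statistics
control.

`rnndyn` is for computational neuroscientists and dynamical-systems
researchers who want to ask: *given only coarse statistics of a synaptic
weight matrix — how dense it is, how excitation and inhibition balance, how
symmetric it is — what long-time behavior does the network show?* The
package generates random weight matrices with prescribed statistics,
simulates the deterministic network map, measures chaos, periodicity and
correlation, and aggregates ensembles into dynamical phase diagrams.

## Model

A network of `n` logistic units with zero bias, updated synchronously:

    z_i(t) = Σ_j w_ij y_j(t-1),      y_i(t) = 1 / (1 + e^{-z_i(t)}),

with `w_ii = 0`. Nonzero weight magnitudes are log-normal
(`ln|w| ~ N(μ, σ)`, default μ=0, σ=1). An ensemble is prescribed by three
statistics over the `m` nonzero weights:

* **density**   `d̂ = m / (n(n-1))` ∈ [0, 1]
* **balance**   `b̂ = (m₊ - m₋) / m` ∈ [-1, 1]
* **symmetry**  `ŝ = m_s / m` ∈ [0, 1]   (`m_s` = entries with `w_ji = w_ij` exactly)

Per network the package measures the maximum Lyapunov exponent λ (Benettin
two-trajectory renormalization), the attractor period `T` (first recurrence
of the state, found by hashing quantized states with full-period
verification; `T = 1` is a fixed point, no recurrence within the horizon is
censored), and `ρ_rms`, the RMS of all pairwise Pearson correlations between
neuron time series. Per ensemble cell it reports `f_pos` (fraction with
λ > 0), `T_av`, the censored fraction and the mean `ρ_rms`.

## Worked example

```python
import numpy as np
from rnndyn import (WeightConfig, generate_weight_matrix, measure_balance,
                    random_initial_state, summarize_network, run_ensemble)

# one inhibition-dominated network
cfg = WeightConfig(n=100, density=0.5, balance=-0.8, symmetry=0.0, seed=1)
W = generate_weight_matrix(cfg)
y0 = random_initial_state(100, np.random.default_rng(1))
s = summarize_network(W, y0, t_max=100_000)
print(f"balance={measure_balance(W):+.3f}  lambda={s.lyapunov:+.3f}  "
      f"T={s.period}  rho_rms={s.rho_rms:.3f}")

# an ensemble cell deep in the excitation-dominated regime
cell = run_ensemble(n=100, balance=0.8, density=0.5, symmetry=0.0,
                    ensemble_size=20, master_seed=1, t_max=100_000)
print(f"f_pos={cell.f_pos}  T_av={cell.t_av}  rho_rms={cell.rho_rms_mean}")
```

prints

```
balance=-0.800  lambda=-6.109  T=2  rho_rms=1.000
f_pos=0.0  T_av=1.0  rho_rms=1.0
```

The inhibition-dominated network oscillates with period 2 (strongly negative
λ: regular dynamics; ρ_rms = 1: all units locked to the cycle), while the
excitation-dominated ensemble lands entirely on stationary fixed points
(`T_av = 1`, no positive Lyapunov exponents). Near-balanced networks in
between are chaotic: λ > 0, no state recurrence within the horizon, and
decorrelated activity (low ρ_rms). See `docs/methods.md` for the regime
structure this implementation actually measures, including two regime
details it deliberately reports as measured rather than as expected.

## Command line

```sh
rnndyn generate --n 100 --density 0.5 --balance -0.2 --seed 1 --out net.mtx
rnndyn simulate --matrix net.mtx --steps 10000 --seed 2 --out traj.csv
rnndyn measure  --matrix net.mtx --seed 2 --tmax 100000 --out summary.json
rnndyn sweep    --config sweep.yaml --out results/
```

Matrices are MatrixMarket files with a JSON sidecar of the prescribed and
measured statistics; sweeps take a YAML/JSON config mirroring
`EnsembleSpec` and write `phase_grid.csv`, `metadata.json` and optional
heatmap PNGs.

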