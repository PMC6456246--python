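# Methods

## Model

A network of `n` sigmoid units with zero bias evolves by the synchronous map

    z_i(t) = Σ_j w_ij y_j(t-1),        y_i(t) = 1 / (1 + exp(-z_i(t))),

a deterministic autonomous dynamical system on `(0,1)^n`. Self-connections
are forbidden (`w_ii = 0`). The logistic function is evaluated with
`scipy.special.expit` and clamped to the open interval: for `z < ~-745` the
result underflows to exactly `0.0` and for `z > ~37` it rounds to exactly
`1.0`, either of which would leave the state space, so outputs are clipped to
the nearest interior representable doubles. All state arrays are float64;
identical inputs produce bit-identical trajectories.

## Weight-matrix ensemble

A network is drawn from an ensemble prescribed by three counting statistics
over the `m` nonzero weights (`m+` positive, `m-` negative, `m_s` with an
exactly equal mirror entry `w_ji = w_ij`):

* density  `d = m / (n(n-1))`,
* balance  `b = (m+ - m-) / m`,
* symmetry `s = m_s / m`.

Magnitudes are log-normal, `ln|w| ~ Normal(mu, sigma)` with defaults
`mu = 0, sigma = 1`, mimicking the heavy-tailed synaptic strength
distributions observed in cortex.

Construction, all draws from one seeded `numpy` Generator in a fixed order
(support, magnitudes, signs, swaps):

1. **Counts.** `m = round(d·n(n-1))`; for the symmetric path the upper
   triangle gets `m_u = round(d·n(n-1)/2)` cells so that the mirrored matrix
   satisfies `|m - d·n(n-1)| ≤ 1`. Negative counts are `round(m(1-b)/2)`
   (or the per-triangle analogue), so `|b_measured - b| ≤ 2/m`. Rounding is
   deterministic and unbiased to ±0.5. A prescription whose counts round to
   zero raises a generation error rather than falling back silently.
2. **Support.** Nonzero positions are drawn uniformly without replacement
   among the admissible cells (off-diagonal, or strictly upper-triangular
   for `s > 0`).
3. **Signs.** A uniformly chosen subset of the nonzero weights of size
   `round(m(1-b)/2)` is multiplied by −1.
4. **Symmetry.** For `s > 0` the signed upper triangle is copied below the
   diagonal (value *and* sign, so mirror equality is exact), then pairs of
   below-diagonal cells — zero cells included, which is necessary to reach
   low symmetry at low density — are chosen uniformly and their values
   exchanged until the measured symmetry is within `4/m` of the target
   (the granularity of one swap, which changes `m_s` by at most 4). A swap
   that would *increase* the match count is undone; unconditionally random
   swaps can re-create matches and stall arbitrarily close to the target.
   Because swaps only permute the lower-triangle value multiset, `m`, `m+`,
   `m-` — hence density and balance — are preserved exactly. The `s = 0`
   path skips mirroring entirely. Mirroring-then-swapping can leave residual
   correlations of magnitudes between the two triangles; no correction is
   applied.

Symmetry equality is tested by exact float comparison: matched pairs are
created by copying, and coincidental equality of independent log-normal
draws has probability ~0.

## Measures

**Maximum Lyapunov exponent.** Benettin two-trajectory scheme: a companion
trajectory displaced by `eps` is co-evolved; each step the log of the
separation growth is recorded and the companion is pulled back to distance
`eps` along the current separation direction; the estimate is the mean log
stretch over `horizon` steps after `transient` steps of relaxation. Defaults
`eps = 1e-8` (far above float quantization noise ~1e-16, far below the O(1)
state scale), `transient = 1e3`, `horizon = 1e4`, reporting floor −50 when
the separation underflows to zero (infinitely contracting maps). The
estimator takes any deterministic vector map; the test suite validates it on
the logistic map at `r = 4` (λ = ln 2 exactly) and against the fixed-point
linearization λ = ln(spectral radius of `diag(y*(1-y*))·W`). During
development it was additionally cross-checked against exact tangent-space
(Jacobian-product) integration, agreeing to three decimals on every probed
network. Chaos is scored as strictly `λ > 0` with no dead band; estimator
noise is absorbed by the ensemble statistic `f_pos`.

**Attractor period.** The first recurrence time `T` of the network state
(`T = 1` is a fixed point). States are quantized to multiples of
`quantum = 1e-12` — far below dynamical scales, far above accumulated
rounding error at these horizons; bare float states would never repeat for
attractors approached asymptotically. Each quantized state is hashed; on a
hash hit the putative cycle is verified by re-simulating one full period and
requiring quantized equality at every step. The hash table keeps *all*
occurrence times per key, tried oldest-first: keeping only the first time
would let a transient state that aliases onto an attractor key block every
later detection (a bug class caught by the brute-force oracle, against which
the detector is tested exhaustively on small networks). A run with no
verified recurrence within `t_max` is reported censored at `t_max`; censored
runs enter the ensemble mean `T_av` at `t_max`, so chaotic cells show a
diverging `T_av`, and the censored fraction is reported separately.

**Cross-correlation RMS.** Population-moment Pearson coefficients between
all ordered pairs of neuron time series over a post-transient window
(defaults: last 1e4 steps after a 1e3-step transient; configurable — a fixed
window bounds memory for long runs). A series with standard deviation below
`1e-12` counts as constant and its correlations are defined as exactly 1,
so a fixed-point window yields `rho_rms = 1`; independent series yield about
`1/sqrt(n)` (diagonal terms only). The diagonal is included in the mean over
all `n²` ordered pairs.

## Ensembles and phase grids

A grid cell `(balance, density, symmetry)` is summarized over an ensemble of
networks by `f_pos` (fraction with λ > 0), `T_av`, the censored fraction and
the mean `rho_rms`. Member `k` of cell `i` derives all its randomness from
`SeedSequence((master_seed, i, k))`, so cells are independent, reproducible
in isolation, and order-invariant. Reference-scale defaults follow the study
conditions (100 networks per cell, `t_max = 1e6`, 11×10 balance-density
grid spanning [−1, 1] × [0.1, 1]; density 0 is excluded because balance and
symmetry are undefined for an empty matrix). Tests and the acceptance script
use desk-scale ensembles — 10-20 networks, `t_max = 1e5`, Lyapunov horizon
1e4 — which are this package's chosen problem sizes for routine runs;
regime-level fractions at ensemble size 20 carry sampling noise of order
1/√20 ≈ 0.22.

An infeasible prescription inside a sweep marks that cell failed (with the
reason) without aborting the other cells.

## Empirical regime structure, and two deliberate non-reproductions

With everything above implemented as stated, scanning balance upward at
fixed density and `s = 0` traverses periodic (`T_av ≈ 2`) → chaotic →
fixed-point (`T_av = 1`) regimes, the three measures are mutually consistent
(chaotic cells: `f_pos` high, censored periods, low `rho_rms`), and the
chaotic band narrows as density grows. Two widely quoted regime details do
*not* emerge from this model, and the package reports what it measures
rather than the expected values:

1. **Band location.** The chaotic band at `n = 100` peaks at balance
   ≈ −0.2…0, not at +0.1: a positive balance surplus produces a strong mean
   drive (mean activity ≈ 0.72 already at balance 0.1, density 0.9) that
   saturates units and quenches the local gain `y(1-y)`. At density 0.2,
   balance 0.1 the ensembles sit at the *edge* of chaos — very long periods,
   `T_av ~ 2·10^4`, `f_pos ≈ 0-0.1` — rather than deep inside it. Because
   the Benettin estimate coincides with exact tangent-space integration,
   this is a property of the model, not of the estimator. A one-step,
   non-renormalized divergence estimate (a plausible alternative reading of
   the finite-difference definition of λ) is biased positive for non-normal
   Jacobians in mid-activity regions and would shift the apparent band
   toward positive balance.
2. **Fully symmetric networks.** At `s = 1` synchronous symmetric networks
   generically settle into period-2 cycles when inhibition is present
   (measured `T_av = 2.0` at balance ≤ 0), in line with the classical
   result that symmetric synchronous networks have eventual period dividing
   two; fixed points dominate only at positive balance. λ is negative
   throughout, so the *non-chaotic* character of the symmetric plane does
   reproduce — but "all fixed points irrespective of balance" does not.

## Synthetic scope

All inputs are generated internally; there is no external data. The
ensembles emulate random recurrent connectivity with controlled first-order
weight statistics. They do not emulate Dale's principle (sign-consistent
neurons), degree heterogeneity beyond the binomial support law,
magnitude-weighted symmetry, external drive, or stochastic units — so
passing tests say nothing about those features of biological networks.

## Degenerate inputs and tie-breaks

* `n = 1` is rejected (no admissible connections); `m = 0` makes balance and
  symmetry undefined and raises.
* Balance ±1 and symmetry 0 or 1 are exact: no negation / no swap step fires,
  and `s = 1` outputs satisfy `W == W.T` bitwise.
* `argmax` over a balance scan returns the first maximizer on ties
  (numpy convention).
* `fraction_positive` uses strict `> 0`; an exactly zero λ counts as
  non-chaotic.
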