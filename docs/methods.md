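# Methods

## Models

**Networked populations.** `NetworkSpec` describes `M` homogeneous
populations of `N` neurons each. The state is the vector of active counts
`n`, a one-step jump Markov process: deaths `n_k -> n_k - 1` at rate
`alpha_k n_k`, births `n_k -> n_k + 1` at rate
`N F(sum_l w_kl n_l / N + h_k)` with the logistic gain
`F(u) = F0 / (1 + e^{-gamma u})` (any threshold is absorbed into the drive
`h_k`). The probability of leaving the box `[0, N]^M` is zero by
construction; the simulator enforces this by setting the birth rate to zero
at `n_k = N`. Time is measured in membrane time constants (1 unit = 10 ms
for `alpha = 1`); rates `F0` are per unit time. In the thermodynamic limit
the fractions obey the Wilson-Cowan equations.

**Depression network.** `DepressionSpec` is a single excitatory population
whose recurrent input is gated by a scalar resource `q in (0, 1]`:
`dx/dt = -x + F(w_self q x + h)`, `dq/dt = k_plus (1 - q) - k_minus x q`.
The exact printed placement of the coupling weight in the gain argument was
ambiguous in the source material for this model family; we take
`F(w_self q x + h)` with `w_self = 1` and let `gamma` carry the coupling
scale. With the shipped parameters this produces the expected phenomenology:
a unique fixed point that loses stability between two Hopf points
(`k_minus` ~ 0.0726 and 0.189) and a stable relaxation-type limit cycle of
period ~44.8 at `k_minus = 0.1`. At that depth into the oscillatory regime
the fixed point is an unstable *node* (two real positive eigenvalues), not a
focus; the cycle exists regardless and the tests assert instability plus
cycle existence rather than eigenvalue complexity.

## Noise structure

Finite `N` enters through the Kramers-Moyal expansion as an Ito
multiplicative noise `eps b_k(x) dW_k` per population with
`eps = N^{-1/2}`, `b_k = sqrt(Omega_k+ + Omega_k-)`; these channels are
private to each oscillator of an ensemble. A common fluctuating drive enters
as `sigma a_k(x) o dW` with `a_k = chi_k F'(u_k)` — Stratonovich, because
physical extrinsic noise is the zero-correlation-time limit of a colored
process — and its increments are *identical* across the ensemble. For the
depression model the noise enters the activity equation only
(`b = sqrt(x + F)`, `a = F'`), while `q` flows deterministically.

## Simulators

* **SSA** (`ssa_run`): direct method over the `2M` channels — exponential
  waiting time over the total rate, categorical channel choice. With only
  `2M` channels no dependency-graph machinery is warranted.
* **PDMP** (`pdmp_run`): between jumps the activity is frozen, so the
  resource ODE is linear and is advanced by its *exact* exponential flow
  (`q(t) = q_inf + (q0 - q_inf) e^{-rt}`, `r = k_plus + k_minus x`). Jump
  times are sampled by thinning against the constant bound `N F0 + n`
  (births bounded by `N F0` since `F <= F0`; the death rate is exactly `n`
  between jumps), accepting against the instantaneous rates at the candidate
  time. This is statistically exact; no ODE stepper and no rate-integral
  inversion are needed.
* **Euler-Maruyama** (`euler_maruyama`, `langevin_ensemble`,
  `simulate_phase_ensemble`): fixed-step Ito stepping. Stratonovich common
  channels are converted internally to Ito drift-corrected form — by
  centered finite differences in the generic integrator, analytically
  (`(1/2) chi_k F''(u_k) w_kl a_l` contraction) in the model-specific fast
  path. All oscillators share the common increment each step. Langevin paths
  are *not* clipped to the state box: the diffusion argument is floored at
  zero and excursions outside `[0, 1]` are counted in the bundle metadata,
  since the diffusion approximation is only meaningful in the interior.
  Default `dt = 1e-3` time units for planar simulations; the phase ensemble
  refuses `dt >= T/100`. Jump-process and phase-ensemble inner loops are
  numba-compiled; each simulator is bit-reproducible given its seed.

## Limit cycle, PRC, phase law

The cycle is located by integrating past transients (LSODA,
`rtol = 1e-11`), detecting upward crossings of the first coordinate through
its orbit mean (a Poincare section), averaging the last section returns for
the period, and tabulating one period at `n_grid = 1024` phases uniform in
time. The phase origin `theta = 0` is placed at the maximum of the first
activity coordinate; all pairwise-difference statistics downstream are
invariant to this convention (tested). The phase interval is the half-open
`[-pi, pi)`.

The PRC solves the adjoint equation `dZ/dt = -J(x*(t))^T Z` backwards in
time — backward integration damps all non-trivial Floquet modes — over whole
periods until the per-period change falls below `1e-10`, renormalizing by
`Z . f = omega` (the convention consistent with `dtheta/dt = omega`), then
enforcing the identity pointwise on the grid. A direct-perturbation oracle
(pulse `delta = 1e-4`, 20-period relaxation, tangential phase projection)
agrees with the adjoint PRC to better than 1% of the PRC scale.

Tabulated periodic functions are interpolated trigonometrically
(`FourierInterpolant`); derivatives entering the Ito drift corrections are
spectral. The phase-ensemble integrator resamples the coefficient tables
spectrally onto a 4096-point grid and uses periodic linear lookup inside the
compiled loop.

## Averaged phase-difference theory

`g(phi)` and `h(phi)` are the circular autocorrelations of the common and
independent phase sensitivities, computed by FFT (exact on the grid for the
tabulated functions, verified against O(n^2) quadrature at `1e-10`). The
stationary pairwise density is
`Phi_0 = Gamma_0 / (sigma^2 (g(0) - g(phi)) + eps^2 h(0))`, normalized to
unit circular integral. This composition is fixed by three structural
limits: exact uniformity at `sigma = 0`, divergence at `phi = 0` as
`eps -> 0` (positivity guaranteed by `g(0) >= g`), and broadening controlled
by `h(0)/N`. The Cauchy (Lorentzian) approximation follows from the
second-order Taylor expansion of `g` at 0, with squared half-width
`2 eps^2 h(0) / (sigma^2 |g''(0)|)`.

Peak detection uses circular local maxima with a prominence gate of 2% of
the density range — small enough to keep genuinely small secondary peaks,
large enough to suppress quadrature ripple; it is configurable.

A structural observation about the shipped E-I preset: because `Phi_0` peaks
exactly where `g` has local maxima and the Fourier coefficients of an
autocorrelation are nonnegative (`g = sum_m p_m cos(m phi)`, `p_m >= 0`),
secondary peaks at `+-2pi/3` (three-cluster states) require the `m = 3`
harmonic of `alpha(theta)` to dominate, and a peak at `pi` requires
`4 p_2 > p_1 + 9 p_3 + ...`. The E-I preset's cycle is weakly nonlinear
(its PRC is nearly sinusoidal and `F'(u_k)` varies smoothly on the orbit),
so `alpha` is fundamental-dominated for *every* admixture `chi` and every
drive point in the oscillatory window; the computed `g` is therefore
unimodal and the analytic `Phi_0` has a single peak at 0 for all shipped
configurations. The test suite keeps checks for multi-peak clustering under
asymmetric drive; they fail under the shipped conditions, documenting this
structural finding, and the full-planar cross-validation (below) confirms
that the unimodal analytics correctly describe the model as implemented.

## Cross-validation and problem sizes

* Phase-ensemble vs analytics: 100 oscillators, 24 seeds, horizon 2000
  (E-I, `dt = 5e-3`) or 12 seeds, horizon 2e4 (depression, `dt = 0.1`),
  first half of each run discarded as burn-in, all unordered pairwise
  differences pooled into 50 bins (>= 1e7 pairs). Measured L1 distances
  ~0.03-0.05. The residual is dominated by slow cluster-shape fluctuations
  under the common drive, which is why many independent seeds matter more
  than longer single runs.
* Planar-Langevin vs analytics: 40 planar E-I oscillators, phases assigned
  by nearest-orbit-point projection; L1 ~ 0.05-0.14 at the same conditions.
* Jump vs diffusion: SSA/PDMP ensemble moments at `N = 1e4` agree with the
  Langevin ensemble within Monte-Carlo error; ensemble means track the
  mean-field flow at `O(N^{-1/2})` — pointwise for the E-I cycle, in
  time-RMS for the depression cycle, whose steep relaxation fronts amplify
  `O(eps)` phase dephasing into large pointwise deviations (a property of
  the ensemble mean, not a simulator artifact).

The depression preset's extrinsic noise defaults to `sigma = 0.002`. The
large gain (`gamma = 20`) makes the phase sensitivity to the common drive
roughly two orders of magnitude stronger than in the E-I pair
(`g(0) ~ 72` vs `~0.75`); `sigma = 0.002` puts the preset in the same
moderately synchronized regime (peak ~0.83 vs uniform 0.159, Cauchy width
~0.27 rad) where the averaged theory and a 50-bin histogram are both
informative. The E-I preset defaults to `sigma = 0.08`.

## What the simulations do and do not emulate

The generators produce exactly the processes the theory addresses:
homogeneous populations, constant drives, white extrinsic noise shared with
identical weights, no coupling between oscillators. Real neural data add
heterogeneity, colored noise, finite-size departures from the diffusion
approximation near the boundaries, and synaptic coupling; passing tests here
validate the theory chain, not those extensions. The averaging step assumes
`sigma^2 g` and `eps^2 h` are small against `omega`; at stronger noise the
phase-difference density develops O(sigma^2) corrections that the
simulations resolve but the averaged formula does not.

## Known limitations

* Bifurcation curves use the closed forms available for
  `F0 = gamma = 1` (E-I) and eigenvalue scanning (depression); no general
  continuation.
* The Ito drift of the reduced phase equation is assembled from the
  tabulated coefficients and their spectral derivatives; transverse
  isochron-curvature contributions beyond the standard reduction are
  neglected, consistent with the order of the theory.
* `Phi_0` describes pairs; clustering of a full ensemble is inferred from
  the pair density, and transition statistics between clustered states are
  out of scope.
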