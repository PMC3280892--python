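# stochsync

Noise-induced synchronization of stochastic neural population oscillators.

## The problem

Populations of cortical neurons can oscillate collectively (e.g. gamma-band
rhythms generated by interacting excitatory and inhibitory populations), and
*uncoupled* population oscillators can nevertheless synchronize when they are
driven by a **common fluctuating input**. How well they synchronize is limited
by the **intrinsic noise** of each population, which stems from its finite
size. `stochsync` implements the full analysis chain for this competition:

1. **Master equation.** The number `n_k` of active neurons in population `k`
   (of `N`) follows a birth-death jump process with death rate
   `alpha_k n_k` and birth rate `N F(sum_l w_kl n_l / N + h_k)`, where
   `F(u) = F0 / (1 + e^{-gamma u})`. In the limit `N -> inf` the fractions
   `x_k = n_k / N` obey the Wilson-Cowan equations
   `dx_k/dt = -alpha_k x_k + F(sum_l w_kl x_l + h_k)`.
2. **Langevin approximation.** A Kramers-Moyal expansion in `1/N` gives the
   Ito SDE `dX_k = A_k dt + eps b_k dW_k + sigma a_k o dW`, with
   `eps = N^{-1/2}`, intrinsic amplitudes `b_k = sqrt(Omega_k+ + Omega_k-)`
   (Ito, private per oscillator), and a common extrinsic channel
   `a_k = chi_k F'(u_k)` (Stratonovich, shared by every oscillator). Both
   noises are *multiplicative*.
3. **Phase reduction.** If the deterministic system has a stable limit cycle
   `x*(theta)` with frequency `omega = 2 pi / T`, each oscillator reduces to a
   circular phase with sensitivities given by the adjoint phase-resetting
   curve `Z(theta)` (normalized by `Z . dx*/dt = omega`):
   `dTheta = omega dt + sigma alpha(Theta) o dW + eps sum_k beta_k(Theta) o dW_k`
   with `alpha = sum_k Z_k a_k`, `beta_k = Z_k b_k` on the cycle (plus the
   Ito drift corrections).
4. **Averaging.** The stationary density of the phase difference `phi`
   between any two oscillators is

       Phi_0(phi) = Gamma_0 / [ sigma^2 (g(0) - g(phi)) + eps^2 h(0) ]

   where `g` and `h` are the cycle-averaged circular autocorrelations of
   `alpha` and `(beta_k)`. With `sigma = 0` the density is uniform (complete
   desynchronization); as `N -> inf` it diverges at 0 (complete common-noise
   synchronization); near the peak it is approximately Cauchy with half-width
   `sqrt(2 eps^2 h(0) / (sigma^2 |g''(0)|))`.

Every analytic stage is cross-validated by direct stochastic simulation:
exact SSA for the master equation, exact thinning-based simulation of the
piecewise-deterministic depression model, and Euler-Maruyama ensembles for
the planar Langevin and the reduced phase equations.

Two presets ship with the package: `ei`, a mutually coupled
excitatory-inhibitory pair (`w_EE = 11.5`, `w_IE = -w_EI = 10`,
`w_II = -2`, `h_E = 0`, `h_I = -4`, `F0 = gamma = 1`), and `depression`, a
recurrent excitatory population with synaptic depression (`k+ = 0.02`,
`k- = 0.1`, `gamma = 20`, `h = -0.15`), a stochastic hybrid system in which
the activity jumps while the depression resource flows.

## Worked example

```python
import numpy as np
from stochsync import (preset, find_limit_cycle, compute_prc,
                       build_phase_law, stationary_distribution)

spec = preset("ei")                      # N = 1e5, sigma = 0.08
lc = find_limit_cycle(spec)
prc = compute_prc(lc, spec)
law = build_phase_law(lc, prc, spec)
dist = stationary_distribution(law)

print(f"period T = {lc.period:.4f}, omega = {lc.omega:.4f}")
print(f"Phi0(0) = {dist.phi0[law.n_grid // 2]:.4f}")
print(f"peaks   = {[(round(p[0], 3), round(p[1], 3)) for p in dist.peaks]}")
```

prints

```
period T = 4.2949, omega = 1.4630
Phi0(0) = 0.3324
peaks   = [(0.0, 0.332)]
```

The E-I pair oscillates with period 4.29 membrane time constants (43 ms at
`alpha^{-1} = 10 ms`). At `sigma = 0.08` and `N = 1e5` the phase-difference
density peaks at `phi = 0` at about twice the uniform level `1/(2 pi) =
0.159` — partial synchronization by the common drive, broadened by the
finite-size noise. Lowering `N` flattens the peak; raising it sharpens it.

The same chain runs from the shell:

```
stochsync syncdist --preset ei --out-dir out/      # g, h, Phi_0 tables
stochsync prc      --preset depression --out-dir out/
stochsync pipeline --preset ei --out-dir out/      # everything + manifest
```

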