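"""Stochastic phase reduction of noise-driven population oscillators.

Near its stable limit cycle a noise-driven oscillator is described by a
single circular phase.  Projecting the Langevin dynamics onto the phase via
the PRC gives, in Stratonovich form,

    dTheta = [omega + eps^2 c(Theta)] dt
             + sigma alpha(Theta) o dW  +  eps sum_k beta_k(Theta) o dW_k

where ``alpha(theta) = sum_k Z_k(theta) a_k(theta)`` couples the shared
extrinsic channel, ``beta_k(theta) = Z_k(theta) b_k(theta)`` couple the
private intrinsic channels, all amplitudes evaluated on the limit cycle,
and ``c(theta) = -(1/2) sum_k Z_k b_k (db_k/dx_k)`` is the drift inherited
from the intrinsic noise being Ito in the full system.  Converting to Ito form
adds ``(sigma^2/2) alpha alpha' + (eps^2/2) sum_k beta_k beta_k'``.

``build_phase_law`` assembles these coefficients on the phase grid;
``simulate_phase_ensemble`` integrates the Ito phase equations for an
ensemble sharing the common channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .limit_cycle_prc import PRC, LimitCycle
from .stochastic_sim import (TrajectoryBundle, diffusion_divergence,
                             langevin_drift_diffusion)

__all__ = ["PhaseLaw", "build_phase_law", "simulate_phase_ensemble"]


def _spectral_deriv(values: np.ndarray) -> np.ndarray:
    """d/dtheta of a 2pi-periodic uniform tabulation, by FFT."""
    n = values.shape[0]
    k = np.fft.rfftfreq(n, d=1.0 / n)  # integer wavenumbers
    c = np.fft.rfft(values, axis=0)
    kk = k.reshape((-1,) + (1,) * (values.ndim - 1))
    d = np.fft.irfft(1j * kk * c, n=n, axis=0)
    return d


@dataclass(frozen=True)
class PhaseLaw:
    """Tabulated coefficients of the reduced phase Langevin equation."""

    omega: float
    grid: np.ndarray            # (n,) phases in [-pi, pi)
    common_coeff: np.ndarray    # (n,) alpha(theta), per unit sigma
    indep_coeffs: np.ndarray    # (n, M) beta_k(theta), per unit epsilon
    strat_correction: np.ndarray  # (n,) Ito-origin drift, per eps^2
    epsilon: float
    sigma: float

    @property
    def n_grid(self) -> int:
        return self.grid.size

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega

    @property
    def ito_drift(self) -> np.ndarray:
        """Full Ito drift on the grid: ``omega`` plus the Ito-origin term
        and the Stratonovich-to-Ito conversions of both channels."""
        a = self.common_coeff
        b = self.indep_coeffs
        drift = np.full(self.n_grid, self.omega)
        drift += self.epsilon ** 2 * self.strat_correction
        drift += 0.5 * self.sigma ** 2 * a * _spectral_deriv(a)
        drift += 0.5 * self.epsilon ** 2 * np.sum(
            b * _spectral_deriv(b), axis=1)
        return drift

    def with_noise(self, epsilon: float | None = None,
                   sigma: float | None = None) -> "PhaseLaw":
        return PhaseLaw(
            omega=self.omega, grid=self.grid,
            common_coeff=self.common_coeff, indep_coeffs=self.indep_coeffs,
            strat_correction=self.strat_correction,
            epsilon=self.epsilon if epsilon is None else epsilon,
            sigma=self.sigma if sigma is None else sigma)


def build_phase_law(lc: LimitCycle, prc: PRC, spec) -> PhaseLaw:
    """Assemble the phase-equation coefficients on the limit cycle.

    All amplitudes are evaluated on the deterministic orbit: the common
    coefficient is ``sum_k Z_k a_k``, the independent coefficients are
    ``Z_k b_k``, and the Ito-origin drift is
    ``-(1/2) sum_k Z_k b_k db_k/dx_k`` (per ``eps^2``); noise strengths
    ``epsilon`` (derived from ``spec.N``) and ``sigma`` are carried
    alongside.
    """
    if lc.grid.size != prc.grid.size or not np.allclose(lc.grid, prc.grid):
        raise ValueError("limit cycle and PRC are tabulated on different grids")
    _, b, a = langevin_drift_diffusion(lc.orbit, spec)
    bdb = diffusion_divergence(lc.orbit, spec)
    Z = prc.Z
    alpha = np.sum(Z * a, axis=1)
    beta = Z * b
    strat = -0.5 * np.sum(Z * bdb, axis=1)
    return PhaseLaw(omega=lc.omega, grid=lc.grid, common_coeff=alpha,
                    indep_coeffs=beta, strat_correction=strat,
                    epsilon=spec.epsilon, sigma=spec.sigma)


@njit(cache=True)
def _phase_em_core(theta0, drift_tab, alpha_tab, beta_tab, sigma, eps,
                   dt, n_steps, record_every, seed):
    np.random.seed(seed)
    n_osc = theta0.size
    n_tab = drift_tab.size
    M = beta_tab.shape[1]
    inv_h = n_tab / (2.0 * np.pi)
    theta = theta0.copy()
    n_rec = n_steps // record_every + 1
    out = np.empty((n_rec, n_osc))
    out[0] = theta
    rec = 1
    sq = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        dWc = np.random.normal(0.0, sq) if sigma > 0.0 else 0.0
        for m in range(n_osc):
            # periodic linear interpolation on the uniform table
            pos = (theta[m] + np.pi) * inv_h
            i0 = int(np.floor(pos)) % n_tab
            i1 = (i0 + 1) % n_tab
            w = pos - np.floor(pos)
            d = drift_tab[i0] * (1 - w) + drift_tab[i1] * w
            dth = d * dt
            if sigma > 0.0:
                al = alpha_tab[i0] * (1 - w) + alpha_tab[i1] * w
                dth += sigma * al * dWc
            if eps > 0.0:
                for k in range(M):
                    be = beta_tab[i0, k] * (1 - w) + beta_tab[i1, k] * w
                    dth += eps * be * np.random.normal(0.0, sq)
            th = theta[m] + dth
            # wrap to [-pi, pi)
            th = (th + np.pi) % (2.0 * np.pi) - np.pi
            theta[m] = th
        if step % record_every == 0:
            out[rec] = theta
            rec += 1
    return out[:rec]


def simulate_phase_ensemble(law: PhaseLaw, n_osc: int, horizon: float,
                            dt: float = 1e-3, seed: int = 0,
                            theta0=None, record_every: int | None = None,
                            n_dense: int = 4096) -> TrajectoryBundle:
    """Euler-Maruyama integration of the Ito phase equations.

    Every oscillator receives the identical increment of the common Wiener
    process scaled by its own ``alpha(Theta)``, plus private increments
    scaled by ``beta_k(Theta)``.  Phases are wrapped to ``[-pi, pi)`` each
    step.  Coefficients are resampled spectrally onto a dense table
    (``n_dense`` points) and looked up by periodic linear interpolation.
    """
    if n_osc < 2:
        raise ValueError("an ensemble needs at least two oscillators")
    if dt >= law.period / 100.0:
        raise ValueError(
            f"dt={dt} too coarse: must resolve the cycle "
            f"(dt < T/100 = {law.period / 100:.4g})")
    rng = np.random.default_rng(seed)
    if theta0 is None:
        theta0 = rng.uniform(-np.pi, np.pi, n_osc)
    theta0 = np.asarray(theta0, dtype=float)

    def dense(vals):
        c = np.fft.rfft(vals, axis=0)
        return np.fft.irfft(c, n=n_dense, axis=0) * (n_dense / vals.shape[0])

    drift_tab = dense(law.ito_drift)
    alpha_tab = dense(law.common_coeff)
    beta_tab = np.ascontiguousarray(dense(law.indep_coeffs))

    n_steps = int(round(horizon / dt))
    if record_every is None:
        record_every = max(1, n_steps // 400)
    core_seed = int(rng.integers(0, 2**32))
    out = _phase_em_core(theta0, drift_tab, alpha_tab, beta_tab,
                         law.sigma, law.epsilon, dt, n_steps,
                         record_every, core_seed)
    times = np.arange(out.shape[0]) * (record_every * dt)
    return TrajectoryBundle(times=times, states=out, kind="diffusion",
                            seed=seed,
                            meta={"dt": dt, "epsilon": law.epsilon,
                                  "sigma": law.sigma})
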