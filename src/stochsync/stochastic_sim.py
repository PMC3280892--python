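"""Stochastic simulators: exact jump processes and Langevin integrators.

Three simulation routes are provided.

``ssa_run``
    Statistically exact sampling of the population master equation (a
    one-step birth-death jump process over ``2M`` reaction channels) by the
    direct stochastic simulation algorithm: exponential waiting time over
    the total rate, categorical channel choice.

``pdmp_run``
    Exact simulation of the depression hybrid model — a piecewise
    deterministic Markov process in which the activity count jumps while
    the depression variable flows.  Between jumps the resource ODE is
    linear (the activity is frozen), so the flow is applied in closed form;
    jump times are sampled by thinning against the constant bound
    ``N F0 + n`` (births are bounded by ``N F0`` since ``F <= F0``, deaths
    are exactly ``n`` between jumps).

``euler_maruyama``
    Fixed-step integration of the Langevin (diffusion) approximation for an
    ensemble of oscillators with a diagonal independent (intrinsic) noise
    per oscillator — interpreted in the Ito sense, as produced by the
    Kramers-Moyal expansion — and a single common (extrinsic) channel shared
    by every oscillator — interpreted in the Stratonovich sense and
    converted internally to Ito drift-corrected form.

The drift and noise amplitudes of the Langevin approximation are exposed by
``langevin_drift_diffusion``: drift ``A_k = Omega_k+ - Omega_k-``, intrinsic
amplitude ``b_k = sqrt(Omega_k+ + Omega_k-)`` and common amplitude
``a_k = chi_k F'(u_k)``, all per unit ``epsilon = N**-0.5`` and ``sigma``
respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
from numba import njit

from .model_core import (DepressionSpec, NetworkSpec, sigmoid_gain,
                         sigmoid_gain_deriv)

__all__ = ["TrajectoryBundle", "NoiseLayout", "ssa_run", "pdmp_run",
           "euler_maruyama", "langevin_drift_diffusion"]


@dataclass
class TrajectoryBundle:
    """A simulated path (or ensemble of paths) with its provenance."""

    times: np.ndarray          # (n_t,) strictly increasing
    states: np.ndarray         # (n_t, ...) state records
    kind: str                  # "jump" | "diffusion"
    seed: int
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) < 0):
            raise ValueError("record times must be increasing")


@dataclass(frozen=True)
class NoiseLayout:
    """Wiener-channel layout for an oscillator ensemble.

    Each oscillator carries ``n_independent`` private channels (Ito);
    ``has_common`` adds one channel whose increments are identical across
    the ensemble (Stratonovich, the zero-correlation-time limit of colored
    extrinsic noise).
    """

    n_independent: int
    has_common: bool = True


class SimulationDiverged(RuntimeError):
    pass


# ----------------------------------------------------------------- SSA ---

@njit(cache=True)
def _ssa_core(w, h, alpha, gamma, F0, N, n0, t_eval, seed):
    np.random.seed(seed)
    M = n0.size
    n = n0.astype(np.float64)
    out = np.empty((t_eval.size, M))
    t = 0.0
    idx = 0
    absorbed = False
    rates = np.empty(2 * M)
    while idx < t_eval.size:
        # rates: birth k -> +e_k, death k -> -e_k
        total = 0.0
        for k in range(M):
            u = h[k]
            for l in range(M):
                u += w[k, l] * n[l] / N
            birth = N * F0 / (1.0 + np.exp(-gamma * u))
            if n[k] >= N:      # boundary: no flux above N
                birth = 0.0
            death = alpha[k] * n[k]
            rates[k] = birth
            rates[M + k] = death
            total += birth + death
        if total <= 0.0:
            absorbed = True
            break
        t += np.random.exponential(1.0 / total)
        while idx < t_eval.size and t_eval[idx] < t:
            out[idx] = n
            idx += 1
        if idx >= t_eval.size:
            break
        r = np.random.random() * total
        acc = 0.0
        ch = 2 * M - 1
        for c in range(2 * M):
            acc += rates[c]
            if r < acc:
                ch = c
                break
        if ch < M:
            n[ch] += 1.0
        else:
            n[ch - M] -= 1.0
    while idx < t_eval.size:
        out[idx] = n
        idx += 1
    return out, absorbed


def ssa_run(spec: NetworkSpec, n0, horizon: float, seed: int,
            t_eval=None) -> TrajectoryBundle:
    """Exact sample path of the population master equation.

    Records occupations at ``t_eval`` (default: 200 uniform times over the
    horizon); the path is piecewise constant between jumps so grid sampling
    is exact.  If the total rate vanishes the state is absorbing: the run
    returns early with ``meta['absorbed'] = True``.
    """
    n0 = np.asarray(n0, dtype=np.int64)
    if np.any(n0 < 0) or np.any(n0 > spec.N):
        raise ValueError("initial occupation outside [0, N]")
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 201)
    t_eval = np.asarray(t_eval, dtype=float)
    out, absorbed = _ssa_core(
        np.ascontiguousarray(spec.weights), spec.drive, spec.decay,
        spec.gain.gamma, spec.gain.F0, float(spec.N), n0, t_eval,
        seed % 2**32)
    return TrajectoryBundle(times=t_eval, states=out, kind="jump",
                            seed=seed, meta={"absorbed": bool(absorbed),
                                             "N": spec.N})


# ---------------------------------------------------------------- PDMP ---

@njit(cache=True)
def _pdmp_core(N, k_plus, k_minus, w_self, drive, gamma, F0, n0, q0,
               t_eval, seed):
    np.random.seed(seed)
    n = float(n0)
    q = q0
    t = 0.0
    idx = 0
    out = np.empty((t_eval.size, 2))
    absorbed = False

    while idx < t_eval.size:
        lam = N * F0 + n  # bound: birth <= N*F0, death = n (frozen)
        if lam <= 0.0:
            absorbed = True
            break
        dt_c = np.random.exponential(1.0 / lam)
        x = n / N
        r = k_plus + k_minus * x
        qinf = k_plus / r
        # record any grid times inside (t, t + dt_c]: q flows in closed form
        while idx < t_eval.size and t_eval[idx] < t + dt_c:
            dtg = t_eval[idx] - t
            out[idx, 0] = x
            out[idx, 1] = qinf + (q - qinf) * np.exp(-r * dtg)
            idx += 1
        if idx >= t_eval.size:
            break
        # advance q exactly to the candidate time
        q = qinf + (q - qinf) * np.exp(-r * dt_c)
        t += dt_c
        u = w_self * q * x + drive
        birth = N * F0 / (1.0 + np.exp(-gamma * u))
        if n >= N:
            birth = 0.0
        death = n
        if np.random.random() * lam < birth + death:
            if np.random.random() * (birth + death) < birth:
                n += 1.0
            else:
                n -= 1.0
    while idx < t_eval.size:
        out[idx, 0] = n / N
        out[idx, 1] = q
        idx += 1
    return out, absorbed


def pdmp_run(spec: DepressionSpec, n0: int, q0: float, horizon: float,
             seed: int, t_eval=None) -> TrajectoryBundle:
    """Exact piecewise-deterministic path of the depression hybrid model.

    Between jumps the activity count is frozen, so the resource equation
    ``dq/dt = k+(1-q) - k- x q`` is linear and is advanced by its exact
    exponential flow.  Jump times are sampled by thinning against the
    constant bound ``N F0 + n``, accepting with the instantaneous rates at
    the candidate time.  Records ``(x, q)`` at ``t_eval``.
    """
    if not (0 < q0 <= 1.0):
        raise ValueError("q0 must lie in (0, 1]")
    if not (0 <= n0 <= spec.N):
        raise ValueError("n0 must lie in [0, N]")
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 201)
    t_eval = np.asarray(t_eval, dtype=float)
    out, absorbed = _pdmp_core(
        float(spec.N), spec.k_plus, spec.k_minus, spec.w_self, spec.drive,
        spec.gain.gamma, spec.gain.F0, float(n0), float(q0), t_eval,
        seed % 2**32)
    return TrajectoryBundle(times=t_eval, states=out, kind="jump",
                            seed=seed, meta={"absorbed": bool(absorbed),
                                             "N": spec.N})


# ------------------------------------------------------- Langevin / EM ---

def langevin_drift_diffusion(state, spec):
    """Drift and noise amplitudes of the Langevin approximation at a state.

    Returns ``(A, b, a)``: drift ``A_k`` (difference of jump intensities),
    intrinsic diffusion amplitudes ``b_k = sqrt(Omega_k+ + Omega_k-)``
    (per unit ``epsilon``), and common-noise amplitudes
    ``a_k = chi_k F'(u_k)`` (per unit ``sigma``).

    For the depression model the state is ``(x, q)``; noise enters the
    activity equation only, so ``b = (sqrt(x + F(u)), 0)`` and
    ``a = (F'(u), 0)`` with ``u = w_self q x + h``; the drift includes the
    deterministic resource flow.
    """
    state = np.asarray(state, dtype=float)
    if isinstance(spec, DepressionSpec):
        x, q = state[..., 0], state[..., 1]
        u = spec.w_self * q * x + spec.drive
        f = sigmoid_gain(u, spec.gain)
        A = np.stack([-x + f,
                      spec.k_plus * (1.0 - q) - spec.k_minus * x * q],
                     axis=-1)
        b = np.stack([np.sqrt(np.maximum(x + f, 0.0)),
                      np.zeros_like(x)], axis=-1)
        a = np.stack([sigmoid_gain_deriv(u, spec.gain),
                      np.zeros_like(x)], axis=-1)
        return A, b, a
    u = state @ spec.weights.T + spec.drive
    f = sigmoid_gain(u, spec.gain)
    A = -spec.decay * state + f
    b = np.sqrt(np.maximum(spec.decay * state + f, 0.0))
    a = spec.chi * sigmoid_gain_deriv(u, spec.gain)
    return A, b, a


def diffusion_divergence(state, spec):
    """``b_k * db_k/dx_k`` on a state — the Ito-to-Stratonovich drift shift
    of the intrinsic noise, equal to ``(d(b_k^2)/dx_k) / 2``."""
    state = np.asarray(state, dtype=float)
    if isinstance(spec, DepressionSpec):
        x, q = state[..., 0], state[..., 1]
        u = spec.w_self * q * x + spec.drive
        fp = sigmoid_gain_deriv(u, spec.gain)
        return np.stack([0.5 * (1.0 + spec.w_self * q * fp),
                         np.zeros_like(x)], axis=-1)
    u = state @ spec.weights.T + spec.drive
    fp = sigmoid_gain_deriv(u, spec.gain)
    return 0.5 * (spec.decay + np.diag(spec.weights) * fp)


def euler_maruyama(drift: Callable, x0, horizon: float, dt: float, seed: int,
                   indep_amp: Callable | None = None,
                   common_amp: Callable | None = None,
                   strat_common: bool = True,
                   record_every: int = 1) -> TrajectoryBundle:
    """Fixed-step Euler-Maruyama for an ensemble with shared common noise.

    ``x0`` has shape ``(n_osc, dim)``.  ``drift(x)``, ``indep_amp(x)`` and
    ``common_amp(x)`` map states to arrays of the same shape: independent
    channels are diagonal (one private Wiener process per component per
    oscillator, Ito), while every oscillator receives the *same* increment
    of the single common Wiener process, scaled by ``common_amp``.

    With ``strat_common=True`` the common channel is Stratonovich and the
    conversion drift ``(1/2) sum_l a_l da_k/dx_l`` is added internally
    (derivatives by centered finite differences), so stepping is always in
    Ito form.  Diverging (NaN) states abort with the step and oscillator
    index.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.array(x0, dtype=float)
    if x.ndim != 2:
        raise ValueError("x0 must have shape (n_osc, dim)")
    n_osc, dim = x.shape
    rng = np.random.default_rng(seed)
    n_steps = int(round(horizon / dt))
    rec_t = [0.0]
    rec_x = [x.copy()]
    sq = np.sqrt(dt)
    fd = 1e-6

    def strat_corr(xx):
        a0 = common_amp(xx)
        corr = np.zeros_like(xx)
        for l in range(dim):
            xp = xx.copy(); xp[:, l] += fd
            xm = xx.copy(); xm[:, l] -= fd
            da = (common_amp(xp) - common_amp(xm)) / (2 * fd)
            corr += a0[:, l:l + 1] * da
        return 0.5 * corr

    for step in range(1, n_steps + 1):
        mu = drift(x)
        if strat_common and common_amp is not None:
            mu = mu + strat_corr(x)
        dx = mu * dt
        if indep_amp is not None:
            dW = rng.standard_normal((n_osc, dim)) * sq
            dx = dx + indep_amp(x) * dW
        if common_amp is not None:
            dWc = rng.standard_normal() * sq
            dx = dx + common_amp(x) * dWc
        x = x + dx
        if not np.all(np.isfinite(x)):
            bad = np.argwhere(~np.isfinite(x))
            raise SimulationDiverged(
                f"non-finite state at step {step} (t={step * dt:.4g}), "
                f"oscillator {bad[0][0]} component {bad[0][1]}")
        if step % record_every == 0 or step == n_steps:
            rec_t.append(step * dt)
            rec_x.append(x.copy())
    return TrajectoryBundle(times=np.asarray(rec_t),
                            states=np.asarray(rec_x), kind="diffusion",
                            seed=seed, meta={"dt": dt})


def stratonovich_correction(state, spec):
    """Analytic Stratonovich-to-Ito drift of the common channel, per unit
    ``sigma^2``: ``(1/2) sum_l a_l da_k/dx_l`` with ``a_k = chi_k F'(u_k)``
    so ``da_k/dx_l = chi_k F''(u_k) w_kl`` (for the depression model the
    resource gates the recurrent input: ``da/dx = F'' w q``, ``da/dq =
    F'' w x``)."""
    state = np.asarray(state, dtype=float)
    g = spec.gain
    if isinstance(spec, DepressionSpec):
        x, q = state[..., 0], state[..., 1]
        u = spec.w_self * q * x + spec.drive
        f = sigmoid_gain(u, g) / g.F0
        fp = sigmoid_gain_deriv(u, g)
        fpp = g.gamma * fp * (1.0 - 2.0 * f)
        corr_x = 0.5 * fp * fpp * spec.w_self * q
        return np.stack([corr_x, np.zeros_like(x)], axis=-1)
    u = state @ spec.weights.T + spec.drive
    f = sigmoid_gain(u, g) / g.F0
    fp = sigmoid_gain_deriv(u, g)
    fpp = g.gamma * fp * (1.0 - 2.0 * f)
    a = spec.chi * fp
    return 0.5 * spec.chi * fpp * (a @ spec.weights.T)


def langevin_ensemble(spec, x0, horizon: float, dt: float, seed: int,
                      record_every: int = 1) -> TrajectoryBundle:
    """Ensemble of full (state-space) Langevin oscillators for ``spec``.

    Euler-Maruyama on the Ito form: intrinsic noise ``epsilon b_k`` private
    per oscillator, common extrinsic noise ``sigma a_k`` shared across the
    ensemble with its Stratonovich conversion drift added analytically.
    Langevin paths are not clipped to the state box; the sqrt argument is
    floored at zero and excursions outside [0, 1] are counted in
    ``meta['excursions']``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.array(x0, dtype=float)
    if x.ndim != 2:
        raise ValueError("x0 must have shape (n_osc, dim)")
    n_osc, dim = x.shape
    eps, sig = spec.epsilon, spec.sigma
    rng = np.random.default_rng(seed)
    n_steps = int(round(horizon / dt))
    sq = np.sqrt(dt)
    rec_t = [0.0]
    rec_x = [x.copy()]
    excursions = 0
    for step in range(1, n_steps + 1):
        A, b, a = langevin_drift_diffusion(x, spec)
        mu = A
        if sig > 0:
            mu = mu + sig ** 2 * stratonovich_correction(x, spec)
        dx = mu * dt
        if eps > 0:
            dx = dx + eps * b * rng.standard_normal((n_osc, dim)) * sq
        if sig > 0:
            dx = dx + sig * a * (rng.standard_normal() * sq)
        x = x + dx
        if not np.all(np.isfinite(x)):
            bad = np.argwhere(~np.isfinite(x))
            raise SimulationDiverged(
                f"non-finite state at step {step}, oscillator {bad[0][0]}")
        excursions += int(np.any((x < 0) | (x > 1)))
        if step % record_every == 0 or step == n_steps:
            rec_t.append(step * dt)
            rec_x.append(x.copy())
    return TrajectoryBundle(times=np.asarray(rec_t),
                            states=np.asarray(rec_x), kind="diffusion",
                            seed=seed,
                            meta={"dt": dt, "excursions": excursions,
                                  "spec": spec})
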