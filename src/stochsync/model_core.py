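"""Deterministic and stochastic structure of neural population models.

Two model families are supported:

* An ``M``-population Wilson-Cowan network in which the number of active
  neurons ``n_k`` in population ``k`` (out of ``N``) evolves as a one-step
  birth-death process.  Deaths occur at rate ``alpha_k * n_k`` (activity
  decay) and births at rate ``N * F(sum_l w_kl n_l / N + h_k)`` where ``F``
  is a sigmoid gain.  In the thermodynamic limit ``N -> inf`` the fraction
  ``x_k = n_k / N`` obeys the deterministic Wilson-Cowan rate equations.

* A single recurrent excitatory population with short-term synaptic
  depression: the available presynaptic resource ``q`` is depleted at a
  rate proportional to activity and recovers at a constant rate, gating the
  recurrent input.  The stochastic version is a hybrid (piecewise
  deterministic) process: the activity jumps, ``q`` flows.

This module holds the model containers, the gain function, transition
rates, mean-field vector fields, Jacobians, fixed-point location, and
Hopf/fold bifurcation-curve construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "GainParams",
    "NetworkSpec",
    "DepressionSpec",
    "sigmoid_gain",
    "sigmoid_gain_deriv",
    "transition_rates",
    "meanfield_rhs",
    "jacobian",
    "find_fixed_points",
    "hopf_curve_ei",
    "fold_curve_ei",
    "hopf_points_depression",
]


@dataclass(frozen=True)
class GainParams:
    """Sigmoid gain ``F(u) = F0 / (1 + exp(-gamma * u))``.

    ``gamma`` is the dimensionless gain and ``F0`` the maximum firing rate
    in units of the membrane rate constant (time is measured in membrane
    time constants throughout).
    """

    gamma: float = 1.0
    F0: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.F0 <= 0:
            raise ValueError("gain parameters gamma and F0 must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    """An M-population stochastic Wilson-Cowan network.

    Parameters
    ----------
    N : int
        Neurons per population; the intrinsic-noise amplitude is
        ``epsilon = N ** -0.5`` (a derived quantity, see :attr:`epsilon`).
    weights : (M, M) array
        Effective synaptic weights ``w_kl`` from population ``l`` to ``k``.
    drive : (M,) array
        Constant external inputs ``h_k`` (thresholds absorbed).
    decay : (M,) array
        Activity decay rate constants ``alpha_k``.
    gain : GainParams
    chi : (M,) array
        Weights ``chi_k >= 0`` with which the common extrinsic white noise
        enters each population's drive.
    sigma : float
        Strength of the common extrinsic noise (dimensionless).
    """

    N: int
    weights: np.ndarray
    drive: np.ndarray
    decay: np.ndarray
    gain: GainParams = field(default_factory=GainParams)
    chi: np.ndarray | None = None
    sigma: float = 0.0

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.weights, dtype=float))
        M = w.shape[0]
        if w.shape != (M, M):
            raise ValueError("weights must be a square matrix")
        h = np.broadcast_to(np.asarray(self.drive, dtype=float), (M,)).copy()
        a = np.broadcast_to(np.asarray(self.decay, dtype=float), (M,)).copy()
        chi = self.chi
        if chi is None:
            chi = np.full(M, 1.0 / M)
        chi = np.broadcast_to(np.asarray(chi, dtype=float), (M,)).copy()
        if np.any(chi < 0):
            raise ValueError("common-noise weights chi must be nonnegative")
        if int(self.N) < 1:
            raise ValueError("system size N must be a positive integer")
        if self.sigma < 0:
            raise ValueError("extrinsic noise strength sigma must be >= 0")
        if np.any(a <= 0):
            raise ValueError("decay rates alpha must be positive")
        object.__setattr__(self, "N", int(self.N))
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "drive", h)
        object.__setattr__(self, "decay", a)
        object.__setattr__(self, "chi", chi)

    @property
    def M(self) -> int:
        return self.weights.shape[0]

    @property
    def epsilon(self) -> float:
        """Intrinsic-noise amplitude ``N ** -0.5`` (never stored)."""
        return 1.0 / np.sqrt(self.N)

    def replace(self, **kw) -> "NetworkSpec":
        d = dict(
            N=self.N, weights=self.weights, drive=self.drive,
            decay=self.decay, gain=self.gain, chi=self.chi, sigma=self.sigma,
        )
        d.update(kw)
        return NetworkSpec(**d)

    def inputs(self, x: np.ndarray) -> np.ndarray:
        """Summed synaptic input ``u_k = sum_l w_kl x_l + h_k``."""
        return self.weights @ np.asarray(x, dtype=float) + self.drive


@dataclass(frozen=True)
class DepressionSpec:
    """Recurrent excitatory population with synaptic depression.

    The mean field is ``dx/dt = -x + F(w_self * q * x + h)`` and
    ``dq/dt = k_plus * (1 - q) - k_minus * x * q``: the resource ``q`` in
    (0, 1] recovers at rate ``k_plus`` and is depleted at rate
    ``k_minus * x``.  The effective coupling scale is carried by the gain
    ``gamma``; ``w_self`` defaults to 1.
    """

    N: int
    k_plus: float
    k_minus: float
    drive: float
    gain: GainParams = field(default_factory=GainParams)
    w_self: float = 1.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.k_plus <= 0:
            raise ValueError("recovery rate k_plus must be positive")
        if self.k_minus < 0:
            raise ValueError("depletion rate k_minus must be >= 0")
        if int(self.N) < 1:
            raise ValueError("system size N must be a positive integer")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "N", int(self.N))

    @property
    def M(self) -> int:
        return 1

    @property
    def epsilon(self) -> float:
        return 1.0 / np.sqrt(self.N)

    def replace(self, **kw) -> "DepressionSpec":
        d = dict(
            N=self.N, k_plus=self.k_plus, k_minus=self.k_minus,
            drive=self.drive, gain=self.gain, w_self=self.w_self,
            sigma=self.sigma,
        )
        d.update(kw)
        return DepressionSpec(**d)


def sigmoid_gain(u, p: GainParams):
    """``F(u) = F0 / (1 + exp(-gamma u))``; overflow-safe via expit."""
    return p.F0 * expit(p.gamma * np.asarray(u, dtype=float))


def sigmoid_gain_deriv(u, p: GainParams):
    """``F'(u) = gamma * F * (1 - F / F0)``.

    For ``F0 = gamma = 1`` this is the identity ``F' = F (1 - F)``.
    """
    f = expit(p.gamma * np.asarray(u, dtype=float))
    return p.F0 * p.gamma * f * (1.0 - f)


def transition_rates(n, spec: NetworkSpec, rescaled: bool = False):
    """Birth/death rates of the population master equation.

    ``T_k- = alpha_k n_k`` and ``T_k+ = N F(sum_l w_kl n_l / N + h_k)``.
    With ``rescaled=True`` returns the intensities ``Omega_k,± = T_k,± / N``
    in terms of ``x = n / N``.

    The occupation must lie in ``[0, N]^M``; the master-equation boundary
    convention (vanishing probability outside the box) is enforced in the
    simulator by never accepting a jump out of the box.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0) or np.any(n > spec.N):
        raise ValueError("occupation vector outside [0, N]")
    x = n / spec.N
    birth = sigmoid_gain(spec.inputs(x), spec.gain)
    death = spec.decay * x
    if rescaled:
        return birth, death
    return spec.N * birth, spec.N * death


def meanfield_rhs(state, spec):
    """Mean-field vector field (the thermodynamic limit of the jump process).

    For a :class:`NetworkSpec`: ``dx_k/dt = -alpha_k x_k + F(u_k)``,
    identically ``Omega_k,+ - Omega_k,-``.  For a :class:`DepressionSpec`
    the state is ``(x, q)``.
    """
    state = np.asarray(state, dtype=float)
    if isinstance(spec, DepressionSpec):
        x, q = state[..., 0], state[..., 1]
        u = spec.w_self * q * x + spec.drive
        dx = -x + sigmoid_gain(u, spec.gain)
        dq = spec.k_plus * (1.0 - q) - spec.k_minus * x * q
        return np.stack([dx, dq], axis=-1)
    u = state @ spec.weights.T + spec.drive
    return -spec.decay * state + sigmoid_gain(u, spec.gain)


def jacobian(state, spec, method: str = "analytic", h: float = 1e-6):
    """Jacobian of the mean-field vector field at ``state``.

    ``method='analytic'`` uses ``F' = gamma F (1 - F/F0)`` (exact for the
    sigmoid, reducing to ``F' = F(1-F)`` when ``F0 = gamma = 1``);
    ``method='fd'`` uses centered finite differences, kept as a generic
    fallback and cross-check.
    """
    state = np.asarray(state, dtype=float)
    if method == "fd":
        n = state.size
        J = np.empty((n, n))
        for j in range(n):
            dp = state.copy()
            dm = state.copy()
            dp[j] += h
            dm[j] -= h
            J[:, j] = (meanfield_rhs(dp, spec) - meanfield_rhs(dm, spec)) / (2 * h)
        return J
    if isinstance(spec, DepressionSpec):
        x, q = state
        fp = sigmoid_gain_deriv(spec.w_self * q * x + spec.drive, spec.gain)
        w = spec.w_self
        return np.array([
            [-1.0 + fp * w * q, fp * w * x],
            [-spec.k_minus * q, -spec.k_plus - spec.k_minus * x],
        ])
    fp = sigmoid_gain_deriv(spec.inputs(state), spec.gain)
    return -np.diag(spec.decay) + fp[:, None] * spec.weights


def find_fixed_points(spec, n_starts: int = 5, tol: float = 1e-12,
                      merge_tol: float = 1e-8) -> list[np.ndarray]:
    """Locate equilibria by damped Newton iteration from a grid of starts.

    Starts on an ``n_starts``-per-axis grid over the state box; converged
    roots closer than ``merge_tol`` are merged.  The region of interest
    holds 1-3 equilibria.
    """
    if isinstance(spec, DepressionSpec):
        dim = 2
    else:
        dim = spec.M
    axes = [np.linspace(0.05, 0.95, n_starts)] * dim
    roots: list[np.ndarray] = []
    for start in np.stack(np.meshgrid(*axes), axis=-1).reshape(-1, dim):
        x = start.copy()
        ok = False
        for _ in range(200):
            f = meanfield_rhs(x, spec)
            if np.linalg.norm(f) < tol:
                ok = True
                break
            J = jacobian(x, spec)
            try:
                step = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError:
                break
            lam = 1.0
            base = np.linalg.norm(f)
            while lam > 1e-8:
                xn = x + lam * step
                if np.linalg.norm(meanfield_rhs(xn, spec)) < base:
                    break
                lam /= 2.0
            x = x + lam * step
        if not ok:
            continue
        if not any(np.linalg.norm(x - r) < merge_tol for r in roots):
            roots.append(x)
    return sorted(roots, key=lambda r: tuple(r))


def _invert_sigmoid(x, p: GainParams):
    # logit of x / F0, scaled by gamma
    x = np.asarray(x, dtype=float)
    return np.log(x / (p.F0 - x)) / p.gamma


def hopf_curve_ei(spec: NetworkSpec, n_points: int = 400) -> np.ndarray:
    """Hopf bifurcation locus of a 2-population E-I network.

    Works with the closed form available for ``F0 = gamma = 1`` and
    ``alpha = 1``, where ``F' = F(1-F)`` so the Jacobian at a fixed point
    ``(xE*, xI*)`` depends only on ``s_k = x_k (1 - x_k)``:
    ``Tr J = -2 + s_E w_EE + s_I w_II``.  Setting ``Tr J = 0`` (with
    ``Det J > 0``) and sweeping ``x_E*`` gives two branches in ``x_I*``
    (the trace condition is quadratic in ``x_I*``); each fixed point is
    mapped to drive coordinates ``(h_E, h_I)`` by inverting the
    fixed-point equations.

    Returns an array with columns ``(branch_id, xE*, xI*, h_E, h_I)``.
    """
    _require_unit_gain(spec)
    w = spec.weights
    wEE, wEI = w[0, 0], w[0, 1]
    wIE, wII = w[1, 0], w[1, 1]
    rows = []
    xE = np.linspace(1e-4, 1.0 - 1e-4, n_points)
    sE = xE * (1.0 - xE)
    with np.errstate(invalid="ignore"):
        sI = (2.0 - sE * wEE) / wII
    for branch, sign in ((0, -1.0), (1, 1.0)):
        disc = 1.0 - 4.0 * sI
        valid = (sI > 0) & (sI <= 0.25) & (disc >= 0)
        xI = 0.5 * (1.0 + sign * np.sqrt(np.where(valid, disc, np.nan)))
        for xe, se, xi, si, v in zip(xE, sE, xI, sI, valid):
            if not v:
                continue
            det = (-1.0 + se * wEE) * (-1.0 + si * wII) - se * si * wEI * wIE
            if det <= 0:
                continue
            hE = _invert_sigmoid(xe, spec.gain) - wEE * xe - wEI * xi
            hI = _invert_sigmoid(xi, spec.gain) - wIE * xe - wII * xi
            rows.append((branch, xe, xi, hE, hI))
    if not rows:
        warnings.warn("empty Hopf locus for the requested sweep", stacklevel=2)
        return np.empty((0, 5))
    return np.asarray(rows)


def fold_curve_ei(spec: NetworkSpec, n_points: int = 400) -> np.ndarray:
    """Saddle-node (fold) locus, ``Det J = 0`` with ``Tr J < 0``.

    ``Det J`` is linear in ``s_I = x_I (1 - x_I)`` at fixed ``s_E``, so
    ``s_I`` is solved in closed form and each admissible root unfolds into
    two ``x_I*`` branches.  Columns as in :func:`hopf_curve_ei`.
    """
    _require_unit_gain(spec)
    w = spec.weights
    wEE, wEI = w[0, 0], w[0, 1]
    wIE, wII = w[1, 0], w[1, 1]
    rows = []
    xE = np.linspace(1e-4, 1.0 - 1e-4, n_points)
    for xe in xE:
        se = xe * (1.0 - xe)
        a = -1.0 + se * wEE
        denom = a * wII - se * wEI * wIE
        if denom == 0:
            continue
        si = a / denom
        if not (0 < si <= 0.25):
            continue
        if a + (-1.0 + si * wII) >= 0:  # Tr J < 0 required
            continue
        disc = np.sqrt(1.0 - 4.0 * si)
        for branch, xi in ((0, 0.5 * (1 - disc)), (1, 0.5 * (1 + disc))):
            hE = _invert_sigmoid(xe, spec.gain) - wEE * xe - wEI * xi
            hI = _invert_sigmoid(xi, spec.gain) - wIE * xe - wII * xi
            rows.append((branch, xe, xi, hE, hI))
    if not rows:
        warnings.warn("empty fold locus for the requested sweep", stacklevel=2)
        return np.empty((0, 5))
    return np.asarray(rows)


def _require_unit_gain(spec: NetworkSpec) -> None:
    g = spec.gain
    if not (g.F0 == 1.0 and g.gamma == 1.0):
        raise ValueError("closed-form E-I bifurcation curves require F0 = gamma = 1")
    if spec.M != 2:
        raise ValueError("E-I bifurcation curves require M = 2")


def _depression_fixed_point(spec: DepressionSpec) -> np.ndarray:
    """Unique fixed point: ``q* = k+/(k+ + k- x*)`` with ``x*`` from the
    scalar self-consistency equation."""
    from scipy.optimize import brentq

    def resid(x):
        q = spec.k_plus / (spec.k_plus + spec.k_minus * x)
        return -x + sigmoid_gain(spec.w_self * q * x + spec.drive, spec.gain)

    x = brentq(resid, 1e-12, 1.0 - 1e-12, xtol=1e-14)
    q = spec.k_plus / (spec.k_plus + spec.k_minus * x)
    return np.array([x, q])


def hopf_points_depression(spec: DepressionSpec, k_minus_range=(1e-3, 1.0),
                           n_scan: int = 400) -> np.ndarray:
    """Hopf points along the depletion-rate axis ``k_minus``.

    Scans the fixed-point branch, records the leading eigenvalue, and
    brackets sign changes of its real part by bisection.  Returns an array
    with columns ``(k_minus, x*, q*, re_lambda, im_lambda)`` — one row per
    Hopf point.
    """
    ks = np.linspace(k_minus_range[0], k_minus_range[1], n_scan)

    def lead_re(k):
        s = spec.replace(k_minus=k)
        fp = _depression_fixed_point(s)
        lam = np.linalg.eigvals(jacobian(fp, s))
        return lam[np.argmax(lam.real)].real

    res = np.array([lead_re(k) for k in ks])
    rows = []
    for i in np.flatnonzero(np.sign(res[:-1]) != np.sign(res[1:])):
        lo, hi = ks[i], ks[i + 1]
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if np.sign(lead_re(mid)) == np.sign(lead_re(lo)):
                lo = mid
            else:
                hi = mid
        k = 0.5 * (lo + hi)
        s = spec.replace(k_minus=k)
        fp = _depression_fixed_point(s)
        lam = np.linalg.eigvals(jacobian(fp, s))
        lead = lam[np.argmax(lam.real)]
        rows.append((k, fp[0], fp[1], lead.real, abs(lead.imag)))
    if not rows:
        warnings.warn("no Hopf point in the scanned k_minus range", stacklevel=2)
        return np.empty((0, 5))
    return np.asarray(rows)
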