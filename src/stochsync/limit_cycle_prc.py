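"""Limit-cycle location, phase parameterization, and phase-resetting curves.

A stable limit cycle ``x*(t)`` of period ``T`` is parameterized by a phase
``theta in [-pi, pi)`` advancing uniformly in time, ``theta = omega t`` with
``omega = 2 pi / T``, with the origin ``theta = 0`` placed at the global
maximum of the first activity coordinate along the cycle (downstream
phase-difference statistics are invariant to this convention).

The infinitesimal phase-resetting curve (PRC) ``Z(theta)`` — the gradient of
asymptotic phase along the cycle — is the unique 2pi-periodic solution of
the adjoint equation ``dZ/dt = -J(x*(t))^T Z`` normalized by
``Z(theta) . dx*/dt(theta) = omega``.  It is computed by integrating the
adjoint equation backwards in time (all non-trivial Floquet exponents of
the adjoint flow are positive, so backward integration converges onto the
periodic solution), renormalizing each period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import jacobian, meanfield_rhs

__all__ = ["LimitCycle", "PRC", "FourierInterpolant", "find_limit_cycle",
           "compute_prc"]


class FourierInterpolant:
    """Trigonometric interpolation of 2pi-periodic tabulations.

    Built from samples on the uniform grid ``theta_j = -pi + 2 pi j / n``;
    evaluation sums the trigonometric polynomial, which is spectrally
    accurate for smooth data and exactly periodic.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        self._n = values.shape[0]
        # grid starts at -pi: multiply coefficients by the phase shift
        self._coef = np.fft.rfft(values, axis=0) / self._n
        k = np.arange(self._coef.shape[0])
        shift = np.exp(1j * k * np.pi)
        self._coef = self._coef * shift.reshape((-1,) + (1,) * (values.ndim - 1))
        if self._n % 2 == 0:  # Nyquist mode: real cosine only
            self._coef[-1] = self._coef[-1].real

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        k = np.arange(self._coef.shape[0])
        ph = np.exp(1j * np.multiply.outer(theta, k))
        w = np.full(self._coef.shape[0], 2.0)
        w[0] = 1.0
        if self._n % 2 == 0:
            w[-1] = 1.0
        vals = (ph * w) @ self._coef.reshape(self._coef.shape[0], -1)
        out = vals.real.reshape(theta.shape + self._coef.shape[1:])
        return out

    def derivative(self) -> "FourierInterpolant":
        """Spectral differentiation: a new interpolant of d/dtheta."""
        out = object.__new__(FourierInterpolant)
        out._n = self._n
        k = np.arange(self._coef.shape[0]).reshape(
            (-1,) + (1,) * (self._coef.ndim - 1))
        out._coef = self._coef * (1j * k)
        if self._n % 2 == 0:
            out._coef[-1] = 0.0  # derivative of the real Nyquist cosine mode
        return out


@dataclass(frozen=True)
class LimitCycle:
    """Tabulated periodic orbit on a uniform phase grid over [-pi, pi)."""

    period: float
    grid: np.ndarray        # (n_grid,) phases in [-pi, pi)
    orbit: np.ndarray       # (n_grid, dim) states x*(theta_j)

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period

    @property
    def n_grid(self) -> int:
        return self.grid.size

    def interpolant(self) -> FourierInterpolant:
        return FourierInterpolant(self.orbit)


@dataclass(frozen=True)
class PRC:
    """Phase-resetting curve components on the limit cycle's phase grid."""

    grid: np.ndarray        # (n_grid,)
    Z: np.ndarray           # (n_grid, dim)

    def interpolant(self) -> FourierInterpolant:
        return FourierInterpolant(self.Z)


class NoLimitCycleError(RuntimeError):
    pass


class FixedPointConvergenceError(NoLimitCycleError):
    """The trajectory converged to a fixed point instead of a cycle."""


def _integrate(spec, x0, t_span, **kw):
    return solve_ivp(lambda t, x: meanfield_rhs(x, spec), t_span, x0,
                     rtol=1e-11, atol=1e-13, dense_output=True,
                     method="LSODA", **kw)


def find_limit_cycle(spec, x0=None, n_grid: int = 1024, tol: float = 1e-9,
                     transient: float | None = None,
                     max_horizon: float = 20000.0) -> LimitCycle:
    """Locate the stable limit cycle of the mean-field flow.

    Integrates past transients, detects the cycle from upward crossings of
    the first coordinate through its long-run mean (a Poincare section),
    refines the period from successive section returns, and tabulates the
    orbit at ``n_grid`` phases uniform in time with ``theta = 0`` at the
    maximum of the first coordinate.

    Raises :class:`FixedPointConvergenceError` if the trajectory settles to
    an equilibrium and :class:`NoLimitCycleError` if no periodic return is
    detected within ``max_horizon``.
    """
    from .model_core import DepressionSpec

    if x0 is None:
        x0 = [0.5, 0.25] if isinstance(spec, DepressionSpec) else \
            np.full(spec.M, 0.25)
    x0 = np.asarray(x0, dtype=float)

    # crude horizon scaling: the depression cycle is slow
    probe_T = 400.0 if isinstance(spec, DepressionSpec) else 60.0
    if transient is None:
        transient = 10 * probe_T
    transient = min(transient, max_horizon / 2)

    sol = _integrate(spec, x0, (0.0, transient))
    x1 = sol.y[:, -1]
    if np.linalg.norm(meanfield_rhs(x1, spec)) < 1e-10:
        raise FixedPointConvergenceError(
            "trajectory converged to a fixed point; no limit cycle")

    # sample one probe window to get the section level and period estimate
    sol = _integrate(spec, x1, (0.0, probe_T))
    ts = np.linspace(0.2 * probe_T, probe_T, 4000)
    xs = sol.sol(ts)[0]
    level = 0.5 * (xs.min() + xs.max())
    if xs.max() - xs.min() < 1e-8:
        raise FixedPointConvergenceError(
            "first coordinate is constant; trajectory is at equilibrium")

    def section(t, x):
        return x[0] - level
    section.direction = 1.0

    # integrate with event detection; use the last few upward crossings
    sol = _integrate(spec, sol.y[:, -1], (0.0, min(probe_T * 12, max_horizon)),
                     events=section)
    ev = sol.t_events[0]
    if len(ev) < 4:
        raise NoLimitCycleError("no periodic return detected on the section")
    periods = np.diff(ev[-4:])
    T = float(periods.mean())
    if np.ptp(periods) > max(tol * 100, 1e-6) * T:
        # not yet converged onto the cycle — extend
        sol = _integrate(spec, sol.y[:, -1], (0.0, 40 * T), events=section)
        ev = sol.t_events[0]
        T = float(np.diff(ev[-4:]).mean())

    # land exactly on the section and tabulate one clean period
    xsec = sol.sol(ev[-1])
    orbit_sol = _integrate(spec, xsec, (0.0, 2.0 * T))

    # closure check
    gap = np.linalg.norm(orbit_sol.sol(T) - xsec)
    if gap > 1e-6:
        raise NoLimitCycleError(
            f"orbit fails to close: |x(T) - x(0)| = {gap:.2e}")

    # theta = 0 at the maximum of the first coordinate
    tt = np.linspace(0.0, T, 8192, endpoint=False)
    imax = int(np.argmax(orbit_sol.sol(tt)[0]))
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda t: -orbit_sol.sol(t % (2 * T))[0],
                          bracket=(tt[imax] - T / 100, tt[imax],
                                   tt[imax] + T / 100))
    t0 = float(res.x) % T

    grid = -np.pi + 2.0 * np.pi * np.arange(n_grid) / n_grid
    times = (t0 + grid * T / (2.0 * np.pi)) % T
    orbit = orbit_sol.sol(times).T

    f = np.array([meanfield_rhs(x, spec) for x in orbit])
    if np.min(np.linalg.norm(f, axis=1)) == 0.0:
        raise NoLimitCycleError("vector field vanishes on the orbit")
    return LimitCycle(period=T, grid=grid, orbit=orbit)


def compute_prc(lc: LimitCycle, spec, tol: float = 1e-10,
                max_periods: int = 100) -> PRC:
    """PRC by backward integration of the adjoint equation.

    Integrates ``dZ/dt = -J(x*(t))^T Z`` backwards over whole periods,
    renormalizing to ``Z . f = omega`` after each period, until the
    per-period sup-norm change falls below ``tol``; then samples the
    converged periodic solution on the phase grid and enforces the
    normalization identity pointwise.
    """
    T, omega = lc.period, lc.omega
    interp = lc.interpolant()

    def orbit_at(t):
        # theta(t) = omega * t with theta=0 at grid time 0
        return interp(omega * t)

    def adjoint_back(s, z):
        # s = -t: dZ/ds = J(x*(-s))^T Z
        J = jacobian(orbit_at(-s), spec)
        return J.T @ z

    f0 = meanfield_rhs(lc.orbit[lc.n_grid // 2], spec)  # state at theta=0
    z = f0 / np.dot(f0, f0) * omega
    prev = None
    for it in range(max_periods):
        sol = solve_ivp(adjoint_back, (it * T, (it + 1) * T), z,
                        rtol=1e-11, atol=1e-13, method="LSODA",
                        dense_output=(prev is not None))
        z = sol.y[:, -1]
        fz = meanfield_rhs(orbit_at(-(it + 1) * T), spec)
        z = z * (omega / np.dot(z, fz))
        if prev is not None and np.max(np.abs(z - prev)) < tol:
            break
        prev = z.copy()
    else:
        raise RuntimeError(
            "adjoint iteration did not converge: slow Floquet decay "
            f"(last change {np.max(np.abs(z - prev)):.2e} after "
            f"{max_periods} periods)")

    # one more clean backward period with dense output to sample the grid
    sol = solve_ivp(adjoint_back, (0.0, T), z, rtol=1e-11, atol=1e-13,
                    method="LSODA", dense_output=True)
    # Z(theta) lives at forward time t = theta/omega = -s
    thetas = lc.grid
    s_vals = (-thetas / omega) % T
    Z = sol.sol(s_vals).T
    # pointwise renormalization (the identity is conserved by the exact
    # adjoint flow; this removes residual integrator drift)
    f = np.array([meanfield_rhs(x, spec) for x in lc.orbit])
    scale = omega / np.einsum("ij,ij->i", Z, f)
    Z = Z * scale[:, None]
    return PRC(grid=lc.grid, Z=Z)
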