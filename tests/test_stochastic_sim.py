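import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.linalg import solve_continuous_lyapunov

from stochsync import (DepressionSpec, GainParams, NetworkSpec,
                       euler_maruyama, find_fixed_points, jacobian,
                       langevin_ensemble, meanfield_rhs, pdmp_run, ssa_run)
from stochsync.stochastic_sim import langevin_drift_diffusion


def pure_death_spec(N=100):
    # drive -> -inf suppresses births entirely (F(-40) ~ 4e-18)
    return NetworkSpec(N=N, weights=[[0.0]], drive=[-40.0], decay=[1.0])


class TestSSA:
    def test_pure_death_process_mean(self):
        """With births suppressed, n(t) is a linear death process whose
        mean decays as n0 * exp(-t)."""
        spec = pure_death_spec()
        n0, runs = 20, 2000
        t_eval = np.array([0.5, 1.0, 2.0])
        samples = np.array([ssa_run(spec, [n0], 3.0, seed=s,
                                    t_eval=t_eval).states[:, 0]
                            for s in range(runs)])
        mean = samples.mean(axis=0)
        expected = n0 * np.exp(-t_eval)
        # binomial thinning: var = n0 e^-t (1 - e^-t)
        se = np.sqrt(expected * (1 - np.exp(-t_eval)) / runs)
        assert np.all(np.abs(mean - expected) < 3 * se)

    def test_occupations_stay_in_bounds(self, ei_spec):
        spec = ei_spec.replace(N=30)
        for seed in range(100):
            b = ssa_run(spec, [15, 15], 5.0, seed=seed,
                        t_eval=np.linspace(0, 5, 40))
            assert np.all(b.states >= 0) and np.all(b.states <= 30)

    def test_ensemble_mean_tracks_mean_field(self, ei_spec):
        """At N = 1e4 the ensemble-average SSA path follows the
        deterministic limit cycle to O(N^-1/2)."""
        spec = ei_spec.replace(N=10_000)
        x0 = np.array([0.5, 0.5])
        horizon = 4.0
        t_eval = np.linspace(0, horizon, 30)
        runs = 200
        acc = np.zeros((t_eval.size, 2))
        for seed in range(runs):
            acc += ssa_run(spec, (x0 * spec.N).astype(int), horizon,
                           seed=seed, t_eval=t_eval).states
        mean_x = acc / (runs * spec.N)
        sol = solve_ivp(lambda t, x: meanfield_rhs(x, spec), (0, horizon),
                        x0, t_eval=t_eval, rtol=1e-10, atol=1e-12)
        dev = np.max(np.abs(mean_x - sol.y.T))
        assert dev < 5 / np.sqrt(spec.N)

    def test_reproducible_with_seed(self, ei_spec):
        spec = ei_spec.replace(N=100)
        a = ssa_run(spec, [50, 50], 5.0, seed=42)
        b = ssa_run(spec, [50, 50], 5.0, seed=42)
        np.testing.assert_array_equal(a.states, b.states)

    def test_suppressed_births_keep_state_empty(self):
        spec = pure_death_spec(N=10)
        b = ssa_run(spec, [0], 1e6, seed=0)
        # no deaths possible and birth rate ~ 1e-17: jump times astronomical
        assert np.all(b.states == 0)


class TestPDMP:
    def test_resource_recovery_closed_form(self):
        """With depletion off and activity pinned at zero, q relaxes to 1
        as 1 - (1-q0) exp(-k+ t)."""
        spec = DepressionSpec(N=50, k_plus=0.1, k_minus=0.0, drive=-40.0,
                              gain=GainParams(1.0, 1.0))
        q0 = 0.3
        t_eval = np.linspace(0, 30, 10)
        b = pdmp_run(spec, 0, q0, 30.0, seed=1, t_eval=t_eval)
        expected = 1 - (1 - q0) * np.exp(-spec.k_plus * t_eval)
        np.testing.assert_allclose(b.states[:, 1], expected, atol=1e-10)

    def test_thinning_matches_direct_ssa_with_frozen_resource(self):
        """With q frozen the hybrid process is an ordinary birth-death
        process; its marginal moments must match the direct SSA for the
        equivalent one-population network."""
        q0 = 0.6
        dep = DepressionSpec(N=200, k_plus=1e-12, k_minus=0.0, drive=-0.1,
                             gain=GainParams(2.0, 1.0), w_self=1.5)
        # equivalent static network: F(w_self*q0*x + h)
        net = NetworkSpec(N=200, weights=[[1.5 * q0]], drive=[-0.1],
                          decay=[1.0], gain=GainParams(2.0, 1.0))
        t_eval = np.array([2.0])
        xs_p = np.array([pdmp_run(dep, 100, q0, 2.0, seed=s,
                                  t_eval=t_eval).states[0, 0]
                         for s in range(400)])
        xs_s = np.array([ssa_run(net, [100], 2.0, seed=10_000 + s,
                                 t_eval=t_eval).states[0, 0] / net.N
                         for s in range(400)])
        # z-test on means, F-ish bound on variances
        se = np.sqrt(xs_p.var() / 400 + xs_s.var() / 400)
        assert abs(xs_p.mean() - xs_s.mean()) < 3 * se
        assert 0.6 < xs_p.var() / xs_s.var() < 1.6

    def test_ensemble_mean_tracks_mean_field(self, dep_spec):
        """Ensemble-averaged hybrid paths follow the deterministic
        oscillation at O(N^-1/2); near the steep relaxation fronts phase
        dephasing concentrates the deviation, so the front is gauged by
        the time-RMS rather than the pointwise maximum."""
        spec = dep_spec.replace(N=10_000)
        x0, q0 = 0.5, 0.4
        horizon = 90.0  # about two periods
        t_eval = np.linspace(0, horizon, 40)
        runs = 60
        acc = np.zeros((t_eval.size, 2))
        for seed in range(runs):
            acc += pdmp_run(spec, int(x0 * spec.N), q0, horizon, seed=seed,
                            t_eval=t_eval).states
        mean = acc / runs
        sol = solve_ivp(lambda t, s: meanfield_rhs(s, spec), (0, horizon),
                        [x0, q0], t_eval=t_eval, rtol=1e-10, atol=1e-12)
        dev = np.abs(mean - sol.y.T)
        assert np.sqrt((dev ** 2).mean()) < 2 / np.sqrt(spec.N)
        # away from the fronts the pointwise deviation is also O(eps)
        one_period = t_eval < 40.0
        assert dev[one_period].max() < 5 / np.sqrt(spec.N)

    def test_domain_errors(self, dep_spec):
        with pytest.raises(ValueError):
            pdmp_run(dep_spec, 10, 0.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            pdmp_run(dep_spec, -1, 0.5, 1.0, seed=0)

    def test_reproducible_with_seed(self, dep_spec):
        spec = dep_spec.replace(N=100)
        a = pdmp_run(spec, 50, 0.5, 50.0, seed=3)
        b = pdmp_run(spec, 50, 0.5, 50.0, seed=3)
        np.testing.assert_array_equal(a.states, b.states)


class TestEulerMaruyama:
    def test_zero_diffusion_reduces_to_explicit_euler(self, ei_spec):
        x0 = np.array([[0.3, 0.4]])
        sol = solve_ivp(lambda t, x: meanfield_rhs(x, ei_spec), (0, 5.0),
                        x0[0], rtol=1e-10, atol=1e-12)
        errs = []
        for dt in (1e-2, 5e-3):
            b = euler_maruyama(lambda x: meanfield_rhs(x, ei_spec), x0,
                               5.0, dt, seed=0)
            errs.append(np.max(np.abs(b.states[-1, 0] - sol.y[:, -1])))
        assert errs[0] < 0.05
        # halving dt roughly halves the error (first-order method)
        assert errs[1] < 0.75 * errs[0]

    def test_ou_stationary_variance(self):
        """dX = -X dt + c dW has stationary variance c^2 / 2."""
        c = 0.7
        n = 2000
        b = euler_maruyama(lambda x: -x, np.zeros((n, 1)), 10.0, 1e-3,
                           seed=5, indep_amp=lambda x: np.full_like(x, c),
                           record_every=10_000)
        v = b.states[-1, :, 0].var()
        se = np.sqrt(2.0 / (n - 1)) * (c ** 2 / 2)
        assert abs(v - c ** 2 / 2) < 3 * se

    def test_common_noise_keeps_identical_oscillators_identical(self,
                                                                ei_spec):
        spec = ei_spec.replace(sigma=0.1)

        def common(x):
            _, _, a = langevin_drift_diffusion(x, spec)
            return spec.sigma * a

        x0 = np.tile([0.5, 0.6], (8, 1))
        b = euler_maruyama(lambda x: meanfield_rhs(x, spec), x0, 2.0, 1e-3,
                           seed=9, common_amp=common, record_every=100)
        spread = np.ptp(b.states, axis=1)
        assert np.max(spread) == 0.0

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            euler_maruyama(lambda x: -x, np.zeros((2, 1)), 1.0, 0.0, seed=0)


class TestLangevinEnsemble:
    def test_reproducible_with_seed(self, ei_spec):
        x0 = np.full((4, 2), 0.5)
        a = langevin_ensemble(ei_spec, x0, 1.0, 1e-3, seed=11)
        b = langevin_ensemble(ei_spec, x0, 1.0, 1e-3, seed=11)
        np.testing.assert_array_equal(a.states, b.states)

    def test_intrinsic_diffusion_dominates_drift_bound(self, ei_spec, rng):
        # b_k^2 = sum of intensities, A_k = difference: |A_k| <= b_k^2
        for _ in range(20):
            x = rng.uniform(0.05, 0.95, 2)
            A, b, _ = langevin_drift_diffusion(x, ei_spec)
            assert np.all(b ** 2 >= np.abs(A) - 1e-12)

    def test_single_population_amplitudes(self):
        # M=1, w=0, I=0, F0=gamma=1: A = 1/2 - x, b = sqrt(x + 1/2)
        spec = NetworkSpec(N=100, weights=[[0.0]], drive=[0.0], decay=[1.0])
        A, b, _ = langevin_drift_diffusion(np.array([0.5]), spec)
        assert A[0] == pytest.approx(0.0)
        assert b[0] == pytest.approx(1.0)

    def test_stationary_covariance_matches_lyapunov_equation(self, ei_spec):
        """Linear-noise check at a stable focus: the stationary covariance
        of the Langevin fluctuations solves J C + C J^T + eps^2 D = 0."""
        spec = ei_spec.replace(N=10_000, sigma=0.0, drive=[0.0, -6.0])
        (fp,) = find_fixed_points(spec)
        J = jacobian(fp, spec)
        assert np.max(np.linalg.eigvals(J).real) < 0  # genuinely stable
        _, b, _ = langevin_drift_diffusion(fp, spec)
        D = spec.epsilon ** 2 * np.diag(b ** 2)
        C_theory = solve_continuous_lyapunov(J, -D)
        n = 4000
        x0 = np.tile(fp, (n, 1))
        bundle = langevin_ensemble(spec, x0, 8.0, 2e-3, seed=13,
                                   record_every=1000)
        dev = bundle.states[-1] - fp
        C_emp = np.cov(dev.T)
        assert np.linalg.norm(C_emp - C_theory) < 0.10 * np.linalg.norm(
            C_theory)

    def test_ssa_and_langevin_marginals_agree(self, ei_spec):
        """One-time mean/variance of x_E at t = T/2 agree between the jump
        process and its diffusion approximation at N = 1e4."""
        spec = ei_spec.replace(N=10_000, sigma=0.0)
        x0 = np.array([0.5, 0.5])
        t_end = 2.15
        runs = 200
        xs_s = np.array([ssa_run(spec, (x0 * spec.N).astype(int), t_end,
                                 seed=s, t_eval=np.array([t_end])
                                 ).states[0, 0] / spec.N
                         for s in range(runs)])
        bundle = langevin_ensemble(spec, np.tile(x0, (runs, 1)), t_end,
                                   1e-3, seed=77, record_every=10 ** 6)
        xl = bundle.states[-1, :, 0]
        se = np.sqrt(xs_s.var() / runs + xl.var() / runs)
        assert abs(xs_s.mean() - xl.mean()) < 3 * se
        assert 0.5 < xs_s.var() / xl.var() < 2.0

    def test_stratonovich_correction_consistency(self, ei_spec):
        """The generic finite-difference Stratonovich conversion inside
        euler_maruyama and the analytic conversion inside langevin_ensemble
        must produce the same paths for the same noise stream."""
        spec = ei_spec.replace(N=10 ** 12, sigma=0.3)  # eps ~ 0: common only

        def common(x):
            _, _, a = langevin_drift_diffusion(x, spec)
            return spec.sigma * a

        def indep(x):
            _, b, _ = langevin_drift_diffusion(x, spec)
            return spec.epsilon * b

        x0 = np.tile([0.5, 0.6], (4, 1))
        a = euler_maruyama(lambda x: meanfield_rhs(x, spec), x0, 2.0, 1e-3,
                           seed=21, indep_amp=indep, common_amp=common,
                           record_every=200)
        b = langevin_ensemble(spec, x0, 2.0, 1e-3, seed=21,
                              record_every=200)
        np.testing.assert_allclose(a.states, b.states, atol=1e-7)
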