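import numpy as np
import pytest

from ratemoments import (
    ClosureConfig,
    FICurveParams,
    MomentState,
    NetworkSpec,
    activity_to_firing,
    closure_rhs,
    e1,
    integrate_closure,
    mf,
    pair_count,
    pair_indices,
    sample_network,
    solve_steady_state,
)
from ratemoments.moments import ClosureBreakdownError, firing_statistics
from ratemoments.network import eval_input
from ratemoments.trajectory import StatTrajectory

# ---------------------------------------------------------------------------
# Independent literal transcription of the closure right-hand side, assembled
# cell-by-cell with scalar expectation calls.  This is the oracle against
# which the vectorized production path is checked.
# ---------------------------------------------------------------------------


def literal_mean_rhs(spec, mu, sigma, mu_bg, j):
    acc = sum(
        spec.coupling[j, k] * e1(spec.fi[k], mu[k], sigma[k]) for k in range(spec.n_cells)
    )
    return (-mu[j] + mu_bg[j] + acc) / spec.tau[j]


def _mf_lit(spec, j, k, mu, sigma):
    c = 1.0 if j == k else spec.corr[j, k]
    return mf(j, k, c, spec.fi[k], mu[k], sigma[k])


def literal_diag_rhs(spec, mu, sigma, e_mat, mu_bg, sig_bg, j):
    acc = sum(
        spec.coupling[j, k]
        * (mu[j] * e1(spec.fi[k], mu[k], sigma[k]) + sigma[j] * _mf_lit(spec, j, k, mu, sigma))
        for k in range(spec.n_cells)
    )
    return (
        sig_bg[j] ** 2 / spec.tau[j] + 2.0 * (-e_mat[j, j] + mu_bg[j] * mu[j] + acc)
    ) / spec.tau[j]


def literal_offdiag_rhs(spec, mu, sigma, e_mat, mu_bg, sig_bg, j, k):
    t1 = -e_mat[j, k] + mu_bg[j] * mu[k] + sum(
        spec.coupling[j, l]
        * (mu[k] * e1(spec.fi[l], mu[l], sigma[l]) + sigma[k] * _mf_lit(spec, k, l, mu, sigma))
        for l in range(spec.n_cells)
    )
    t2 = -e_mat[j, k] + mu_bg[k] * mu[j] + sum(
        spec.coupling[k, l]
        * (mu[j] * e1(spec.fi[l], mu[l], sigma[l]) + sigma[j] * _mf_lit(spec, j, l, mu, sigma))
        for l in range(spec.n_cells)
    )
    return (
        spec.corr[j, k] * sig_bg[j] * sig_bg[k] + spec.tau[k] * t1 + spec.tau[j] * t2
    ) / (spec.tau[j] * spec.tau[k])


def random_state(spec, rng):
    n = spec.n_cells
    mu = rng.normal(0, 0.5, n)
    a = rng.normal(0, 0.4, (n, n))
    cov = a @ a.T + np.diag(rng.uniform(0.1, 1.0, n))
    return MomentState.from_stats(mu, cov)


class TestMomentState:
    def test_dimension_bookkeeping(self):
        state = MomentState(mu=np.zeros(50), second_moments=np.eye(50))
        assert state.dim == 50 + 50 * 51 // 2 == 1325
        assert pair_count(50) == 1225

    def test_flatten_roundtrip(self, rng):
        spec = sample_network(4, 1.0, seed=0)
        state = random_state(spec, rng)
        rebuilt = MomentState.from_flat(4, state.flatten())
        np.testing.assert_allclose(rebuilt.mu, state.mu, atol=1e-15)
        np.testing.assert_allclose(
            rebuilt.second_moments, state.second_moments, atol=1e-15
        )

    def test_cov_symmetry(self, rng):
        spec = sample_network(3, 1.0, seed=1)
        state = random_state(spec, rng)
        np.testing.assert_allclose(state.cov, state.cov.T, atol=1e-12)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            MomentState(mu=np.zeros(2), second_moments=[[1.0, 0.2], [0.1, 1.0]])


class TestClosureRHS:
    def test_matches_literal_transcription(self, weak_triplet, rng):
        spec = weak_triplet
        state = random_state(spec, rng)
        deriv = closure_rhs(state, 0.0, spec)
        mu, sigma = state.mu, np.sqrt(state.variances)
        mu_bg, sig_bg = eval_input(spec, 0.0)
        for j in range(3):
            assert deriv.mu[j] == pytest.approx(
                literal_mean_rhs(spec, mu, sigma, mu_bg, j), abs=1e-8
            )
            assert deriv.second_moments[j, j] == pytest.approx(
                literal_diag_rhs(spec, mu, sigma, state.second_moments, mu_bg, sig_bg, j),
                abs=1e-8,
            )
        for j in range(3):
            for k in range(j + 1, 3):
                assert deriv.second_moments[j, k] == pytest.approx(
                    literal_offdiag_rhs(
                        spec, mu, sigma, state.second_moments, mu_bg, sig_bg, j, k
                    ),
                    abs=1e-8,
                )

    def test_diagonal_recovers_variance_equation(self, rng):
        # the j = k instance of the pair formula equals the dedicated
        # variance formula on random states and networks
        for trial in range(100):
            spec = sample_network(3, 1.0, seed=1000 + trial)
            state = random_state(spec, rng)
            mu, sigma = state.mu, np.sqrt(state.variances)
            mu_bg, sig_bg = eval_input(spec, 0.0)
            for j in range(3):
                lhs = literal_offdiag_rhs(
                    spec, mu, sigma, state.second_moments, mu_bg, sig_bg, j, j
                )
                rhs = literal_diag_rhs(
                    spec, mu, sigma, state.second_moments, mu_bg, sig_bg, j
                )
                assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_uncoupled_fixed_point(self, uncoupled_pair):
        spec = uncoupled_pair
        cov = spec.corr * np.outer(spec.sigma_bg, spec.sigma_bg) / (
            spec.tau[:, None] + spec.tau[None, :]
        )
        state = MomentState.from_stats(spec.mu_bg, cov)
        deriv = closure_rhs(state, 0.0, spec)
        np.testing.assert_allclose(deriv.mu, 0.0, atol=1e-12)
        np.testing.assert_allclose(deriv.second_moments, 0.0, atol=1e-12)

    def test_nonfinite_state_names_index(self, weak_triplet):
        state = MomentState(mu=np.array([0.0, np.nan, 0.0]), second_moments=np.eye(3))
        with pytest.raises(ValueError, match=r"\[1\]"):
            closure_rhs(state, 0.0, weak_triplet)

    def test_breakdown_on_bad_variance(self, weak_triplet):
        e_mat = np.eye(3) * 0.5
        state = MomentState(mu=np.array([2.0, 0.0, 0.0]), second_moments=e_mat)
        with pytest.raises(ClosureBreakdownError):
            closure_rhs(state, 0.0, weak_triplet)


class TestIntegrateClosure:
    def test_uncoupled_mean_transient(self, single_cell):
        # linear ODE: mu(t) = 0.8 * (1 - exp(-t)) from mu(0) = 0
        times = np.linspace(0, 6, 61)
        init = MomentState(mu=np.array([0.0]), second_moments=np.array([[0.5]]))
        traj = integrate_closure(single_cell, times, init=init)
        expected = 0.8 * (1.0 - np.exp(-times))
        np.testing.assert_allclose(traj.mean_activity[:, 0], expected, atol=1e-6)
        # variance starts and stays at its stationary value
        np.testing.assert_allclose(traj.var_activity[:, 0], 0.5, atol=1e-6)

    def test_steady_init_is_constant(self, uncoupled_pair):
        times = np.linspace(0, 8, 33)
        traj = integrate_closure(uncoupled_pair, times)
        for fam in ("mean_activity", "var_activity", "cov_activity", "mean_firing"):
            arr = traj.family(fam)
            np.testing.assert_allclose(arr - arr[0], 0.0, atol=1e-7)

    def test_uncoupled_second_moment_transients(self):
        # OU closed form: var_j(t) = var_inf + (var_0 - var_inf) e^{-2t/tau_j},
        # cov(t) = cov_inf + (cov_0 - cov_inf) e^{-(1/tau_j + 1/tau_k) t}
        spec = NetworkSpec(
            n_cells=2,
            tau=[1.0, 2.0],
            mu_bg=[0.0, 0.0],
            sigma_bg=[1.0, 1.0],
            corr=[[1.0, 0.5], [0.5, 1.0]],
            coupling=np.zeros((2, 2)),
            fi=(FICurveParams(0.0, 0.2), FICurveParams(0.0, 0.2)),
        )
        var0 = np.array([0.2, 0.9])
        cov0 = 0.05
        init = MomentState.from_stats(
            np.zeros(2), np.array([[var0[0], cov0], [cov0, var0[1]]])
        )
        times = np.linspace(0, 10, 101)
        traj = integrate_closure(spec, times, init=init)
        var_inf = spec.sigma_bg**2 / (2 * spec.tau)
        for j in range(2):
            expected = var_inf[j] + (var0[j] - var_inf[j]) * np.exp(
                -2 * times / spec.tau[j]
            )
            np.testing.assert_allclose(traj.var_activity[:, j], expected, atol=1e-6)
        cov_inf = 0.5 * 1.0 * 1.0 / (1.0 + 2.0)
        rate = 1.0 / 1.0 + 1.0 / 2.0
        expected_cov = cov_inf + (cov0 - cov_inf) * np.exp(-rate * times)
        np.testing.assert_allclose(traj.cov_activity[:, 0], expected_cov, atol=1e-6)

    def test_uncoupled_pair_cov_quarter(self):
        # tau = tau' = 1, sigma_bg = 1, c = 0.5 -> long-time covariance 0.25
        spec = NetworkSpec(
            n_cells=2,
            tau=[1.0, 1.0],
            mu_bg=[0.1, -0.1],
            sigma_bg=[1.0, 1.0],
            corr=[[1.0, 0.5], [0.5, 1.0]],
            coupling=np.zeros((2, 2)),
            fi=(FICurveParams(0.0, 0.2), FICurveParams(0.0, 0.2)),
        )
        init = MomentState.from_stats(spec.mu_bg, np.diag([0.5, 0.5]))
        traj = integrate_closure(spec, np.linspace(0, 20, 41), init=init)
        assert traj.cov_activity[-1, 0] == pytest.approx(0.25, abs=1e-7)

    def test_longtime_matches_steady_state(self, weak_triplet):
        spec = weak_triplet
        t_end = 50 * spec.tau.max()
        traj = integrate_closure(spec, np.linspace(0, t_end, 51))
        ss = solve_steady_state(spec)
        np.testing.assert_allclose(traj.mean_activity[-1], ss.mu, atol=1e-6)
        np.testing.assert_allclose(traj.var_activity[-1], ss.sigma**2, atol=1e-6)
        jj, kk = pair_indices(3)
        np.testing.assert_allclose(traj.cov_activity[-1], ss.cov[jj, kk], atol=1e-6)

    def test_correlation_coefficient_bounded(self, weak_triplet):
        from ratemoments import standard_signal

        spec = weak_triplet.with_inputs(mu_bg=standard_signal("pulse"))
        traj = integrate_closure(spec, np.linspace(0, 8, 81))
        jj, kk = pair_indices(3)
        sig = np.sqrt(traj.var_activity)
        rho = traj.cov_activity / (sig[:, jj] * sig[:, kk])
        assert np.max(np.abs(rho)) <= 1.0 + 1e-6

    def test_bad_time_grid(self, uncoupled_pair):
        with pytest.raises(ValueError):
            integrate_closure(uncoupled_pair, [0.0, 0.0, 1.0])


class TestActivityToFiring:
    def test_deterministic_limit(self, uncoupled_pair):
        spec = uncoupled_pair
        nu, var_nu, cov_nu = firing_statistics(
            spec,
            mean=np.array([[0.3, -0.1]]),
            var=np.array([[0.0, 0.0]]),
            cov=np.array([[0.0]]),
        )
        expected = spec.firing(np.array([0.3, -0.1]))
        np.testing.assert_allclose(nu[0], expected, atol=1e-12)
        np.testing.assert_allclose(var_nu[0], 0.0, atol=1e-12)

    def test_zero_correlation_gives_zero_cov(self, uncoupled_pair):
        _, _, cov_nu = firing_statistics(
            uncoupled_pair,
            mean=np.array([[0.2, 0.4]]),
            var=np.array([[0.5, 0.3]]),
            cov=np.array([[0.0]]),
        )
        assert abs(cov_nu[0, 0]) < 1e-12

    def test_var_firing_bounds(self, weak_triplet):
        traj = integrate_closure(weak_triplet, np.linspace(0, 5, 21))
        assert np.all(traj.mean_firing >= 0.0) and np.all(traj.mean_firing <= 1.0)
        assert np.all(traj.var_firing >= 0.0) and np.all(traj.var_firing <= 0.25)

    def test_inconsistent_moments_rejected(self, uncoupled_pair):
        with pytest.raises(ValueError, match="inconsistent"):
            firing_statistics(
                uncoupled_pair,
                mean=np.array([[0.0, 0.0]]),
                var=np.array([[0.0, 1.0]]),
                cov=np.array([[0.2]]),
            )

    def test_static_input_mode(self, uncoupled_pair):
        # with zero coupling the activity correlation equals the input
        # correlation, so both output modes agree
        traj = integrate_closure(uncoupled_pair, np.linspace(0, 4, 9))
        alt = activity_to_firing(
            StatTrajectory(
                times=traj.times,
                mean_activity=traj.mean_activity,
                var_activity=traj.var_activity,
                cov_activity=traj.cov_activity,
            ),
            uncoupled_pair,
            ClosureConfig(firing_corr_mode="static_input"),
        )
        np.testing.assert_allclose(alt.cov_firing, traj.cov_firing, atol=1e-9)
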