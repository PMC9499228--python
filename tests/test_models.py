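"""Model-core checks against independent numerical oracles."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp
from scipy.stats import poisson

import veloscope as v
from veloscope import models as M

from oracles import total_variation


def ode_oracle(schedule, t_eval, init=None):
    """Adaptive ODE integration of the mean equations (independent route)."""
    if init is None:
        init = schedule.steady_state()

    def rhs(t, y):
        a = schedule.alpha_at(t)
        return [a - schedule.beta * y[0], schedule.beta * y[0] - schedule.gamma * y[1]]

    sol = solve_ivp(
        rhs, (0.0, max(t_eval)), list(init), t_eval=sorted(t_eval),
        rtol=1e-11, atol=1e-13, max_step=0.1,
    )
    return sol.y


class TestMeanTrajectory:
    def test_steady_state_is_fixed_point(self):
        sched = v.RateSchedule((), (2.0,), 1.0, 0.5, 10.0)
        mu_u, mu_s = v.mean_trajectory(sched, np.linspace(0, 10, 7))
        assert np.allclose(mu_u, 2.0) and np.allclose(mu_s, 4.0)

    def test_birth_death_relaxation_to_alpha_over_beta(self):
        # one-species analogue: u relaxes from 0 toward alpha/beta = 1
        sched = v.RateSchedule((), (1.0,), 1.0, 1.0, 50.0)
        mu_u, _ = v.mean_trajectory(sched, [0.0, 1.0, 30.0], init=(0.0, 0.0))
        assert mu_u[0] == 0.0
        assert mu_u[1] == pytest.approx(1.0 - np.exp(-1.0), rel=1e-12)
        assert mu_u[2] == pytest.approx(1.0, abs=1e-10)

    def test_piecewise_solution_matches_ode_quadrature(self):
        sched = v.RateSchedule((3.0, 7.0), (1.0, 5.0, 1.0), 2.0, 1.0, 10.0)
        times = [0.5, 3.0, 3.5, 6.9, 7.4, 10.0]
        mu_u, mu_s = v.mean_trajectory(sched, times)
        ref = ode_oracle(sched, times)
        assert np.allclose(mu_u, ref[0], rtol=1e-8)
        assert np.allclose(mu_s, ref[1], rtol=1e-8)

    def test_degenerate_beta_equals_gamma_branch(self):
        exact = v.RateSchedule((2.0,), (1.0, 4.0), 1.5, 1.5, 6.0)
        near = v.RateSchedule((2.0,), (1.0, 4.0), 1.5, 1.5 * (1 + 1e-7), 6.0)
        times = [1.0, 2.5, 5.0]
        for a, b in zip(v.mean_trajectory(exact, times),
                        v.mean_trajectory(near, times)):
            assert np.allclose(a, b, rtol=1e-5)
        ref = ode_oracle(exact, times)
        assert np.allclose(v.mean_trajectory(exact, times)[1], ref[1], rtol=1e-8)

    def test_continuity_across_switches(self):
        sched = v.RateSchedule((3.0,), (1.0, 6.0), 2.0, 0.7, 8.0)
        eps = 1e-9
        left = v.mean_trajectory(sched, [3.0 - eps])
        right = v.mean_trajectory(sched, [3.0 + eps])
        assert left[0][0] == pytest.approx(right[0][0], abs=1e-6)
        assert left[1][0] == pytest.approx(right[1][0], abs=1e-6)


class TestBirthDeathOccupationPGF:
    def test_normalization_at_one(self):
        assert v.birth_death_occupation_pgf(2.0, 1.0, 0.0, 5.0, 1.0) == 1.0

    def test_ergodic_limit_is_poisson_pgf(self):
        for z in (0.0, 0.3, 0.8):
            h = v.birth_death_occupation_pgf(2.0, 1.0, 0.0, 1e5, z)
            assert h == pytest.approx(np.exp((z - 1.0) * 2.0), rel=1e-3)

    def test_closed_form_matches_quadrature(self):
        alpha, beta, y0, horizon = 2.0, 1.0, 0.0, 5.0
        z = 0.5

        def g(t):
            y = (y0 - alpha / beta) * np.exp(-beta * t) + alpha / beta
            return np.exp((z - 1.0) * y)

        ref = quad(g, 0, horizon, epsabs=1e-13, epsrel=1e-13)[0] / horizon
        h = v.birth_death_occupation_pgf(alpha, beta, y0, horizon, z)
        assert h == pytest.approx(ref, rel=1e-8)

    def test_constant_mean_limit(self):
        # y0 = alpha/beta: the mean never moves, H(z) = exp(u alpha/beta)
        h = v.birth_death_occupation_pgf(3.0, 1.5, 2.0, 4.0, 0.25)
        assert h == pytest.approx(np.exp(-0.75 * 2.0), rel=1e-12)

    def test_invalid_z_rejected(self):
        with pytest.raises(ValueError):
            v.birth_death_occupation_pgf(1.0, 1.0, 0.0, 1.0, 1.5)


class TestCanonicalJointPMF:
    sched = v.RateSchedule((3.0, 7.0), (1.0, 5.0, 1.0), 2.0, 1.0, 10.0)

    def test_mass_at_origin(self):
        pmf = v.canonical_joint_pmf(self.sched, 5.0)
        mu_u, mu_s = v.mean_trajectory(self.sched, 5.0)
        assert pmf.probs[0, 0] == pytest.approx(np.exp(-mu_u - mu_s), rel=1e-12)

    def test_marginal_is_poisson(self):
        pmf = v.canonical_joint_pmf(self.sched, 5.0)
        mu_u, _ = v.mean_trajectory(self.sched, 5.0)
        expected = poisson.pmf(np.arange(pmf.probs.shape[0]), mu_u)
        # marginalizing the truncated product leaves a deficit of the order of
        # the truncated spliced mass
        assert np.allclose(pmf.marginal_u(), expected, atol=5 * pmf.truncated_mass)

    def test_normalization_within_truncation(self):
        pmf = v.canonical_joint_pmf(self.sched, 2.0)
        assert pmf.total() == pytest.approx(1.0, abs=1e-5)
        assert pmf.probs.shape[0] >= 11 and pmf.probs.shape[1] >= 11


class TestOccupationPMF:
    def test_dirac_measure_is_instantaneous_pmf(self):
        sched = v.RateSchedule((), (2.0,), 1.0, 0.5, 40.0)
        occ = v.occupation_pmf(sched, v.SamplingMeasure("dirac", 40.0))
        inst = v.canonical_joint_pmf(sched, 40.0, bounds=(occ.max_u, occ.max_s))
        assert np.allclose(occ.probs, inst.probs, atol=1e-12)

    def test_ergodic_limit_constant_schedule(self):
        beta, gamma = 1.0, 0.5
        horizon = 50.0 / min(beta, gamma)
        sched = v.RateSchedule((), (2.0,), beta, gamma, horizon)
        occ = v.occupation_pmf(sched)
        pu = poisson.pmf(np.arange(occ.probs.shape[0]), 2.0 / beta)
        ps = poisson.pmf(np.arange(occ.probs.shape[1]), 2.0 / gamma)
        tv = 0.5 * np.abs(occ.probs - np.outer(pu, ps)).sum()
        assert tv < 1e-3

    def test_bimodal_marginals_for_separated_rates(self):
        sched = v.RateSchedule((20.0,), (1.0, 20.0), 1.0, 1.0, 40.0)
        marg = v.occupation_pmf(sched).marginal_s()
        interior = marg[1:-1]
        peaks = np.flatnonzero(
            (interior > np.roll(marg, 1)[1:-1]) & (interior > np.roll(marg, -1)[1:-1])
        )
        assert peaks.size >= 2

    def test_exponential_measure_integrates_to_one(self):
        sched = v.RateSchedule((1.0,), (1.0, 4.0), 1.0, 0.8, 3.0)
        occ = v.occupation_pmf(sched, v.SamplingMeasure("exponential", 3.0))
        assert occ.total() == pytest.approx(1.0, abs=1e-4)


class TestBurstyStationaryPMF:
    def test_sums_to_one(self):
        pmf = v.bursty_stationary_pmf(v.BurstModel(2.0), 0.5, 1.0, 0.5,
                                      deficit_tol=np.inf)
        assert pmf.total() == pytest.approx(1.0, abs=1e-6)

    def test_unspliced_mean_from_pgf_derivative(self):
        # numerical derivative of the PGF at z=1 against burst_freq * b / beta
        burst, alpha, beta, gamma = v.BurstModel(1.5), 0.4, 1.0, 0.7
        h = 1e-6
        g_u = np.array([-h, 0.0, h])
        g_s = np.zeros(3)
        logpgf = M._bursty_log_pgf(burst, alpha, beta, gamma, g_u, g_s)
        deriv = (np.exp(logpgf[2]) - np.exp(logpgf[0])) / (2 * h)
        assert deriv == pytest.approx(alpha * burst.mean_burst / beta, rel=1e-5)

    def test_moments_match_wide_truncation_pmf(self):
        burst, alpha, beta, gamma = v.BurstModel(2.0), 0.5, 1.0, 0.5
        mu_u, mu_s, var_u, var_s = M.bursty_moments(burst, alpha, beta, gamma)
        pmf = v.bursty_stationary_pmf(burst, alpha, beta, gamma,
                                      truncation=(60, 100), deficit_tol=np.inf)
        got_u, got_s = pmf.mean()
        assert got_u == pytest.approx(mu_u, rel=1e-6)
        assert got_s == pytest.approx(mu_s, rel=1e-6)
        xu = np.arange(pmf.probs.shape[0])
        xs = np.arange(pmf.probs.shape[1])
        assert pmf.marginal_u() @ (xu - mu_u) ** 2 == pytest.approx(var_u, rel=1e-5)
        assert pmf.marginal_s() @ (xs - mu_s) ** 2 == pytest.approx(var_s, rel=1e-5)


class TestMixture:
    s1 = v.RateSchedule((3.0, 7.0), (1.0, 5.0, 1.0), 2.0, 1.0, 10.0)
    s2 = v.RateSchedule((3.0, 7.0), (1.0, 0.2, 3.0), 2.0, 1.0, 10.0)
    measure = v.SamplingMeasure("uniform", 10.0)

    def test_degenerate_mixture_is_single_component(self):
        mix = v.MixtureModel((1.0, 0.0), (self.s1, self.s2))
        one = v.MixtureModel((1.0,), (self.s1,))
        assert v.mixture_pgf(mix, self.measure, 0.5, 0.7) == pytest.approx(
            v.mixture_pgf(one, self.measure, 0.5, 0.7), rel=1e-12
        )

    def test_normalization(self):
        mix = v.MixtureModel((0.4, 0.6), (self.s1, self.s2))
        assert v.mixture_pgf(mix, self.measure, 1.0, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_pmf_linearity(self):
        mix = v.MixtureModel((0.4, 0.6), (self.s1, self.s2))
        pmix = M.mixture_occupation_pmf(mix)
        p1 = v.occupation_pmf(self.s1)
        p2 = v.occupation_pmf(self.s2)
        ref = np.zeros(pmix.probs.shape)
        ref[: p1.probs.shape[0], : p1.probs.shape[1]] += 0.4 * p1.probs
        ref[: p2.probs.shape[0], : p2.probs.shape[1]] += 0.6 * p2.probs
        assert np.abs(pmix.probs - ref).max() < 1e-10

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            v.MixtureModel((0.7, 0.7), (self.s1, self.s2))


class TestNetVelocityIntegral:
    def test_equilibrium_interval_is_zero(self):
        sched = v.RateSchedule((), (5.0,), 1.0, 0.7, 2.0)
        assert v.net_velocity_integral(sched, 0) == pytest.approx(0.0, abs=1e-12)

    def test_vanishes_for_long_intervals(self):
        vals = []
        for delta in (2.0, 20.0, 200.0, 2000.0):
            sched = v.RateSchedule((), (5.0,), 1.0, 0.7, delta)
            vals.append(abs(v.net_velocity_integral(sched, 0, init=(1.0, 1.0))))
        assert vals[0] > vals[1] > vals[2] > vals[3]
        # decay is O(1/Delta): the mean increment saturates at s_inf - s_0
        assert vals[2] / vals[3] == pytest.approx(10.0, rel=0.05)
        assert vals[3] < 5e-3

    def test_closed_form_matches_quadrature(self):
        # beta = 1 convention; out-of-equilibrium start
        sched = v.RateSchedule((), (5.0,), 1.0, 0.7, 2.0)
        ref = ode_oracle(sched, [0.0, 2.0], init=(1.0, 1.0))
        expected = (ref[1][1] - ref[1][0]) / 2.0
        got = v.net_velocity_integral(sched, 0, init=(1.0, 1.0))
        assert got == pytest.approx(expected, rel=1e-8)

    def test_moment_identity_over_horizon(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            beta, gamma = rng.uniform(0.5, 3.0, 2)
            sched = v.RateSchedule(
                (3.0, 7.0), tuple(rng.uniform(0.2, 6.0, 3)), beta, gamma, 10.0
            )
            lhs = v.net_velocity_integral(sched)
            mu_u_bar, mu_s_bar = M.occupation_means(sched)
            assert lhs == pytest.approx(beta * mu_u_bar - gamma * mu_s_bar, abs=1e-8)


class TestValidation:
    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            v.RateSchedule((7.0, 3.0), (1.0, 2.0, 3.0), 1.0, 1.0, 10.0)
        with pytest.raises(ValueError):
            v.RateSchedule((), (1.0,), 0.0, 1.0, 10.0)
        with pytest.raises(ValueError):
            v.RateSchedule((3.0,), (1.0,), 1.0, 1.0, 10.0)

    def test_sampling_measure_kinds(self):
        with pytest.raises(ValueError):
            v.SamplingMeasure("gauss", 1.0)

    def test_canonical_pmf_time_bounds(self):
        sched = v.RateSchedule((), (1.0,), 1.0, 1.0, 5.0)
        with pytest.raises(ValueError):
            v.canonical_joint_pmf(sched, 6.0)
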