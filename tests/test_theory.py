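import math

import numpy as np
import pytest
from scipy import integrate

from syncache import theory


class TestScalingFormulas:
    def test_update_count(self):
        assert theory.K_theory(1000, 1000) == pytest.approx(2000.0)
        assert theory.K_theory(1900, 1000) == pytest.approx(380000.0)

    def test_learning_time(self):
        assert theory.T_theory(1000, 1000) == pytest.approx(1000**1.5)
        assert theory.T_theory(100, 1000) == pytest.approx(100**1.5 / 1.9**2)

    def test_inefficiency_value_and_identity(self):
        assert theory.perceptron_inefficiency(1900, 1000) == pytest.approx(772.9, rel=1e-3)
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(50, 5000)
            p = int(n * rng.uniform(0.1, 1.9))
            if p < 1:
                continue
            lhs = theory.perceptron_inefficiency(p, n)
            rhs = math.sqrt(math.pi / 2) * math.sqrt(theory.K_theory(p, n))
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_capacity_limit_rejected(self):
        for fn in (theory.K_theory, theory.T_theory, theory.perceptron_inefficiency):
            with pytest.raises(ValueError):
                fn(2000, 1000)

    def test_minimal_energy_unit_case_and_homogeneity(self):
        assert theory.minimal_energy_theory(1, 1, 1.0) == pytest.approx(math.sqrt(2 / math.pi))
        assert theory.minimal_energy_theory(10, 8.0) == pytest.approx(
            math.sqrt(2) * theory.minimal_energy_theory(10, 4.0)
        )

    def test_optimal_threshold_limits(self):
        assert theory.optimal_threshold(1.0, 300.0, 0.0, 1000.0) == pytest.approx(math.sqrt(900.0))
        assert theory.optimal_threshold(1.0, 300.0, 1e9, 1000.0) == 1.0  # floor at eta

    def test_cached_inefficiency_branches(self):
        assert theory.cached_inefficiency(0.0, 100.0, 1e9) == pytest.approx(
            math.sqrt(2 * math.pi / 3)
        )
        # large cT: capped at the plain perceptron inefficiency sqrt(pi K / 2)
        k = 500.0
        assert theory.cached_inefficiency(1e9, 1e9, k) == pytest.approx(math.sqrt(math.pi * k / 2))


class TestSteadyState:
    @pytest.mark.parametrize("sigma, theta", [(1.0, 2.0), (0.5, 5.0), (2.0, 3.0), (1.0, 0.3)])
    def test_density_normalization_boundary_symmetry(self, sigma, theta):
        total, _ = integrate.quad(
            lambda s: theory.steady_state_density(s, sigma, theta), -theta, theta, limit=400
        )
        assert total == pytest.approx(1.0, rel=1e-8)
        assert theory.steady_state_density(theta, sigma, theta) == 0.0
        assert theory.steady_state_density(-theta, sigma, theta) == 0.0
        rng = np.random.default_rng(1)
        s = rng.uniform(0, theta, 100)
        assert np.allclose(
            theory.steady_state_density(s, sigma, theta),
            theory.steady_state_density(-s, sigma, theta),
        )
        assert np.all(theory.steady_state_density(s * 0.999, sigma, theta) >= 0)

    def test_density_outside_support_rejected(self):
        with pytest.raises(ValueError):
            theory.steady_state_density(2.1, 1.0, 2.0)

    @pytest.mark.parametrize("sigma", [0.1, 0.5, 1.0, 3.0, 10.0])
    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0])
    def test_normalization_closed_form_vs_quadrature(self, sigma, theta):
        if theta / sigma > 26:  # beyond double range: the overflow is reported
            with pytest.raises(OverflowError):
                theory.normalization_Z(sigma, theta)
            return
        z = theory.normalization_Z(sigma, theta)
        zq = theory.normalization_Z_quadrature(sigma, theta)
        assert z == pytest.approx(zq, rel=1e-6)

    def test_mean_abs_saturates_at_half_normal_mean(self):
        # decay-dominated regime: the threshold is irrelevant, <|s|> -> sigma/sqrt(pi)
        for sigma, theta in [(0.1, 10.0), (1.0, 40.0)]:
            assert theory.mean_abs_transient(sigma, theta) == pytest.approx(
                sigma / math.sqrt(math.pi), rel=1e-6
            )

    def test_normalization_homogeneity(self):
        # Z(lambda sigma, lambda theta) = lambda Z(sigma, theta)
        for lam in (0.5, 2.0, 7.0):
            assert theory.normalization_Z(lam * 1.3, lam * 2.1) == pytest.approx(
                lam * theory.normalization_Z(1.3, 2.1), rel=1e-10
            )

    def test_triangular_limit_of_density(self):
        """For theta << sigma the density tends to (theta - |s|) / theta^2."""
        sigma, theta = 50.0, 1.0
        s = np.linspace(-0.99, 0.99, 41)
        dens = theory.steady_state_density(s, sigma, theta)
        tri = (theta - np.abs(s)) / theta**2
        assert np.allclose(dens, tri, rtol=0.01)

    def test_mean_abs_triangular_limit(self):
        assert theory.mean_abs_transient(100.0, 1.0) == pytest.approx(1.0 / 3.0, rel=1e-3)

    def test_scale_invariance_of_mean(self):
        for lam in (0.5, 3.0):
            assert theory.mean_abs_transient(lam * 1.0, lam * 2.0) == pytest.approx(
                lam * theory.mean_abs_transient(1.0, 2.0), rel=1e-10
            )

    def test_rate_nonnegative_on_grid(self):
        for sigma in (0.2, 1.0, 4.0):
            for theta in (0.5, 2.0, 10.0, 100.0):
                assert theory.consolidation_rate(sigma, theta, tau=100.0) >= 0.0

    def test_rate_no_decay_limit(self):
        """As tau grows at fixed sigma_s, r -> sigma_s^2 / theta^2."""
        eta, p, theta = 1.0, 0.5, 10.0
        sigma_s2 = p * eta**2
        for tau in (1e4, 1e6):
            sigma = math.sqrt(tau * sigma_s2)
            r = theory.consolidation_rate(sigma, theta, tau)
            assert r == pytest.approx(sigma_s2 / theta**2, rel=2e-2 if tau < 1e5 else 2e-4)

    def test_powers_limits(self):
        m_trans, m_cons = theory.powers(0.0, 1000, 0.5, 1.0, 500.0, 5.0)
        assert m_trans == 0.0 and m_cons > 0.0
        # small theta/sigma: m_trans/(c N theta) -> 1/3 within 1%
        m_trans, m_cons = theory.powers(0.02, 1000, 0.5, 1.0, 1e6, 0.05)
        assert m_trans / (0.02 * 1000 * 0.05) == pytest.approx(1 / 3, rel=0.01)
        # and m_cons -> p N eta^2 / theta
        assert m_cons == pytest.approx(0.5 * 1000 * 1.0 / 0.05, rel=0.01)

    def test_steady_state_bundle_consistency(self):
        ss = theory.steady_state(p=0.3, eta=1.0, tau=400.0, theta=6.0, c=0.01, N=500)
        assert ss.sigma == pytest.approx(math.sqrt(400 * 0.3))
        assert ss.m_trans == pytest.approx(0.01 * 500 * ss.mean_abs)
        assert ss.m_cons == pytest.approx(500 * 6.0 * ss.rate)
        assert ss.density(0.0) > ss.density(5.9)


class TestMonteCarloOracle:
    def test_walk_matches_analytic_summary(self):
        """Ensemble walk agrees with the closed-form mean |s| and reset rate."""
        sigma, theta, tau = 1.0, 2.0, 150.0
        walk = theory.simulate_reset_walk(sigma, theta, tau, n_walkers=8000,
                                          n_record=30, seed=7)
        mean_th = theory.mean_abs_transient(sigma, theta)
        rate_th = theory.consolidation_rate(sigma, theta, tau)
        assert abs(walk.mean_abs - mean_th) < 3 * walk.mean_abs_se + 1e-3
        assert abs(walk.rate - rate_th) < 3 * walk.rate_se + 1e-6
        assert theory.ks_distance(walk.samples, sigma, theta) < 0.02

    def test_two_threshold_walk_mean(self):
        got = theory.simulate_two_threshold_walk(theta=20.0, n_walkers=50,
                                                 n_steps=4000, seed=3)
        assert got / 20.0 == pytest.approx(1 / 3, rel=0.03)
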