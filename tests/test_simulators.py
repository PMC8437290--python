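"""Individual-based model, SPDE grid solver, and noise-term Monte Carlo."""

import dataclasses
import math

import numpy as np
import pytest

from stochlife import (
    BranchingSimConfig,
    GBMAllometricParams,
    ModelGrid,
    NoiseField,
    SPDEGridConfig,
    EnvironmentSpec,
    dominant_root,
    fit_quadratic_coefficient,
    q_term_statistics,
    simulate_branching,
    simulate_spde,
)
from stochlife.errors import ConfigurationError, ParameterError
from stochlife.perturbation import dev_norm_closed_form
from stochlife.simulators import (
    default_qterm_grid,
    default_spde_config,
    spde_epsilon2_coefficient,
)


class TestConfigs:
    def test_branching_config_invariants(self):
        with pytest.raises(ConfigurationError):
            BranchingSimConfig(dt=0.0)
        with pytest.raises(ConfigurationError):
            BranchingSimConfig(dt=1.0, t_max=10.0)
        with pytest.raises(ConfigurationError):
            BranchingSimConfig(pop_cap=10)

    def test_spde_dt_must_divide_age_cell(self):
        with pytest.raises(ConfigurationError, match="divide"):
            SPDEGridConfig(z_min=-5, z_max=5, n_z=10, a_max=10, n_a=10,
                           dt=0.3, t_max=10.0)


class TestBranching:
    def test_linear_birth_death_limit(self):
        # no growth, no size noise: a plain birth-death process whose
        # growth rate is f0 x^rho - mu0
        p = GBMAllometricParams(b1=0.0, sigma1=0.0, x=0.01, mu0=0.1,
                                f0=1.0, rho=0.4)
        target = p.f0 * p.x**p.rho - p.mu0
        cfg = BranchingSimConfig(dt=0.01, t_max=80.0, n0=3000, pop_cap=60000,
                                 seed=5, burn_in=0.2)
        est = simulate_branching(p, cfg)
        assert est.slope == pytest.approx(target, abs=0.012)

    def test_identical_seed_identical_trajectory(self, fig2):
        cfg = BranchingSimConfig(dt=0.02, t_max=20.0, n0=100, pop_cap=5000, seed=3)
        a = simulate_branching(fig2, cfg)
        b = simulate_branching(fig2, cfg)
        assert a.slope == b.slope and a.diagnostics == b.diagnostics

    def test_extinction_reported_not_raised(self):
        p = GBMAllometricParams(b1=0.0, sigma1=0.0, x=0.01, mu0=5.0,
                                f0=0.1, rho=0.4)
        cfg = BranchingSimConfig(dt=0.02, t_max=30.0, n0=5, pop_cap=1000, seed=0)
        est = simulate_branching(p, cfg)
        assert est.diagnostics["extinct"]
        assert math.isnan(est.slope)

    def test_cap_resampling_keeps_growth_unbiased(self, fig2):
        # same dynamics with a small cap (frequent resampling) should give a
        # compatible slope to a larger-cap run
        cfg_small = BranchingSimConfig(dt=0.01, t_max=60.0, n0=500,
                                       pop_cap=2000, seed=8, burn_in=0.3)
        cfg_big = BranchingSimConfig(dt=0.01, t_max=60.0, n0=500,
                                     pop_cap=50000, seed=8, burn_in=0.3)
        a = simulate_branching(fig2, cfg_small)
        b = simulate_branching(fig2, cfg_big)
        assert a.diagnostics["n_resamples"] > 5
        assert a.slope == pytest.approx(b.slope, abs=0.02)


class TestNoiseField:
    def test_increment_statistics_match_white_noise_scaling(self):
        grid = ModelGrid(-2.0, 2.0, 8, 4.0, 4)
        field = NoiseField(grid, seed=2)
        dt = 0.1
        draws = np.stack([field.increments(dt) for _ in range(4000)])
        target_var = dt / (grid.cell_area_ay())
        assert np.allclose(draws.mean(axis=0), 0.0,
                           atol=4 * np.sqrt(target_var / 4000))
        assert np.allclose(draws.var(axis=0) / target_var, 1.0, atol=0.15)
        # distinct cells are uncorrelated
        flat = draws.reshape(4000, -1)
        corr = np.corrcoef(flat[:, 0], flat[:, 17])[0, 1]
        assert abs(corr) < 0.05

    def test_hermite_orthogonality_sanity(self):
        # standard-normal draws: E[h_m] = 0, E[h_m^2] = m!
        from numpy.polynomial.hermite_e import hermeval

        rng = np.random.default_rng(12)
        x = rng.standard_normal(200_000)
        for m, fact in ((1, 1.0), (2, 2.0), (3, 6.0)):
            coeffs = [0.0] * m + [1.0]
            h = hermeval(x, coeffs)
            assert np.mean(h) == pytest.approx(0.0, abs=4 * math.sqrt(fact / x.size))
            assert np.mean(h * h) == pytest.approx(fact, rel=0.05)


class TestSPDE:
    def test_deterministic_limit_converges_to_r0(self, fig2):
        r0 = dominant_root(fig2).r0
        coarse = default_spde_config(fig2, t_max=30.0, delta_a=0.25,
                                     delta_z=0.25, substeps=4)
        fine = default_spde_config(fig2, t_max=30.0, delta_a=0.125,
                                   delta_z=0.125, substeps=4)
        err_c = abs(simulate_spde(fig2, EnvironmentSpec(0.0), coarse).slope - r0)
        err_f = abs(simulate_spde(fig2, EnvironmentSpec(0.0), fine).slope - r0)
        assert err_c / r0 < 0.035
        assert err_f / r0 < 0.015
        assert err_f < 0.75 * err_c

    def test_log_mass_affine_after_transient(self, fig2):
        cfg = default_spde_config(fig2, t_max=30.0, delta_a=0.25,
                                  delta_z=0.25, substeps=4)
        est, traj = simulate_spde(fig2, EnvironmentSpec(0.0), cfg,
                                  return_trajectory=True)
        t, logm = traj[:, 0], traj[:, 1]
        late = t >= 15.0
        resid = logm[late] - (logm[late].mean()
                              + est.slope * (t[late] - t[late].mean()))
        assert np.max(np.abs(resid)) < 5e-3

    def test_fixed_seed_reproducible(self, fig2):
        cfg = default_spde_config(fig2, t_max=10.0, delta_a=0.5, delta_z=0.5,
                                  substeps=8, seed=9)
        a, tra = simulate_spde(fig2, EnvironmentSpec(0.1), cfg,
                               return_trajectory=True)
        b, trb = simulate_spde(fig2, EnvironmentSpec(0.1), cfg,
                               return_trajectory=True)
        assert a.slope == b.slope
        assert np.array_equal(tra, trb)

    def test_neonate_size_must_lie_in_window(self, fig2):
        cfg = SPDEGridConfig(z_min=0.0, z_max=5.0, n_z=50, a_max=10.0,
                             n_a=20, dt=0.125, t_max=10.0)
        with pytest.raises(ConfigurationError):
            simulate_spde(fig2, EnvironmentSpec(0.0), cfg)

    def test_sigma_zero_rejected(self):
        p = GBMAllometricParams(b1=0.2, sigma1=0.0, x=0.01, mu0=0.1,
                                f0=1.0, rho=0.4)
        cfg = SPDEGridConfig(z_min=-6, z_max=2, n_z=32, a_max=8.0, n_a=16,
                             dt=0.25, t_max=10.0)
        with pytest.raises(ParameterError):
            simulate_spde(p, EnvironmentSpec(0.0), cfg)

    def test_quadratic_response_matches_grid_deviation_at_small_amplitude(
        self, fig2
    ):
        """Within the grid's perturbative range, the second-difference
        estimate of the epsilon^2 coefficient agrees with minus half the
        grid deviation sum."""
        cfg = default_spde_config(fig2, t_max=30.0, delta_a=0.5, delta_z=0.5,
                                  substeps=16, a_tail=1e-5)
        cfg = dataclasses.replace(cfg, burn_in=0.1)
        out = spde_epsilon2_coefficient(fig2, cfg, eps=0.02, n_rep=64,
                                        seed=11, relax_time=15.0)
        target = -0.5 * out["grid_dev_norm"]
        assert out["coefficient"] < 0.0
        assert abs(out["coefficient"] - target) <= max(
            3.0 * out["stderr"], 0.15 * abs(target)
        )


class TestQTerms:
    def test_projected_noise_variance_estimates_deviation_term(self, fig2):
        stats = q_term_statistics(fig2, t=5.0, n_rep=400, seed=3)
        dev = dev_norm_closed_form(fig2)
        # the grid resolves the squared product to a few percent
        assert stats.grid_dev_norm == pytest.approx(dev, rel=0.05)
        assert stats.var_q1_over_t == pytest.approx(
            stats.grid_dev_norm, rel=4.0 * math.sqrt(2.0 / stats.n_rep)
        )

    def test_second_order_term_mean_zero(self, fig2):
        stats = q_term_statistics(fig2, t=5.0, n_rep=400, seed=4)
        lo, hi = stats.ci95_q2
        assert lo <= 0.0 <= hi

    def test_api_is_amplitude_free(self):
        # the normalized statistics multiply eps^m in the series and must
        # not take a noise amplitude
        import inspect

        sig = inspect.signature(q_term_statistics)
        assert "epsilon" not in sig.parameters and "eps" not in sig.parameters

    def test_narrow_window_fails_mass_check(self, fig2):
        grid = ModelGrid(math.log(fig2.x) - 0.5, math.log(fig2.x) + 0.5,
                         8, 10.0, 20)
        with pytest.raises(ConfigurationError, match="resolve"):
            q_term_statistics(fig2, t=2.0, n_rep=10, grid=grid, seed=0)

    def test_seeded_reproducibility(self, fig2):
        grid = default_qterm_grid(fig2, delta_z=0.2, n_a=60)
        a = q_term_statistics(fig2, t=2.0, n_rep=50, grid=grid, seed=6)
        b = q_term_statistics(fig2, t=2.0, n_rep=50, grid=grid, seed=6)
        assert a == b


class TestQuadraticFit:
    def test_exact_quadratic_recovered(self):
        eps = np.array([0.0, 0.05, 0.1, 0.2])
        slopes = 0.27 - 1.4 * eps**2
        fit = fit_quadratic_coefficient(zip(eps, slopes))
        assert fit.coefficient == pytest.approx(-1.4, abs=1e-12)
        assert fit.intercept == pytest.approx(0.27, abs=1e-12)

    def test_requires_three_distinct_eps_including_zero(self):
        with pytest.raises(ParameterError):
            fit_quadratic_coefficient([(0.0, 1.0), (0.1, 0.9)])
        with pytest.raises(ParameterError):
            fit_quadratic_coefficient([(0.05, 1.0), (0.1, 0.9), (0.2, 0.7)])

    def test_coverage_on_noisy_synthetic_slopes(self):
        rng = np.random.default_rng(14)
        c2, hits, n_runs = -2.0, 0, 200
        eps = np.repeat([0.0, 0.05, 0.1], 20)
        for _ in range(n_runs):
            slopes = 0.3 + c2 * eps**2 + 0.001 * rng.standard_normal(eps.size)
            fit = fit_quadratic_coefficient(zip(eps, slopes))
            hits += abs(fit.coefficient - c2) <= 1.96 * fit.stderr
        assert 0.90 <= hits / n_runs <= 0.99

    def test_linear_term_option(self):
        eps = np.array([0.0, 0.05, 0.1])
        slopes = 0.3 + 0.5 * eps - 2.0 * eps**2
        fit = fit_quadratic_coefficient(zip(eps, slopes), include_linear=True)
        assert fit.coefficient == pytest.approx(-2.0, abs=1e-9)
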