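"""Characteristic function, dominant root, eigenpair and their oracles."""

import math

import numpy as np
import pytest

from stochlife import (
    GBMAllometricParams,
    dominant_root,
    dominant_root_numeric,
    eigenfunction_w,
    eigenpair,
    feynman_kac_value_mc,
    pairing,
    psi,
    psi_quadrature,
    reproduction_number,
    reproductive_value,
)
from stochlife.errors import DegenerateInputError, DivergenceError, ParameterError
from stochlife.spectral import convergence_abscissa

from conftest import random_gbm_params


class TestPsi:
    def test_equals_one_at_dominant_root(self, fig2):
        r0 = dominant_root(fig2).r0
        assert psi(r0, fig2) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_growth_limit(self):
        # no growth, no volatility: psi(0) is fertility over mortality
        p = GBMAllometricParams(b1=0.0, sigma1=0.0, x=0.01, mu0=0.1, f0=1.0, rho=0.4)
        assert psi(0.0, p) == pytest.approx(p.f0 * p.x**p.rho / p.mu0)

    def test_matches_quadrature_through_transition_density(self, fig2):
        val = psi(0.3, fig2)
        quad = psi_quadrature(0.3, fig2, use_transition_density=True)
        assert quad == pytest.approx(val, rel=1e-8)

    def test_strictly_decreasing_and_diverges_at_pole(self, fig2):
        pole = convergence_abscissa(fig2)
        grid = pole + np.geomspace(1e-6, 10.0, 40)
        vals = [psi(r, fig2) for r in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[0] > 1e4 and vals[-1] < 0.1
        with pytest.raises(DivergenceError):
            psi(pole, fig2)


class TestDominantRoot:
    def test_fig2_reference_value(self, fig2):
        # 0.4*(0.6 - 0.075) + 0.01**0.4 - 0.1
        assert dominant_root(fig2).r0 == pytest.approx(0.2684893192, abs=1e-9)

    def test_degenerate_reduction(self):
        p = GBMAllometricParams(b1=0.0, sigma1=0.0, x=0.01, mu0=0.1, f0=1.0, rho=0.4)
        assert dominant_root(p).r0 == pytest.approx(p.f0 * p.x**p.rho - p.mu0)

    def test_internal_stochasticity_reduces_growth(self, fig2):
        sigmas = np.linspace(0.1, 1.5, 20)
        r0s = [dominant_root(fig2.with_sigma1(s)).r0 for s in sigmas]
        assert all(a > b for a, b in zip(r0s, r0s[1:]))

    def test_closed_form_equals_bracketed_root_on_random_parameters(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = random_gbm_params(rng)
            assert dominant_root_numeric(p) == pytest.approx(
                dominant_root(p).r0, abs=1e-10
            )


class TestReproductionNumber:
    def test_reference_value(self):
        p = GBMAllometricParams(b1=0.6, sigma1=0.5, x=0.01, mu0=0.5, f0=1.0, rho=0.4)
        assert reproduction_number(p) == pytest.approx(0.01**0.4 / 0.29, rel=1e-12)

    def test_diverges_when_discounted_growth_dominates(self, fig2):
        with pytest.raises(DivergenceError, match="R0 undefined"):
            reproduction_number(fig2)  # abscissa 0.11 > 0

    def test_threshold_identity_r0_zero_iff_R0_one(self):
        # solve mu0 so that r0 = 0 on a parameter slice, then R0 must be 1
        base = dict(b1=0.3, sigma1=0.4, x=0.05, f0=1.0, rho=0.4)
        mu0 = (base["rho"] * (base["b1"] - 0.5 * base["sigma1"]**2 * 0.6)
               + base["f0"] * base["x"]**base["rho"])
        p = GBMAllometricParams(mu0=mu0, **base)
        assert dominant_root(p).r0 == pytest.approx(0.0, abs=1e-14)
        assert reproduction_number(p) == pytest.approx(1.0, rel=1e-12)

    def test_sign_agreement(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = random_gbm_params(rng)
            if convergence_abscissa(p) >= 0:
                continue
            r0 = dominant_root(p).r0
            assert math.copysign(1, reproduction_number(p) - 1) == math.copysign(1, r0) \
                or abs(r0) < 1e-12


class TestEigenfunction:
    def test_size_integral_is_discounted_survival(self, fig2):
        r0 = dominant_root(fig2).r0
        for a in (0.5, 1.0, 3.0):
            z = np.linspace(math.log(fig2.x) - 8, math.log(fig2.x) + 8, 4001)
            y = np.exp(z)
            integral = np.trapezoid(eigenfunction_w(a, y, r0, fig2) * y, z)
            assert integral == pytest.approx(
                math.exp(-(fig2.mu0 + r0) * a), rel=1e-6
            )

    def test_median_size_matches_simulated_gbm_quantile(self, fig2):
        a = 2.0
        median = fig2.x * math.exp((fig2.b1 - fig2.sigma1**2 / 2) * a)
        rng = np.random.default_rng(5)
        paths = fig2.x * np.exp(
            (fig2.b1 - fig2.sigma1**2 / 2) * a
            + fig2.sigma1 * math.sqrt(a) * rng.standard_normal(200_000)
        )
        assert np.median(paths) == pytest.approx(median, rel=0.01)
        # the density integrates to half the discount below the median
        r0 = dominant_root(fig2).r0
        z = np.linspace(math.log(fig2.x) - 8, math.log(median), 4001)
        y = np.exp(z)
        below = np.trapezoid(eigenfunction_w(a, y, r0, fig2) * y, z)
        assert below == pytest.approx(0.5 * math.exp(-(fig2.mu0 + r0) * a), rel=1e-5)

    def test_nonnegative_on_random_draws(self, fig2):
        rng = np.random.default_rng(9)
        a = rng.uniform(0.01, 20.0, 200)
        y = rng.uniform(1e-4, 50.0, 200)
        assert np.all(eigenfunction_w(a, y, dominant_root(fig2).r0, fig2) >= 0.0)

    def test_invalid_inputs(self, fig2):
        with pytest.raises(ParameterError):
            eigenfunction_w(0.0, 0.01, 0.2, fig2)
        with pytest.raises(DegenerateInputError):
            eigenfunction_w(1.0, 0.01, 0.2, fig2.with_sigma1(0.0))


class TestReproductiveValue:
    def test_power_law(self, fig2):
        assert reproductive_value(fig2.x, fig2) == pytest.approx(
            fig2.f0 * fig2.x**fig2.rho
        )
        y = 0.37
        assert reproductive_value(2 * y, fig2) / reproductive_value(y, fig2) == \
            pytest.approx(2**fig2.rho)

    def test_increasing_and_concave(self, fig2):
        y = np.linspace(0.01, 10.0, 300)
        v = reproductive_value(y, fig2)
        assert np.all(np.diff(v) > 0)
        assert np.all(np.diff(v, 2) < 0)


class TestPairing:
    def test_dominant_pairing_is_one(self, fig2):
        assert eigenpair(fig2).pairing == pytest.approx(1.0, abs=1e-8)

    def test_normalization_across_random_parameters(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            p = random_gbm_params(rng)
            assert eigenpair(p).pairing == pytest.approx(1.0, abs=1e-6)

    def test_discounted_pairing_below_one(self, fig2):
        r0 = dominant_root(fig2).r0
        w_up = lambda a, y: eigenfunction_w(a, y, r0 + 0.1, fig2)
        v0 = lambda a, y: reproductive_value(y, fig2)
        val = pairing(v0, w_up, fig2)
        # closed-form reduction: f0 x^rho / (f0 x^rho + 0.1)
        fb = fig2.f0 * fig2.x**fig2.rho
        assert val == pytest.approx(fb / (fb + 0.1), rel=1e-7)
        assert val < 1.0

    def test_zero_function(self, fig2):
        assert pairing(lambda a, y: 0.0 * y, lambda a, y: 0.0 * y, fig2) == 0.0


class TestFeynmanKac:
    def test_deterministic_limit_matches_quadrature(self):
        p = GBMAllometricParams(b1=0.2, sigma1=0.0, x=0.05, mu0=0.2, f0=1.0, rho=0.4)
        r = 0.3
        est = feynman_kac_value_mc(0.05, r, p)
        closed = p.f0 * 0.05**p.rho / (r + p.mu0 - p.rho * p.b1)
        assert est.stderr == 0.0
        assert est.mean == pytest.approx(closed, rel=1e-5)

    def test_characteristic_identity_at_root(self, fig2):
        r0 = dominant_root(fig2).r0
        est = feynman_kac_value_mc(fig2.x, r0, fig2, n_paths=4000, seed=42)
        lo, hi = est.ci95
        assert lo <= 1.0 <= hi

    def test_seed_reproducibility(self, fig2):
        a = feynman_kac_value_mc(0.05, 0.4, fig2, n_paths=500, seed=7)
        b = feynman_kac_value_mc(0.05, 0.4, fig2, n_paths=500, seed=7)
        assert a.mean == b.mean and a.stderr == b.stderr

    def test_divergent_discount_rejected(self, fig2):
        with pytest.raises(DivergenceError):
            feynman_kac_value_mc(0.05, convergence_abscissa(fig2) - 0.01, fig2)

    def test_ci_coverage_of_closed_form(self, fig2):
        # 95% CI should cover the closed form in >= 93% of repeated runs
        r = 0.35
        closed = fig2.f0 * fig2.x**fig2.rho / (r - convergence_abscissa(fig2))
        hits = 0
        n_runs = 60
        for seed in range(n_runs):
            est = feynman_kac_value_mc(fig2.x, r, fig2, n_paths=400,
                                       seed=seed, dt=0.02)
            lo, hi = est.ci95
            hits += lo <= closed <= hi
        assert hits / n_runs >= 0.90


def test_single_root_from_many_brackets(fig2):
    """Root finding started from spread-out brackets always lands on r0."""
    from scipy.optimize import brentq

    pole = convergence_abscissa(fig2)
    r0 = dominant_root(fig2).r0
    rng = np.random.default_rng(2)
    for _ in range(20):
        lo = pole + 10 ** rng.uniform(-8, -2)
        hi = r0 + 10 ** rng.uniform(-2, 2)
        root = brentq(lambda r: psi(r, fig2) - 1.0, lo, hi, xtol=1e-14)
        assert root == pytest.approx(r0, abs=1e-9)
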