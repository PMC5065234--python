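"""Expectation integrals, optimal decoding weights, MSE routes, SNR."""

import numpy as np
import pytest

from effcode.metrics import (
    cross_expectation,
    gaussian_expectations,
    mse,
    mse_monte_carlo,
    optimal_weights,
    snr,
)
from effcode.metrics import mse_optimal_identity
from effcode.model import CircuitParams, Nonlinearity, X_GRID, rescale_nonlinearity
from effcode.single import ramp_expectations

CONST_ONE = Nonlinearity.tabulated(X_GRID, np.ones(X_GRID.size))
CONST_HALF = Nonlinearity.tabulated(X_GRID, np.full(X_GRID.size, 0.5))


class TestGaussianExpectations:
    def test_constant_function(self):
        e = gaussian_expectations(CONST_ONE)
        assert e.mean_f == pytest.approx(1.0, abs=1e-8)
        assert e.y_f == pytest.approx(0.0, abs=1e-8)
        assert e.f_sq == pytest.approx(1.0, abs=1e-8)

    def test_unit_ramp_closed_form(self):
        # <f> = phi(0) - phi(1) + 1 - Phi(1), <y f> = Phi(1) - Phi(0)
        e = gaussian_expectations(Nonlinearity.ramp(0.0, 1.0))
        assert e.mean_f == pytest.approx(0.31563, abs=1e-5)
        assert e.y_f == pytest.approx(0.34134, abs=1e-5)

    def test_off_ramp_mirrors_expectations(self):
        from effcode.model import Polarity

        on = gaussian_expectations(Nonlinearity.ramp(-0.4, 1.2))
        off = gaussian_expectations(Nonlinearity.ramp(-0.4, 1.2, polarity=Polarity.OFF))
        assert off.mean_f == pytest.approx(on.mean_f)
        assert off.y_f == pytest.approx(-on.y_f)
        assert off.f_sq == pytest.approx(on.f_sq)

    def test_quadrature_accurate_on_smooth_functions(self):
        from scipy.integrate import quad
        from scipy.special import expit
        from scipy.stats import norm as _norm

        e = gaussian_expectations(Nonlinearity.logistic(nu=2.0, phi=0.3))
        ref = quad(lambda y: expit(2.0 * (y - 0.3)) * _norm.pdf(y), -9, 9)[0]
        assert e.mean_f == pytest.approx(ref, abs=1e-8)

    def test_tabulated_ramp_quadrature_within_working_tolerance(self):
        # kinked tabulated curves are resolved to ~1e-3 by the fixed rule;
        # exact ramps go through the closed form instead
        from effcode.model import X_GRID

        for x0, x1 in [(-1.5, 0.5), (0.2, 3.0)]:
            m, yf, fsq = ramp_expectations(x0, x1)
            tab = Nonlinearity.tabulated(X_GRID, Nonlinearity.ramp(x0, x1)(X_GRID))
            e = gaussian_expectations(tab)
            assert e.mean_f == pytest.approx(m, abs=2e-3)
            assert e.y_f == pytest.approx(yf, abs=2e-3)
            assert e.f_sq == pytest.approx(fsq, abs=2e-3)

    def test_jensen_inequality(self):
        e = gaussian_expectations(Nonlinearity.logistic(nu=2.0, phi=0.3))
        assert e.f_sq >= e.mean_f**2

    def test_cross_at_zero_correlation_factorises(self):
        f1 = Nonlinearity.ramp(-1.0, 0.5)
        f2 = Nonlinearity.logistic(nu=3.0, phi=-0.2)
        e = gaussian_expectations(f1, f2, rho=0.0)
        # cross goes through quadrature (kink-limited to ~1e-4)
        assert e.cross == pytest.approx(e.mean_f * e.mean_f2, abs=1e-3)

    def test_cross_at_unit_correlation_is_shared_argument(self):
        f = Nonlinearity.logistic(nu=2.0, phi=0.0)
        e = gaussian_expectations(f, f, rho=1.0)
        assert e.cross == pytest.approx(e.f_sq, abs=1e-8)

    def test_cross_monotone_in_rho_for_two_increasing_functions(self):
        f1 = Nonlinearity.ramp(-1.0, 1.0)
        f2 = Nonlinearity.logistic(nu=2.0, phi=0.2)
        vals = [cross_expectation(f1, f2, r) for r in np.linspace(-1, 1, 11)]
        assert np.all(np.diff(vals) > 0)


class TestOptimalWeights:
    def test_constant_nonlinearity_gives_zero_weight(self):
        p = CircuitParams(sigma_up=0.2, kappa=0.0, sigma_down=0.5)
        w = optimal_weights(p, CONST_HALF)
        assert w.D[0] == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_stage_reduction(self):
        # kappa = 0, sigma_down = 0: D = <s f> / var f
        p = CircuitParams(sigma_up=0.7, kappa=0.0, sigma_down=0.0)
        f = Nonlinearity.ramp(-1.0, 1.0)
        ft = rescale_nonlinearity(f, p, "to_rescaled")
        e = gaussian_expectations(ft)
        expected = (p.sigma_s**2 / p.input_scale * e.y_f) / e.var_f
        assert optimal_weights(p, f).D[0] == pytest.approx(expected, rel=1e-10)

    def test_symmetric_pair_gets_equal_weights(self):
        p = CircuitParams(sigma_up=1.0, kappa=0.2, sigma_down=0.3, rho_up=0.5, n_pathways=2)
        f = Nonlinearity.ramp(-1.0, 1.0)
        w = optimal_weights(p, (f, f))
        assert w.D[0] == pytest.approx(w.D[1], rel=1e-10)

    def test_optimal_d0_cancels_mean_response(self):
        p = CircuitParams(sigma_up=0.5, kappa=0.1, sigma_down=0.2)
        f = Nonlinearity.logistic(nu=2.0, phi=0.5)
        w = optimal_weights(p, f)
        ft = rescale_nonlinearity(f, p, "to_rescaled")
        e = gaussian_expectations(ft)
        assert w.D0 == pytest.approx(-w.D[0] * e.mean_f, rel=1e-10)


class TestMse:
    def test_constant_f_decoder_predicts_the_mean(self):
        p = CircuitParams(sigma_s=1.3, sigma_up=0.4, kappa=0.1, sigma_down=0.2)
        assert mse(p, CONST_HALF) == pytest.approx(p.sigma_s**2, abs=1e-6)

    def test_closed_form_matches_monte_carlo(self):
        p = CircuitParams(sigma_up=0.5, kappa=0.25, sigma_down=0.3)
        f = Nonlinearity.logistic(nu=1.5, phi=0.1)
        cf = mse(p, f)
        mc, sem = mse_monte_carlo(p, f, n=200_000, n_reps=4, seed=7)
        assert mc == pytest.approx(cf, abs=4 * sem)

    def test_closed_form_matches_monte_carlo_two_pathways(self):
        p = CircuitParams(
            sigma_up=1.0, kappa=0.2, sigma_down=0.3, rho_up=0.4, rho_down=0.3, n_pathways=2
        )
        pair = (Nonlinearity.ramp(-1.5, 0.5), Nonlinearity.ramp(-0.5, 1.5))
        cf = mse(p, pair)
        mc, sem = mse_monte_carlo(p, pair, n=200_000, n_reps=4, seed=8)
        assert mc == pytest.approx(cf, abs=4 * sem)

    def test_reduced_identity_at_optimal_weights(self):
        p = CircuitParams(sigma_up=0.8, kappa=0.3, sigma_down=0.2)
        f = Nonlinearity.ramp(-1.0, 1.2)
        assert mse(p, f) == pytest.approx(mse_optimal_identity(p, f), abs=1e-10)

    def test_convexity_in_weights(self):
        from effcode.model import DecodingWeights

        p = CircuitParams(sigma_up=0.5, kappa=0.2, sigma_down=0.3)
        f = Nonlinearity.ramp(-1.0, 1.0)
        w = optimal_weights(p, f)
        at_opt = mse(p, f, w)
        for eps in (-0.1, 0.05, 0.2):
            perturbed = DecodingWeights(D=(w.D[0] + eps,), D0=w.D0)
            assert mse(p, f, perturbed) >= at_opt


class TestSnr:
    def test_constant_f_gives_zero(self):
        p = CircuitParams(sigma_up=0.3, kappa=0.1, sigma_down=0.2)
        assert snr(p, CONST_HALF) == pytest.approx(0.0, abs=1e-8)

    def test_no_upstream_noise_reduction(self):
        # sigma_up = 0: SNR = var f / (kappa <f> + sigma_down^2)
        p = CircuitParams(sigma_up=0.0, kappa=0.2, sigma_down=0.3)
        f = Nonlinearity.ramp(-1.0, 1.0)
        e = gaussian_expectations(f)
        expected = e.var_f / (p.kappa * e.mean_f + p.sigma_down**2)
        assert snr(p, f) == pytest.approx(expected, rel=1e-3)

    def test_invariant_under_rescaling(self):
        # SNR depends only on the rescaled shape and the signal fraction
        p1 = CircuitParams(sigma_s=1.0, sigma_up=0.5, kappa=0.2, sigma_down=0.3)
        p2 = CircuitParams(sigma_s=2.0, sigma_up=1.0, kappa=0.2, sigma_down=0.3)
        f1 = Nonlinearity.ramp(-1.0, 1.0)
        f2 = Nonlinearity.ramp(-2.0, 2.0)  # same rescaled shape under p2
        f2 = Nonlinearity.ramp(f1.z0 * p2.input_scale / p1.input_scale,
                               f1.z1 * p2.input_scale / p1.input_scale)
        assert snr(p1, f1) == pytest.approx(snr(p2, f2), rel=1e-8)

    def test_two_pathway_circuit_rejected(self):
        p = CircuitParams(n_pathways=2)
        with pytest.raises(ValueError):
            snr(p, CONST_HALF)
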