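"""Data model: nonlinearity evaluation, rescaling, effective correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effcode.model import (
    CircuitParams,
    Nonlinearity,
    Polarity,
    X_GRID,
    effective_correlation,
    rescale_nonlinearity,
    rho_up_for_effective,
)


class TestEvaluation:
    @pytest.mark.parametrize(
        "z, expected",
        [(0.5, 0.5), (-3.0, 0.0), (7.0, 1.0), (0.0, 0.0), (1.0, 1.0)],
    )
    def test_ramp_values(self, z, expected):
        f = Nonlinearity.ramp(0.0, 1.0)
        assert f(z) == pytest.approx(expected)

    def test_logistic_midpoint(self):
        assert Nonlinearity.logistic(nu=4.0, phi=0.2)(0.2) == pytest.approx(0.5)

    def test_off_polarity_is_mirror(self):
        on = Nonlinearity.ramp(-0.5, 1.5)
        off = Nonlinearity.ramp(-0.5, 1.5, polarity=Polarity.OFF)
        z = np.linspace(-4, 4, 101)
        np.testing.assert_allclose(off(z), on(-z))

    def test_tabulated_holds_boundary_outside_grid(self):
        f = Nonlinearity.tabulated(X_GRID, np.clip(0.5 + X_GRID / 4, 0, 1))
        assert f(-100.0) == f(X_GRID[0])
        assert f(100.0) == f(X_GRID[-1])

    def test_tabulated_interpolates_smoothly(self):
        # a cubic spline through a smooth curve reproduces it off-grid
        f = Nonlinearity.tabulated(X_GRID, 1 / (1 + np.exp(-X_GRID)))
        z = np.linspace(-5, 5, 501)
        np.testing.assert_allclose(f(z), 1 / (1 + np.exp(-z)), atol=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        z=st.floats(-1e6, 1e6),
        rep=st.sampled_from(["ramp", "logistic", "tabulated"]),
        pol=st.sampled_from(list(Polarity)),
    )
    def test_output_always_in_unit_interval(self, z, rep, pol):
        if rep == "ramp":
            f = Nonlinearity.ramp(-1.0, 2.0, polarity=pol)
        elif rep == "logistic":
            f = Nonlinearity.logistic(nu=3.0, phi=0.5, polarity=pol)
        else:
            f = Nonlinearity.tabulated(X_GRID, np.clip(0.5 + np.sin(X_GRID), 0, 1), polarity=pol)
        assert 0.0 <= f(z) <= 1.0

    def test_invalid_construction_rejected(self):
        with pytest.raises(ValueError):
            Nonlinearity.ramp(1.0, 1.0)
        with pytest.raises(ValueError):
            Nonlinearity.tabulated([0, 1, 1, 2], [0, 0.5, 0.6, 1])


class TestEffectiveCorrelation:
    def test_printed_sweep_recipe_point(self):
        p = CircuitParams(sigma_s=1, sigma_up=2, rho_up=0.0625, n_pathways=2)
        assert effective_correlation(p) == pytest.approx(0.25)

    def test_no_upstream_noise_gives_unity(self):
        p = CircuitParams(sigma_s=1, sigma_up=0, rho_up=-0.7, n_pathways=2)
        assert effective_correlation(p) == pytest.approx(1.0)

    def test_zero_requires_anticorrelated_large_noise(self):
        p = CircuitParams(sigma_s=1, sigma_up=2, rho_up=-0.25, n_pathways=2)
        assert effective_correlation(p) == pytest.approx(0.0)

    def test_monotone_in_rho_up_and_value_at_zero(self):
        vals = [
            effective_correlation(
                CircuitParams(sigma_s=1, sigma_up=1.5, rho_up=r, n_pathways=2)
            )
            for r in np.linspace(-1, 1, 9)
        ]
        assert np.all(np.diff(vals) > 0)
        at_zero = effective_correlation(
            CircuitParams(sigma_s=1, sigma_up=1.5, rho_up=0.0, n_pathways=2)
        )
        assert at_zero == pytest.approx(1 / (1 + 1.5**2))

    def test_single_pathway_rejected(self):
        with pytest.raises(ValueError):
            effective_correlation(CircuitParams(n_pathways=1))

    def test_inverse_mapping_round_trip(self):
        for re in (0.0, 0.25, 0.5, 0.75, 1.0):
            ru = rho_up_for_effective(re, 1.0, 2.0)
            p = CircuitParams(sigma_s=1, sigma_up=2, rho_up=ru, n_pathways=2)
            assert effective_correlation(p) == pytest.approx(re, abs=1e-12)


class TestRescaling:
    def test_definition_on_kinks(self):
        p = CircuitParams(sigma_s=1.0, sigma_up=2.0)
        scale = np.sqrt(5.0)
        f = Nonlinearity.ramp(scale * -0.7, scale * 1.2)
        g = rescale_nonlinearity(f, p, "to_rescaled")
        assert g.z0 == pytest.approx(-0.7)
        assert g.z1 == pytest.approx(1.2)

    def test_identity_when_no_upstream_noise(self):
        p = CircuitParams(sigma_s=1.0, sigma_up=0.0)
        f = Nonlinearity.logistic(nu=3.0, phi=0.4)
        g = rescale_nonlinearity(f, p, "to_rescaled")
        assert (g.nu, g.phi) == (f.nu, f.phi)

    @pytest.mark.parametrize("rep", ["ramp", "logistic", "tabulated"])
    def test_round_trip_is_identity(self, rep):
        p = CircuitParams(sigma_s=0.8, sigma_up=1.7)
        if rep == "ramp":
            f = Nonlinearity.ramp(-1.3, 0.9)
        elif rep == "logistic":
            f = Nonlinearity.logistic(nu=2.5, phi=-0.3)
        else:
            f = Nonlinearity.tabulated(X_GRID, np.clip(0.5 + X_GRID / 3, 0, 1))
        g = rescale_nonlinearity(rescale_nonlinearity(f, p, "to_rescaled"), p, "to_raw")
        z = np.linspace(-4, 4, 97)
        np.testing.assert_allclose(g(z), f(z), atol=1e-12)

    def test_rescaled_evaluation_matches_raw(self):
        # f~(x) must equal f(scale * x) pointwise
        p = CircuitParams(sigma_s=1.0, sigma_up=2.0)
        f = Nonlinearity.logistic(nu=1.7, phi=0.6)
        g = rescale_nonlinearity(f, p, "to_rescaled")
        x = np.linspace(-3, 3, 61)
        np.testing.assert_allclose(g(x), f(np.sqrt(5) * x), atol=1e-12)


class TestSerialization:
    @pytest.mark.parametrize("rep", ["ramp", "logistic", "tabulated"])
    def test_json_round_trip(self, rep, tmp_path):
        if rep == "ramp":
            f = Nonlinearity.ramp(-1.0, 2.0, polarity=Polarity.OFF)
        elif rep == "logistic":
            f = Nonlinearity.logistic(nu=2.0, phi=0.1)
        else:
            f = Nonlinearity.tabulated(X_GRID, np.clip(0.5 + X_GRID / 5, 0, 1))
        path = tmp_path / "f.json"
        f.to_json(path)
        g = Nonlinearity.from_json(path)
        z = np.linspace(-4, 4, 33)
        np.testing.assert_allclose(g(z), f(z), atol=1e-12)

    def test_two_column_table_round_trip(self, tmp_path):
        f = Nonlinearity.logistic(nu=2.0, phi=0.3)
        path = tmp_path / "f.txt"
        f.to_table(path)
        g = Nonlinearity.from_table(path)
        z = np.linspace(-5, 5, 41)
        np.testing.assert_allclose(g(z), f(z), atol=1e-4)

    def test_params_dict_round_trip(self):
        p = CircuitParams(sigma_s=0.9, sigma_up=1.1, kappa=0.3, sigma_down=0.2, n_pathways=2)
        assert CircuitParams.from_dict(p.to_dict()) == p

    @pytest.mark.parametrize(
        "bad",
        [
            {"sigma_s": -1.0},
            {"sigma_up": -0.1},
            {"rho_up": 2.0, "n_pathways": 2},
            {"n_pathways": 3},
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            CircuitParams(**bad)
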