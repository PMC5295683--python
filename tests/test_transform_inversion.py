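"""Transform inversion: the Lorentzian product, its quadrature and FFT
inverses, moments, skewness and the limit TMRCA density."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coaltimes import (
    PopulationHistory,
    density_moments,
    etmrca_stable,
    invert_density_fft,
    invert_density_quadrature,
    marginal_density_partial_fraction,
    skewness_profile,
    tmrca_limit_density,
    upsilon_product,
)
from coaltimes.transform_inversion import (
    DensityGrid,
    default_time_grid,
    hypoexponential_moments,
)


class TestUpsilonProduct:
    def test_unit_at_zero_frequency(self):
        assert upsilon_product(100, 2, 0.0) == pytest.approx(1.0)

    def test_single_factor_is_lorentzian(self):
        n = 7
        lam = n * (n - 1) / 2.0
        w = 3.7
        assert upsilon_product(n, n, w) == pytest.approx(lam / (1j * w + lam))

    def test_modulus_decreasing_in_frequency(self):
        w = np.linspace(0.0, 500.0, 200)
        mod = np.abs(upsilon_product(100, 2, w))
        assert np.all(np.diff(mod) < 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(w=st.floats(min_value=1e-3, max_value=1e6))
    def test_conjugate_symmetry_and_bounded_modulus(self, w):
        p = upsilon_product(40, 3, w)
        m = upsilon_product(40, 3, -w)
        assert m == pytest.approx(np.conj(p), rel=1e-12)
        assert abs(p) <= 1.0 + 1e-12

    def test_no_underflow_for_long_products(self):
        # 10^4 factors in log space: finite tiny modulus, no warnings
        val = upsilon_product(10000, 2, 50.0)
        assert np.isfinite(val.real) and np.isfinite(val.imag)


class TestQuadratureInversion:
    def test_pair_constant_is_unit_exponential(self, unit_constant):
        t = np.array([0.1, 1.0, 3.0])
        grid = invert_density_quadrature(2, 2, unit_constant, t)
        assert grid.values == pytest.approx(np.exp(-t), abs=1e-6)

    def test_ten_sample_tmrca_mean(self, unit_constant):
        grid = invert_density_quadrature(10, 2, unit_constant)
        mean, _, _ = density_moments(grid)
        assert mean == pytest.approx(1.8, abs=1e-4)

    def test_table_scale_growth_cell(self, mtdna_model):
        # n=800, k=6 under r=0.001, N0=2e6: mean ~6647.9, sd ~250.6
        grid = invert_density_quadrature(800, 6, mtdna_model)
        mean, sd, _ = density_moments(grid)
        assert mean == pytest.approx(6647.928, abs=0.05)
        assert sd == pytest.approx(250.612, abs=0.05)

    def test_k_equals_n_shortcut(self, growth_model):
        from coaltimes import first_coalescence_density

        grid = invert_density_quadrature(5, 5, growth_model)
        assert grid.values == pytest.approx(
            first_coalescence_density(growth_model, 5, grid.times), rel=1e-12
        )

    def test_agrees_with_stable_expectations(self):
        for n, model in [
            (10, PopulationHistory.constant(1000.0)),
            (100, PopulationHistory.exponential(1000.0, rho=10.0)),
            (800, PopulationHistory.exponential(2e6, r=0.001)),
        ]:
            grid = invert_density_quadrature(n, 2, model)
            mean, _, _ = density_moments(grid)
            assert mean == pytest.approx(etmrca_stable(model, n), rel=1e-4)


class TestPartialFractionDensity:
    def test_three_sample_closed_form(self, unit_constant):
        t = np.array([1.0])
        grid = marginal_density_partial_fraction(3, 2, unit_constant, t)
        assert grid.values[0] == pytest.approx(1.5 * (np.exp(-1) - np.exp(-3)))

    def test_normalization(self, growth_model):
        grid = marginal_density_partial_fraction(20, 5, growth_model)
        assert grid.integral() == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("rho", [0.0, 10.0])
    @pytest.mark.parametrize("k", [2, 10, 20])
    def test_cross_method_with_quadrature(self, k, rho):
        n = 20
        model = (
            PopulationHistory.constant(1000.0)
            if rho == 0.0
            else PopulationHistory.exponential(1000.0, rho=rho)
        )
        times = default_time_grid(n, k, model, n_points=200)
        q = invert_density_quadrature(n, k, model, times)
        p = marginal_density_partial_fraction(n, k, model, times)
        peak = p.values.max()
        mask = p.values > 1e-3 * peak
        assert q.values[mask] == pytest.approx(p.values[mask], rel=1e-5)

    def test_large_n_guarded(self, unit_constant):
        with pytest.raises(ValueError, match="unstable"):
            marginal_density_partial_fraction(60, 2, unit_constant)


class TestFFTInversion:
    def test_agrees_with_quadrature_growth(self):
        model = PopulationHistory.exponential(1000.0, rho=10.0)
        fgrid = invert_density_fft(100, 2, model, grid_points=2048)
        interior = slice(200, fgrid.times.size - 400, (fgrid.times.size - 600) // 20)
        t_check = fgrid.times[interior]
        qgrid = invert_density_quadrature(100, 2, model, t_check)
        assert fgrid.values[interior] == pytest.approx(qgrid.values, rel=1e-3)

    def test_constant_moment_accuracy_500_points(self):
        # moment relative error <= 1e-4 on a 500-point grid, constant size
        n, k = 10000, 2
        grid = invert_density_fft(n, k, PopulationHistory.constant(1.0), grid_points=500)
        m1, sd, _ = hypoexponential_moments(n, k)
        mean, sdg, _ = density_moments(grid)
        assert mean == pytest.approx(m1, rel=1e-4)
        assert sdg == pytest.approx(sd, rel=1e-4)

    def test_growth_moment_accuracy_1000_points(self):
        # transformed-time moments within 1e-3 on a 1000-point tau grid
        n, k = 10000, 2
        model = PopulationHistory.exponential(1e4, rho=1e4)
        grid = invert_density_fft(n, k, model, grid_points=1000)
        mean, _, _ = density_moments(grid)
        ref = invert_density_quadrature(n, k, model)
        mean_ref, _, _ = density_moments(ref)
        assert mean == pytest.approx(mean_ref, rel=1e-3)


class TestDensityMoments:
    def test_unit_exponential(self, unit_constant):
        t = np.linspace(0.0, 40.0, 8000)
        grid = DensityGrid(t, np.exp(-t), unit_constant, 2, 2, "quadrature")
        mean, sd, skew = density_moments(grid)
        assert (mean, sd) == pytest.approx((1.0, 1.0), abs=1e-3)
        assert skew == pytest.approx(2.0, abs=1e-3)

    def test_hypoexponential_closed_forms(self, unit_constant):
        n, k = 30, 10
        grid = invert_density_quadrature(n, k, unit_constant)
        m1, sd, skew = hypoexponential_moments(n, k)
        got = density_moments(grid)
        assert got == pytest.approx((m1, sd, skew), rel=1e-4)

    def test_rejects_unnormalized_grid(self, unit_constant):
        t = np.linspace(0.0, 5.0, 100)
        grid = DensityGrid(t, np.exp(-t) * 3.0, unit_constant, 2, 2, "quadrature")
        with pytest.raises(ValueError, match="integrates"):
            density_moments(grid)


class TestSkewness:
    def test_bottom_of_tree_is_exponential(self, constant_model):
        gamma = skewness_profile(50, constant_model, [50])
        assert gamma[0] == pytest.approx(2.0, abs=1e-3)

    def test_all_positive_constant(self, constant_model):
        gamma = skewness_profile(100, constant_model, [2, 25, 50, 75, 95])
        assert np.all(gamma > 0)

    def test_decreasing_with_growth(self):
        g0 = skewness_profile(100, PopulationHistory.constant(1000.0), [2])
        g100 = skewness_profile(
            100, PopulationHistory.exponential(1000.0, rho=100.0), [2]
        )
        assert g100[0] < g0[0]


class TestLimitDensity:
    def test_normalization_and_mean(self, constant_model):
        grid = tmrca_limit_density(constant_model)
        assert grid.integral() == pytest.approx(1.0, abs=1e-4)
        mean, _, _ = density_moments(grid)
        N0 = constant_model.N0
        assert mean == pytest.approx(2.0 * N0, abs=1e-3 * N0)

    @pytest.mark.parametrize("rho", [1.0, 10.0])
    def test_convergence_ordering(self, rho):
        # the n=100 TMRCA density is closer to the limit than the n=10 one
        model = PopulationHistory.exponential(1000.0, rho=rho)
        tau = np.linspace(1e-3, 8.0, 400)
        from coaltimes import inverse_time_scale

        t = inverse_time_scale(model, tau)
        limit = tmrca_limit_density(model, t)
        d10 = invert_density_quadrature(10, 2, model, t)
        d100 = invert_density_quadrature(100, 2, model, t)
        gap10 = np.max(np.abs(d10.values - limit.values))
        gap100 = np.max(np.abs(d100.values - limit.values))
        assert gap100 < gap10
        assert gap100 < 0.2 * np.max(limit.values)

    def test_scenario_covariance(self):
        # limit density under growth equals the constant-size limit pushed
        # through the time-scale change with the 1/N(t) Jacobian
        model = PopulationHistory.exponential(1000.0, rho=10.0)
        tau = np.linspace(0.0, 10.0, 300)
        from coaltimes import inverse_time_scale, population_size

        t = inverse_time_scale(model, tau)
        direct = tmrca_limit_density(model, t)
        base = tmrca_limit_density(PopulationHistory.constant(1.0), tau[1:])
        pushed = base.values / population_size(model, t[1:])
        assert direct.values[1:] == pytest.approx(pushed, rel=1e-6, abs=1e-12)
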