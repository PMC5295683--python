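"""Population histories, the time-scale change and first-coalescence laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from coaltimes import (
    PopulationHistory,
    exp_scaled_e1,
    expected_first_coalescence_time,
    first_coalescence_density,
    inverse_time_scale,
    population_size,
    time_scale,
)
from coaltimes.popmodels import first_coalescence_means

mpmath = pytest.importorskip("mpmath")


class TestPopulationSize:
    def test_constant_is_flat(self):
        m = PopulationHistory.constant(1000.0)
        assert population_size(m, 5.0) == 1000.0

    def test_exponential_r_zero_reduces_to_constant(self):
        m = PopulationHistory.exponential(1000.0, r=0.0)
        assert population_size(m, 7.0) == 1000.0

    def test_exponential_closed_form(self):
        m = PopulationHistory.exponential(1000.0, r=0.01)
        assert population_size(m, 100.0) == pytest.approx(1000.0 * np.exp(-1.0))

    def test_negative_time_rejected(self):
        m = PopulationHistory.constant(10.0)
        with pytest.raises(ValueError):
            population_size(m, -1.0)

    def test_nonpositive_general_size_rejected(self):
        m = PopulationHistory.general(lambda t: 100.0 - t)
        with pytest.raises(ValueError):
            population_size(m, 150.0)

    def test_rho_product_parameter(self):
        m = PopulationHistory.exponential(1000.0, r=0.01)
        assert m.rho == pytest.approx(10.0)
        assert PopulationHistory.exponential(500.0, rho=10.0).r == pytest.approx(0.02)


class TestTimeScale:
    def test_constant(self):
        m = PopulationHistory.constant(2.0)
        assert time_scale(m, 3.0) == pytest.approx(1.5)

    def test_tiny_r_degenerates_to_constant(self):
        m = PopulationHistory.exponential(1000.0, r=1e-12)
        assert time_scale(m, 100.0) == pytest.approx(0.1, rel=1e-9)

    def test_exponential_matches_quadrature(self):
        m = PopulationHistory.exponential(1000.0, r=0.01)
        expected = (np.e - 1.0) / 10.0
        assert time_scale(m, 100.0) == pytest.approx(expected, rel=1e-12)
        num, _ = quad(lambda s: 1.0 / population_size(m, s), 0.0, 100.0)
        assert time_scale(m, 100.0) == pytest.approx(num, rel=1e-10)

    def test_inverse_constant(self):
        m = PopulationHistory.constant(2.0)
        assert inverse_time_scale(m, 1.5) == pytest.approx(3.0)

    def test_inverse_at_zero(self):
        for m in (
            PopulationHistory.constant(5.0),
            PopulationHistory.exponential(5.0, r=0.1),
            PopulationHistory.general(lambda t: 5.0 + t),
        ):
            assert inverse_time_scale(m, 0.0) == 0.0

    def test_inverse_exponential(self):
        m = PopulationHistory.exponential(1000.0, r=0.01)
        assert inverse_time_scale(m, (np.e - 1.0) / 10.0) == pytest.approx(100.0, rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(t=st.floats(min_value=1e-3, max_value=1e4))
    def test_round_trip_all_kinds(self, t):
        models = [
            PopulationHistory.constant(137.0),
            PopulationHistory.exponential(1000.0, r=0.005),
            PopulationHistory.general(lambda s: 200.0 + 50.0 * np.sin(s / 40.0) ** 2),
        ]
        for m in models:
            assert inverse_time_scale(m, time_scale(m, t)) == pytest.approx(t, rel=1e-10)

    def test_strictly_increasing(self):
        m = PopulationHistory.general(lambda s: 100.0 + s)
        ts = np.linspace(0.0, 500.0, 40)
        taus = time_scale(m, ts)
        assert np.all(np.diff(taus) > 0)


class TestFirstCoalescenceDensity:
    def test_pair_constant_unit_is_unit_exponential(self):
        m = PopulationHistory.constant(1.0)
        t = np.array([0.1, 1.0, 3.0])
        assert first_coalescence_density(m, 2, t) == pytest.approx(np.exp(-t))

    def test_r_zero_equals_constant(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0.0, 5000.0, 10)
        mc = PopulationHistory.constant(1000.0)
        me = PopulationHistory.exponential(1000.0, r=0.0)
        assert first_coalescence_density(me, 5, t) == pytest.approx(
            first_coalescence_density(mc, 5, t), rel=1e-14
        )

    @pytest.mark.parametrize("j", [2, 10, 100, 1000])
    @pytest.mark.parametrize("rho", [0.0, 1.0, 10.0, 1e4])
    def test_normalization(self, j, rho):
        N0 = 1000.0
        m = (
            PopulationHistory.constant(N0)
            if rho == 0.0
            else PopulationHistory.exponential(N0, rho=rho)
        )
        # integrate on the tau scale via substitution-free quadrature in t
        lam = j * (j - 1) / 2.0
        upper = inverse_time_scale(m, 40.0 / lam)
        val, _ = quad(
            lambda t: first_coalescence_density(m, j, t), 0.0, upper, limit=500
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_fewer_than_two_lineages_rejected(self):
        with pytest.raises(ValueError):
            first_coalescence_density(PopulationHistory.constant(1.0), 1, 0.5)


class TestExpectedFirstCoalescence:
    def test_constant_pair(self):
        m = PopulationHistory.constant(500.0)
        assert expected_first_coalescence_time(m, 2) == pytest.approx(500.0)

    def test_r_to_zero_limit(self):
        m = PopulationHistory.exponential(500.0, r=1e-14)
        assert expected_first_coalescence_time(m, 4) == pytest.approx(500.0 / 6.0, abs=1e-6)

    def test_exponential_vs_quadrature_oracle(self):
        N0, r, j = 2e6, 0.001, 3
        m = PopulationHistory.exponential(N0, r=r)
        lam = 3.0
        num, _ = quad(
            lambda t: t * first_coalescence_density(m, j, t),
            0.0,
            inverse_time_scale(m, 50.0 / lam),
            limit=1000,
        )
        assert expected_first_coalescence_time(m, j) == pytest.approx(num, rel=1e-8)

    def test_general_history_vs_exponential(self):
        N0, r = 1000.0, 0.01
        me = PopulationHistory.exponential(N0, r=r)
        mg = PopulationHistory.general(lambda t: N0 * np.exp(-r * t))
        assert expected_first_coalescence_time(mg, 5) == pytest.approx(
            expected_first_coalescence_time(me, 5), rel=1e-8
        )

    def test_decreasing_in_j_and_rho(self):
        N0 = 1000.0
        m = PopulationHistory.exponential(N0, rho=10.0)
        e = first_coalescence_means(m, 50)
        assert np.all(np.diff(e) < 0)
        e_faster = first_coalescence_means(
            PopulationHistory.exponential(N0, rho=100.0), 50
        )
        assert np.all(e_faster < e)


class TestScaledExponentialIntegral:
    def test_matches_arbitrary_precision_oracle(self):
        mpmath.mp.dps = 40
        x = np.geomspace(1e-6, 1e8, 57)
        got = exp_scaled_e1(x)
        ref = np.array([float(mpmath.exp(xi) * mpmath.e1(xi)) for xi in x])
        assert np.max(np.abs(got / ref - 1.0)) < 1e-12

    def test_no_overflow_at_extreme_argument(self):
        v = exp_scaled_e1(1e8)
        assert np.isfinite(v) and 0 < v < 1e-7  # ~ 1/x for large x

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            exp_scaled_e1(0.0)
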