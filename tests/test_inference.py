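"""Goodness of fit, normality acceptance, validation intervals, power."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biopsim.inference import (
    PowerQuery,
    chi_square_gof,
    chi_square_normal_gof,
    normality_check,
    power_one_sample_t,
    sample_size_one_sample_t,
    validation_interval,
)
from biopsim.rng import NormalSpec, UniformSource, sample_normal
from biopsim.service_times import ANALYSIS_MODEL, sample_service_time


class TestChiSquareGof:
    def test_perfect_fit(self):
        res = chi_square_gof([4, 6, 10], [4, 6, 10])
        assert res.chi2 == 0.0
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_two_cells(self):
        res = chi_square_gof([10, 10], [5, 15])
        assert res.chi2 == pytest.approx(6.667, abs=1e-3)
        assert res.v == 1
        assert res.p == pytest.approx(0.0098, abs=2e-4)

    def test_degenerate_single_cell(self):
        with pytest.raises(ValueError):
            chi_square_gof([10], [10])

    @pytest.mark.parametrize("o,e", [([1, 2], [1, 2, 3]), ([1, 2], [0, 3]), ([1, 2], [-1, 4])])
    def test_invalid_inputs(self, o, e):
        with pytest.raises(ValueError):
            chi_square_gof(o, e)

    @settings(derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10**6), k=st.integers(2, 12))
    def test_matches_brute_force_summation(self, seed, k):
        rng = np.random.default_rng(seed)
        o = rng.integers(0, 50, size=k).astype(float)
        e = rng.uniform(0.5, 50, size=k)
        res = chi_square_gof(o, e)
        brute = 0.0
        for oi, ei in zip(o, e):
            brute += (oi - ei) ** 2 / ei
        assert abs(res.chi2 - brute) < 1e-12
        assert res.v == k - 1

    def test_binned_normal_gof_accepts_normal_sample(self):
        x = sample_normal(NormalSpec(10, 2), 2000, UniformSource(3))
        res = chi_square_normal_gof(x)
        assert res.k == 20
        assert (res.expected >= 5).all()
        assert res.p > 0.01


class TestNormalityCheck:
    def test_normal_sample_accepted_across_seeds(self):
        # Under H0 the acceptance rate is exactly 1 - alpha = 0.95, so allow
        # two binomial standard errors below it: 0.95 - 2*sqrt(.05*.95/60).
        n_seeds = 60
        accepted = sum(
            normality_check(sample_normal(NormalSpec(0, 1), 10**4, UniformSource(s))).accepted
            for s in range(n_seeds)
        )
        assert accepted >= 54

    def test_bimodal_sample_rejected(self):
        x = sample_service_time(ANALYSIS_MODEL, 10**4, UniformSource(4))
        assert not normality_check(x).accepted

    def test_constant_sample_is_an_error(self):
        with pytest.raises(ValueError):
            normality_check([5.0] * 20)

    def test_too_small(self):
        with pytest.raises(ValueError):
            normality_check([1, 2, 3])


class TestValidationInterval:
    def test_identical_series_interval_is_degenerate_at_zero(self):
        x = np.array([10.0, 12.0, 9.0, 14.0])
        res = validation_interval(x, x)
        assert res.interval == (0.0, 0.0)
        assert res.contains_zero

    def test_constant_shift_rejects_model(self):
        rng = np.random.default_rng(0)
        y = rng.normal(100, 5, size=30)
        res = validation_interval(y + 1000, y)
        assert not res.contains_zero
        assert res.interval[0] > 0

    def test_contains_zero_iff_bounds_straddle(self):
        rng = np.random.default_rng(1)
        y = rng.normal(100, 5, size=25)
        x = y + rng.normal(0, 5, size=25)
        res = validation_interval(x, y)
        lo, hi = res.interval
        assert res.contains_zero == (lo <= 0 <= hi)

    def test_width_shrinks_like_inverse_sqrt_nu(self):
        rng = np.random.default_rng(2)

        def width(nu):
            y = rng.normal(0, 1, size=nu)
            x = y + rng.normal(0, 1, size=nu)
            lo, hi = validation_interval(x, y).interval
            return hi - lo

        w_small = np.mean([width(40) for _ in range(30)])
        w_big = np.mean([width(160) for _ in range(30)])
        assert w_big == pytest.approx(w_small / 2, rel=0.25)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            validation_interval([1, 2, 3], [1, 2])


class TestPower:
    def test_minimal_sample_sizes_for_both_groups(self):
        assert sample_size_one_sample_t(PowerQuery(delta=3, sd=4.30)) == 29
        assert sample_size_one_sample_t(PowerQuery(delta=5, sd=6.001)) == 21

    def test_round_trip_power_at_boundary(self):
        q = PowerQuery(delta=3, sd=4.30)
        n = sample_size_one_sample_t(q)
        assert power_one_sample_t(n, q.delta, q.sd, q.alpha) >= q.power
        assert power_one_sample_t(n - 1, q.delta, q.sd, q.alpha) < q.power

    def test_monotone_in_effect_size(self):
        sizes = [
            sample_size_one_sample_t(PowerQuery(delta=d, sd=6.0))
            for d in (1.5, 3.0, 6.0, 12.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_agrees_with_statsmodels_solver(self):
        from statsmodels.stats.power import TTestPower

        effect = 3 / 4.30
        n_sm = TTestPower().solve_power(effect_size=effect, alpha=0.05, power=0.95)
        assert sample_size_one_sample_t(PowerQuery(3, 4.30)) == int(np.ceil(n_sm))

    def test_invalid_queries(self):
        with pytest.raises(ValueError):
            PowerQuery(delta=0, sd=1)
        with pytest.raises(ValueError):
            PowerQuery(delta=1, sd=1, power=1.0)

    def test_unreachable_power_errors(self):
        with pytest.raises(ValueError):
            sample_size_one_sample_t(PowerQuery(delta=1e-6, sd=1.0), n_max=50)
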