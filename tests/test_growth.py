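"""Deterministic growth models: rates, equilibria, thresholds, trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

import oncodyn as od
from oncodyn.growth import (
    ApproximationInvalidError,
    DomainError,
    GrowthConfigError,
    erm2_stationary_roots,
)

from conftest import random_erm1_sets, random_erm2_sets


class TestRhs:
    def test_richards_zero_is_equilibrium(self):
        p = od.GrowthParams("richards", nu=2.0, r=0.5, mu=0.1)
        assert od.rhs(0.0, p) == 0.0

    def test_richards_direct_evaluation(self):
        # nu=1, r=1, mu=0.01 -> K=100; at x=50 the logistic rate is 25
        p = od.GrowthParams("richards", nu=1.0, r=1.0, mu=0.01)
        assert od.rhs(50.0, p) == pytest.approx(25.0)

    def test_erm2_origin_is_absorbing_not_minus_s(self):
        p = od.GrowthParams("erm2", nu=1.0, r=0.1, mu=1e-9, s=50.0)
        assert od.rhs(0.0, p) == 0.0

    def test_negative_population_rejected(self):
        p = od.GrowthParams("richards", nu=1.0, r=1.0, mu=0.01)
        with pytest.raises(DomainError):
            od.rhs(-1.0, p)

    def test_erm1_requires_gamma(self):
        with pytest.raises(GrowthConfigError):
            od.GrowthParams("erm1", nu=1.0, r=0.1, mu=0.2)


class TestEquilibria:
    def test_fig3_parameterization_recovers_A_and_K(self):
        # nu=1, r=0.12, mu=0.120012, gamma=1.2e-5 factorizes with A=1, K=1e4
        p = od.GrowthParams("erm1", nu=1.0, r=0.12, mu=0.120012, gamma=1.2e-5)
        rep = od.equilibria(p)
        assert rep.threshold == pytest.approx(1.0, rel=1e-9)
        assert rep.carrying_capacity == pytest.approx(1e4, rel=1e-9)

    def test_erm1_closed_form_matches_independent_root(self):
        """Closed-form A equals the polynomial-root oracle to 1e-9 relative."""
        for p in random_erm1_sets(100, seed=5):
            rep = od.equilibria(p)
            A, K = rep.threshold, rep.carrying_capacity
            assert 0.0 < A < K
            # oracle 1: eigenvalue-based roots of the per-capita quadratic
            # in y = x**(1/nu): gamma*y^2 - mu*y + r = 0
            y_roots = np.sort(np.roots([p.gamma, -p.mu, p.r]))
            assert y_roots[0] ** p.nu == pytest.approx(A, rel=1e-9)
            assert y_roots[1] ** p.nu == pytest.approx(K, rel=1e-9)
            # oracle 2: bracketed root of the raw rhs (ill-conditioned for
            # large nu, hence the looser tolerance)
            root = brentq(lambda x: od.rhs(x, p), A * 1e-6, math.sqrt(A * K), rtol=1e-15)
            assert root == pytest.approx(A, rel=1e-6)

    def test_erm2_with_zero_s_reduces_to_richards(self):
        p2 = od.GrowthParams("erm2", nu=2.0, r=0.3, mu=0.01, s=0.0)
        pr = od.GrowthParams("richards", nu=2.0, r=0.3, mu=0.01)
        assert od.equilibria(p2).equilibria == od.equilibria(pr).equilibria
        assert od.equilibria(p2).defining_feature == pytest.approx(2.0)

    def test_erm1_without_threshold_reports_extinction_only(self):
        # mu^2 <= 4 r gamma: no positive equilibria
        p = od.GrowthParams("erm1", nu=1.0, r=1.0, mu=0.1, gamma=1.0)
        rep = od.equilibria(p)
        assert rep.equilibria == (0.0,)
        assert rep.threshold is None

    def test_erm2_extinction_only_when_s_too_large(self):
        p = od.GrowthParams("erm2", nu=1.0, r=0.1, mu=1e-4, s=1e9)
        rep = od.equilibria(p)
        assert rep.equilibria == (0.0,)

    def test_equilibria_sorted_with_origin_present(self):
        for p in random_erm2_sets(20, seed=8):
            eq = od.equilibria(p).equilibria
            assert eq[0] == 0.0
            assert list(eq) == sorted(eq)

    def test_erm1_large_K_limit_rates(self):
        """nu=1: lambda_grow = r(1-A/K) -> r and lambda_sat = r(K/A-1) -> inf."""
        r, A = 0.5, 10.0
        for K in (1e4, 1e6, 1e8):
            p = od.GrowthParams.erm1_from_thresholds(1.0, r, A, K)
            rep = od.equilibria(p)
            assert rep.lambda_grow == pytest.approx(r * (1 - A / K), rel=1e-9)
            assert rep.lambda_sat == pytest.approx(r * (K / A - 1), rel=1e-9)
            # numerical linearization agrees at the threshold
            num = od.numerical_linearization(p, A)
            assert num == pytest.approx(rep.lambda_grow, rel=1e-4)
        assert rep.lambda_grow == pytest.approx(r, rel=1e-3)


class TestThresholdApprox:
    def test_zero_s_gives_zero_threshold(self):
        p = od.GrowthParams("erm2", nu=1.0, r=0.1, mu=1e-9, s=0.0)
        assert od.erm2_threshold_approx(p) == 0.0

    def test_linear_in_s_at_fixed_exponent(self):
        p1 = od.GrowthParams("erm2", nu=1.0, r=0.1, mu=1e-9, s=100.0)
        p2 = od.GrowthParams("erm2", nu=1.0, r=0.1, mu=1e-9, s=200.0)
        a = 3.0
        assert od.erm2_threshold_approx(p2, a) == pytest.approx(
            2 * od.erm2_threshold_approx(p1, a)
        )

    def test_within_factor_three_of_true_root(self):
        """Self-consistent approximation vs numerically located threshold."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            nu = 10.0 ** rng.uniform(0, 1.5)
            r = 10.0 ** rng.uniform(-2, 0)
            A = 10.0 ** rng.uniform(1, 6)
            K = A * 10.0 ** rng.uniform(2, 5)
            p = od.GrowthParams.erm2_from_thresholds(nu, r, A, K)
            approx = od.erm2_threshold_approx(p)
            true_A = erm2_stationary_roots(p)[0]
            assert true_A / 3 <= approx <= true_A * 3

    def test_invalid_denominator_raises(self):
        p = od.GrowthParams("erm2", nu=1.0, r=1e-6, mu=1.0, s=10.0)
        with pytest.raises(ApproximationInvalidError):
            od.erm2_threshold_approx(p, a=3.0)


class TestIntegrate:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        nu=st.floats(0.5, 100.0),
        logK=st.floats(2, 8),
        r=st.floats(0.05, 1.0),
        frac=st.floats(0.01, 0.9),
    )
    def test_richards_numeric_matches_closed_form(self, nu, logK, r, frac):
        p = od.GrowthParams.richards_from_capacity(nu, r, 10.0**logK)
        x0 = frac * 10.0**logK
        t_end = 5.0 / r
        traj = od.integrate(p, x0, t_end, grid=20, rtol=1e-11)
        exact = od.richards_closed_form(p, x0, traj.times)
        assert np.max(np.abs(traj.values - exact) / exact) < 1e-6

    def test_erm2_below_threshold_goes_extinct_in_finite_time(self):
        p = od.GrowthParams.erm2_from_thresholds(1.0, 0.2, 1e3, 1e9)
        traj = od.integrate(p, 500.0, 200.0, grid=100)
        assert traj.extinct_at is not None
        assert traj.values[-1] == 0.0
        # and stays at zero after extinction
        after = traj.values[traj.times >= traj.extinct_at]
        assert np.all(after == 0.0)

    def test_trajectories_stay_non_negative(self):
        for p in random_erm2_sets(10, seed=3):
            A = erm2_stationary_roots(p)[0]
            traj = od.integrate(p, 0.5 * A, 50.0 / p.r, grid=50)
            assert np.all(traj.values >= 0.0)

    def test_zero_start_stays_zero(self):
        p = od.GrowthParams("richards", nu=1.0, r=1.0, mu=0.01)
        traj = od.integrate(p, 0.0, 10.0, grid=5)
        assert np.all(traj.values == 0.0)

    def test_overflow_guard_triggers(self):
        p = od.GrowthParams("richards", nu=1.0, r=5.0, mu=0.0)
        with pytest.raises(od.growth.IntegrationError):
            od.integrate(p, 1e6, 50.0)


class TestFirstPassage:
    def test_fig3_first_passage_and_traversal_times(self, fig3_erm1):
        """Step-like ERM1 run: ~5.7 units to 1% of K, ~1e-1 through 1%-99%."""
        t1 = od.first_passage_time(fig3_erm1, 2.0, 100.0, 50.0)
        # independent oracle: quadrature of dt = dx / f(x)
        oracle, _ = quad(lambda x: 1.0 / od.rhs(x, fig3_erm1), 2.0, 100.0)
        assert t1 == pytest.approx(oracle, rel=1e-6)
        assert abs(t1 - 5.5) / 5.5 < 0.10

    def test_unreached_target_returns_none(self, fig3_erm1):
        assert od.first_passage_time(fig3_erm1, 0.5, 100.0, 20.0) is None


class TestAsymmetryCurve:
    def test_richards_curve_equals_nu(self):
        grid = [0.5, 1.0, 4.0, 32.0]
        np.testing.assert_allclose(od.asymmetry_curve("richards", grid, 1.0), grid)

    def test_erm1_below_one_and_matches_formula(self):
        grid = np.logspace(-0.3, 2, 8)
        curve = od.asymmetry_curve("erm1", grid, 1.0, A=1.0, K=100.0)
        assert np.all(curve < 1.0)
        np.testing.assert_allclose(curve, (1.0 / 100.0) ** (1.0 / grid), rtol=1e-9)
        assert od.asymmetry_curve("erm1", [1.0], 1.0, A=1.0, K=100.0)[0] == pytest.approx(0.01)

    def test_erm2_at_least_one_for_nu_ge_one(self):
        grid = np.logspace(0, 2, 8)
        curve = od.asymmetry_curve("erm2", grid, 1.0, A=1.0, K=100.0)
        assert np.all(curve >= 1.0 - 1e-12)

    def test_unreachable_targets_flagged_as_nan(self):
        curve = od.asymmetry_curve("erm1", [1.0], 1.0, A=100.0, K=100.0 + 1e-12)
        assert np.isnan(curve[0]) or curve[0] < 1.0  # degenerate A ~ K


class TestDefiningFeatureVsNumericalLinearization:
    """The asymmetry dichotomy, each model against central differences."""

    def test_erm1_feature_below_one(self):
        for p in random_erm1_sets(100, seed=11):
            rep = od.equilibria(p)
            assert rep.defining_feature < 1.0
            A, K = rep.threshold, rep.carrying_capacity
            num = od.numerical_linearization(p, A) / abs(od.numerical_linearization(p, K))
            assert rep.defining_feature == pytest.approx(num, rel=1e-3)
            assert rep.defining_feature == pytest.approx((A / K) ** (1 / p.nu), rel=1e-9)

    def test_erm2_feature_at_least_one_for_nu_ge_one(self):
        for p in random_erm2_sets(100, seed=12, nu_min=1.0):
            rep = od.equilibria(p)
            assert rep.defining_feature >= 1.0 - 1e-9
            num = od.numerical_linearization(p, rep.threshold) / abs(
                od.numerical_linearization(p, rep.carrying_capacity)
            )
            assert rep.defining_feature == pytest.approx(num, rel=1e-3)

    def test_richards_feature_equals_nu(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            nu = 10.0 ** rng.uniform(np.log10(0.5), np.log10(8.0))
            r = 10.0 ** rng.uniform(-2, 0)
            p = od.GrowthParams.richards_from_capacity(nu, r, 10.0 ** rng.uniform(2, 8))
            rep = od.equilibria(p)
            assert rep.defining_feature == pytest.approx(nu, rel=1e-12)
            K = rep.carrying_capacity
            num_sat = abs(od.numerical_linearization(p, K))
            assert num_sat == pytest.approx(r, rel=1e-3)
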