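import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autocrine_allee.meanfield import (
    MechanisticParams,
    PhenomParams,
    classify_allee,
    compute_K,
    critical_death_rate,
    critical_density,
    euler_solve,
    fixed_points,
    growth_rate,
    reduce_params,
)
from conftest import bisect_root, random_phenom


class TestComputeK:
    def test_baseline(self):
        # 1/(2e-3) + 0.2/(4*sqrt(5e-12)) = 500 + 22360.68
        expected = 500.0 + 0.2 / (4.0 * math.sqrt(5e-12))
        assert compute_K(1e-3, 5e-9, 0.2) == pytest.approx(expected, rel=1e-12)
        assert compute_K(1e-3, 5e-9, 0.2) == pytest.approx(2.286e4, rel=1e-3)

    def test_small_domain_limit(self):
        assert compute_K(1e-3, 5e-9, 1e-12) == pytest.approx(500.0, rel=1e-6)

    def test_fast_diffusion_limit(self):
        assert compute_K(1e-3, 1e12, 0.2) == pytest.approx(500.0, rel=1e-6)

    @pytest.mark.parametrize("args", [(0, 5e-9, 0.2), (1e-3, 0, 0.2), (1e-3, 5e-9, 0)])
    def test_rejects_nonpositive(self, args):
        with pytest.raises(ValueError):
            compute_K(*args)


class TestReduceParams:
    def test_baseline_values(self, baseline_mech):
        p = reduce_params(baseline_mech)
        assert p.A == pytest.approx(3.286e-5, rel=1e-3)
        assert p.B == pytest.approx(7.714e-5, rel=1e-3)
        assert p.time_unit == "seconds"

    def test_logistic_limit_structure(self):
        # rho -> 0 gives A -> alpha, B -> 0
        mech = MechanisticParams(rho=1e-15)
        p = reduce_params(mech)
        assert p.A == pytest.approx(mech.alpha, rel=1e-6)
        assert abs(p.B) < 1e-12

    @given(
        alpha=st.floats(1e-6, 1e-4),
        rho=st.floats(1e-4, 1e-1),
        delta=st.floats(1e-4, 1e-2),
    )
    @settings(max_examples=50, deadline=None)
    def test_sum_identity(self, alpha, rho, delta):
        # A + B = alpha*(1 + rho/delta) = Gamma(1) regardless of K
        mech = MechanisticParams(alpha=alpha, rho=rho, delta=delta)
        p = reduce_params(mech)
        assert p.A + p.B == pytest.approx(alpha * (1 + rho / delta), rel=1e-12)

    def test_gamma_matches_mechanistic_form(self, baseline_mech):
        # Gamma(n) = alpha + n*alpha*rho/delta + (alpha*rho*K/N)*(1-n)
        m = baseline_mech
        p = reduce_params(m)
        for n in np.linspace(0, 1, 11):
            gamma_reduced = p.A + p.B * n
            gamma_mech = (
                m.alpha + n * m.alpha * m.rho / m.delta + m.alpha * m.rho * m.K / m.N * (1 - n)
            )
            assert gamma_reduced == pytest.approx(gamma_mech, rel=1e-12)


class TestGrowthRate:
    def test_zero_at_origin(self, weak_params):
        assert growth_rate(0.0, weak_params) == 0.0

    def test_at_capacity_equals_minus_mu(self, strong_params):
        assert growth_rate(1.0, strong_params) == pytest.approx(-strong_params.mu)

    def test_two_fixed_points_at_zero_death(self, baseline_mech):
        p0 = reduce_params(baseline_mech)  # mu = 0
        fps = fixed_points(p0)
        assert [n for n, _ in fps] == pytest.approx([0.0, 1.0])

    def test_rejects_out_of_range(self, weak_params):
        with pytest.raises(ValueError):
            growth_rate(1.5, weak_params)
        with pytest.raises(ValueError):
            growth_rate(-0.1, weak_params)


class TestCriticalDeathRate:
    def test_baseline(self, baseline_mech):
        assert critical_death_rate(reduce_params(baseline_mech)) == pytest.approx(
            3.29e-5, rel=1e-2
        )

    def test_logistic_limit(self):
        mech = MechanisticParams(rho=1e-15)
        assert critical_death_rate(reduce_params(mech)) == pytest.approx(mech.alpha, rel=1e-6)

    def test_identity_mu_c_equals_A(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = random_phenom(rng)
            assert critical_death_rate(p) == p.A


class TestClassify:
    def test_weak_example(self, weak_params):
        assert classify_allee(weak_params) == "weak"

    def test_strong_example(self, strong_params):
        assert classify_allee(strong_params) == "strong"

    def test_pure_logistic_is_none(self):
        assert classify_allee(PhenomParams(A=1.0, B=0.0, mu=0.0, time_unit="hours")) == "none"

    def test_tie_counts_as_strong(self):
        assert classify_allee(PhenomParams(A=0.1, B=0.3, mu=0.1, time_unit="hours")) == "strong"

    def test_agrees_with_numerical_signs(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = random_phenom(rng)
            label = classify_allee(p)
            eps = 1e-7
            f_eps = growth_rate(eps, p)
            percap_slope = (growth_rate(2 * eps, p) / (2 * eps)) - (f_eps / eps)
            if label == "strong":
                assert p.mu >= p.A
                if p.mu > p.A:
                    assert f_eps < 0  # per-capita rate negative near 0
            elif label == "weak":
                assert f_eps > 0 and percap_slope > 0
            else:
                assert f_eps > 0


class TestCriticalDensity:
    def test_strong_example_vs_bisection(self, strong_params):
        n_c = critical_density(strong_params)
        assert n_c == pytest.approx(0.0129, abs=5e-4)
        # independent oracle: bisection on f from 0+ up to f's argmax
        # (bracketing only the lower sign change)
        grid = np.linspace(1e-6, 0.5, 2001)
        f_grid = [growth_rate(n, strong_params) for n in grid]
        hi = grid[int(np.argmax(f_grid))]
        oracle = bisect_root(lambda n: growth_rate(n, strong_params), 1e-6, hi)
        assert n_c == pytest.approx(oracle, abs=1e-9)

    def test_marginal_case_is_zero(self):
        p = PhenomParams(A=0.1, B=0.3, mu=0.1, time_unit="hours")
        assert critical_density(p) == 0.0

    def test_weak_params_have_no_threshold(self, weak_params):
        assert critical_density(weak_params) is None

    def test_root_properties_where_defined(self):
        rng = np.random.default_rng(11)
        found = 0
        for _ in range(1000):
            p = random_phenom(rng)
            n_c = critical_density(p)
            if n_c is not None and n_c > 0:
                found += 1
                assert abs(growth_rate(n_c, p)) < 1e-9
                # unstable: f changes sign from - to +
                assert growth_rate(max(n_c - 1e-6, 0.0), p) < 0
        assert found > 20  # regime actually exercised


class TestFixedPoints:
    def test_zero_death_baseline(self, baseline_mech):
        fps = fixed_points(reduce_params(baseline_mech))
        assert fps[0] == (0.0, "unstable")
        assert fps[1][0] == pytest.approx(1.0)
        assert fps[1][1] == "stable"

    def test_strong_allee_pattern(self, strong_params):
        fps = fixed_points(strong_params)
        labels = [s for _, s in fps]
        values = [n for n, _ in fps]
        assert labels == ["stable", "unstable", "stable"]
        assert values[1] == pytest.approx(critical_density(strong_params), abs=1e-12)

    def test_overwhelming_death_only_origin(self, weak_params):
        p = PhenomParams(
            A=weak_params.A,
            B=weak_params.B,
            mu=10 * (weak_params.A + weak_params.B),
            time_unit="hours",
        )
        fps = fixed_points(p)
        assert fps == [(0.0, "stable")]


class TestEulerSolve:
    def test_empty_stays_empty(self, strong_params):
        _, n = euler_solve(strong_params, 0.0, 100.0, dt=0.25)
        assert np.all(n == 0.0)

    def test_first_order_convergence_to_logistic(self):
        # closed-form logistic: dn/dt = n(1-n), n0=0.1
        p = PhenomParams(A=1.0, B=0.0, mu=0.0, time_unit="hours")

        def exact(t, n0=0.1):
            e = np.exp(t)
            return n0 * e / (1 + n0 * (e - 1))

        sup_errors = {}
        for dt in (0.25, 0.001):
            t, n = euler_solve(p, 0.1, 10.0, dt=dt)
            sup_errors[dt] = np.abs(n - exact(t)).max()
        ratio = sup_errors[0.25] / sup_errors[0.001]
        assert ratio == pytest.approx(250, rel=0.2)

    def test_strong_allee_threshold_behavior(self, strong_params):
        n_c = critical_density(strong_params)
        _, below = euler_solve(strong_params, 0.8 * n_c, 2000.0, dt=0.25)
        _, above = euler_solve(strong_params, 1.5 * n_c, 2000.0, dt=0.25)
        assert below[-1] < 1e-3
        assert np.all(np.diff(below) <= 1e-15)
        upper = max(n for n, _ in fixed_points(strong_params))
        assert above[-1] == pytest.approx(upper, abs=1e-3)
        assert np.all(np.diff(above) >= -1e-15)

    def test_rejects_bad_inputs(self, weak_params):
        with pytest.raises(ValueError):
            euler_solve(weak_params, -0.1, 10.0)
        with pytest.raises(ValueError):
            euler_solve(weak_params, 0.1, 10.0, dt=-1.0)


class TestUnits:
    def test_round_trip_conversion(self, strong_params):
        p_s = strong_params.to_unit("seconds")
        assert p_s.A == pytest.approx(strong_params.A / 3600.0)
        back = p_s.to_unit("hours")
        assert back.A == pytest.approx(strong_params.A)
        assert back.time_unit == "hours"

    def test_mechanistic_spacing_identity(self, baseline_mech):
        assert baseline_mech.d * baseline_mech.N == pytest.approx(baseline_mech.L)
        assert baseline_mech.d == pytest.approx(20e-4)  # 20 um in cm


class TestIdentitySuite:
    """Cross-cutting identities on random parameter draws."""

    def test_identities_on_random_draws(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            p = random_phenom(rng)
            assert growth_rate(0.0, p) == 0.0
            # Gamma(0) = A, Gamma(1) = A + B via f evaluated off the trivial roots
            n = 0.5
            gamma_half = growth_rate(n, p) / (n * (1 - n)) + p.mu / (1 - n)
            assert gamma_half == pytest.approx(p.A + p.B * n, rel=1e-9, abs=1e-12)
            assert critical_death_rate(p) == p.A
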