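"""Within-patch dynamics: closed forms, limits, sensitivities, optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from biofilmhedge.within_patch import (
    WithinPatchParams,
    biofilm_at,
    biofilm_maximizing_colonization,
    biofilm_slope_limit,
    integrate_full_model,
    planktonic_at,
    solve_trajectory,
    total_size_derivative,
)


def ode_oracle(r, c, t_end, P0, B0=0.0, d=0.0, g=0.0, form="none", times=None):
    """Independent numerical integration of the coupled compartment ODEs."""

    def rhs(_t, y):
        P, B = y
        G = {"none": 0.0, "linear": g, "quadratic": g * np.sqrt(max(B, 0.0))}[form]
        return [(r - c) * P + d * B, G + c * P - d * B]

    t_eval = times if times is not None else [t_end]
    sol = solve_ivp(rhs, (0.0, t_end), [P0, B0], rtol=1e-10, atol=1e-8,
                    t_eval=t_eval, method="LSODA")
    assert sol.success
    return sol.y


class TestClosedForms:
    def test_planktonic_static_at_c_equals_r(self):
        p = WithinPatchParams(r=0.08, c=0.08, t_end=40, P0=5e6)
        assert planktonic_at(p, 40.0) == 5e6

    def test_planktonic_malthusian_when_no_colonization(self):
        p = WithinPatchParams(r=0.1, c=0.0, t_end=10, P0=1000)
        assert planktonic_at(p, 10.0) == pytest.approx(1000 * np.e, rel=1e-12)

    def test_initial_condition(self):
        p = WithinPatchParams(r=0.05, c=0.02, t_end=10, P0=123.0)
        assert planktonic_at(p, 0.0) == 123.0
        assert biofilm_at(p, 0.0) == 0.0

    def test_no_biofilm_without_colonization(self):
        p = WithinPatchParams(r=0.08, c=0.0, t_end=40, P0=5e6)
        assert biofilm_at(p, 40.0) == 0.0

    def test_biofilm_linear_accumulation_at_c_equals_r(self):
        # removable singularity: B = c P0 t
        p = WithinPatchParams(r=0.08, c=0.08, t_end=40, P0=5e6)
        assert biofilm_at(p, 40.0) == pytest.approx(1.6e7, rel=1e-12)
        # cross-check by approaching the singularity numerically
        p_eps = WithinPatchParams(r=0.08, c=0.08 * (1 - 1e-9), t_end=40, P0=5e6)
        assert biofilm_at(p_eps, 40.0) == pytest.approx(1.6e7, rel=1e-6)

    def test_biofilm_value_below_r(self):
        p = WithinPatchParams(r=0.08, c=0.04, t_end=40, P0=5e6)
        assert biofilm_at(p, 40.0) == pytest.approx(5e6 * (np.exp(1.6) - 1), rel=1e-12)

    def test_valid_beyond_r(self):
        # c > r: plankton declines but the biofilm count stays non-negative
        p = WithinPatchParams(r=0.05, c=0.2, t_end=30, P0=1e4)
        assert planktonic_at(p, 30.0) < 1e4
        assert biofilm_at(p, 30.0) > 0

    @pytest.mark.parametrize("r,c,t_end", [(0.08, 0.04, 40), (0.05, 0.2, 30), (0.1, 0.0999, 25)])
    def test_matches_ode_oracle(self, r, c, t_end):
        p = WithinPatchParams(r=r, c=c, t_end=t_end, P0=5e6)
        P_num, B_num = ode_oracle(r, c, t_end, 5e6)
        assert planktonic_at(p, t_end) == pytest.approx(P_num[-1], rel=1e-8)
        assert biofilm_at(p, t_end) == pytest.approx(B_num[-1], rel=1e-8)

    def test_domain_errors(self):
        p = WithinPatchParams(r=0.08, c=0.04, t_end=40, P0=5e6)
        with pytest.raises(ValueError):
            planktonic_at(p, -1.0)
        with pytest.raises(ValueError):
            WithinPatchParams(r=0.08, c=0.04, t_end=40, P0=0.0)
        with pytest.raises(ValueError):
            WithinPatchParams(r=-0.1, c=0.04, t_end=40, P0=1.0)


class TestTrajectory:
    def test_single_point_consistent_with_scalars(self):
        p = WithinPatchParams(r=0.06, c=0.03, t_end=40, P0=1e5)
        traj = solve_trajectory(p, [17.0])
        assert traj.P[0] == planktonic_at(p, 17.0)
        assert traj.B[0] == biofilm_at(p, 17.0)

    def test_unsorted_grid_rejected(self):
        p = WithinPatchParams(r=0.06, c=0.03, t_end=40, P0=1e5)
        with pytest.raises(ValueError):
            solve_trajectory(p, [1.0, 0.5, 2.0])

    def test_crossing_pattern_high_c_wins_early_low_c_wins_late(self):
        # short growth favors aggressive colonization; long growth favors the
        # planktonic growth engine (low c)
        r, P0 = 0.08, 5e6
        hi = WithinPatchParams(r=r, c=0.99 * r, t_end=40, P0=P0)
        lo = WithinPatchParams(r=r, c=0.3 * r, t_end=40, P0=P0)
        assert biofilm_at(hi, 5.0) > biofilm_at(lo, 5.0)
        assert biofilm_at(hi, 40.0) < biofilm_at(lo, 40.0)

    def test_plankton_monotone_decreasing_in_c(self):
        r, t_end, P0 = 0.08, 40.0, 5e6
        cs = np.linspace(0.1 * r, 0.99 * r, 10)
        P_end = [planktonic_at(WithinPatchParams(r=r, c=c, t_end=t_end, P0=P0), t_end) for c in cs]
        assert np.all(np.diff(P_end) < 0)

    def test_biofilm_nondecreasing_in_time(self):
        p = WithinPatchParams(r=0.08, c=0.05, t_end=40, P0=5e6)
        traj = solve_trajectory(p, np.linspace(0, 40, 50))
        assert np.all(np.diff(traj.B) >= 0)


class TestFullModel:
    def test_reduces_to_closed_form(self):
        p = WithinPatchParams(r=0.08, c=0.04, t_end=40, P0=5e6)
        times = np.linspace(0, 40, 21)
        traj = integrate_full_model(p, times)
        ref = solve_trajectory(p, times)
        np.testing.assert_allclose(traj.P, ref.P, rtol=1e-6)
        np.testing.assert_allclose(traj.B[1:], ref.B[1:], rtol=1e-6)

    @pytest.mark.parametrize("form,g", [("linear", 40000.0), ("quadratic", 1000.0)])
    def test_biofilm_growth_exceeds_no_growth_model(self, form, g):
        # reference comparison parameters: t=50, P0=5e6, d=0.01
        for r in (0.02, 0.12):
            c = 0.5 * r
            full = WithinPatchParams(r=r, c=c, t_end=50, P0=5e6, d=0.01, g=g, growth_form=form)
            none = WithinPatchParams(r=r, c=c, t_end=50, P0=5e6)
            B_full = integrate_full_model(full, [50.0]).B[-1]
            B_none = biofilm_at(none, 50.0)
            assert B_full > B_none

    def test_rank_order_across_growth_rates_preserved(self):
        # the simplification argument: adding modest biofilm growth does not
        # reorder B(t_end) across planktonic growth rates
        rs = np.linspace(0.02, 0.12, 6)
        B_none, B_lin = [], []
        for r in rs:
            c = 0.5 * r
            B_none.append(biofilm_at(WithinPatchParams(r=r, c=c, t_end=50, P0=5e6), 50.0))
            p = WithinPatchParams(r=r, c=c, t_end=50, P0=5e6, d=0.01, g=40000.0, growth_form="linear")
            B_lin.append(integrate_full_model(p, [50.0]).B[-1])
        assert list(np.argsort(B_none)) == list(np.argsort(B_lin))

    def test_dispersal_returns_cells_to_plankton(self):
        # c=0, g=0: B decays at rate d and feeds P; closed-form linear-system oracle
        r, d, P0, B0, t_end = 0.03, 0.5, 1e3, 1e4, 10.0
        p = WithinPatchParams(r=r, c=0.0, t_end=t_end, P0=P0, B0=B0, d=d)
        traj = integrate_full_model(p, [t_end])
        B_exact = B0 * np.exp(-d * t_end)
        # P' = rP + d B0 e^{-dt}  =>  P = e^{rt} P0 + d B0 (e^{rt} - e^{-dt})/(r+d)
        P_exact = np.exp(r * t_end) * P0 + d * B0 * (np.exp(r * t_end) - np.exp(-d * t_end)) / (r + d)
        assert traj.B[-1] == pytest.approx(B_exact, rel=1e-6)
        assert traj.P[-1] == pytest.approx(P_exact, rel=1e-6)

    def test_quadratic_form_survives_empty_biofilm(self):
        p = WithinPatchParams(r=0.05, c=0.01, t_end=20, P0=1e4, g=1000.0, growth_form="quadratic")
        traj = integrate_full_model(p, np.linspace(0, 20, 11))
        assert np.all(np.isfinite(traj.B))
        assert np.all(traj.B >= 0)


class TestSensitivities:
    def test_slope_limit_zero_at_patch_quality_threshold(self):
        assert biofilm_slope_limit(1.0, 0.05, 40.0) == 0.0

    def test_slope_limit_value(self):
        assert biofilm_slope_limit(1.0, 0.1, 40.0) == pytest.approx(-40.0)

    def test_slope_limit_sign_below_threshold(self):
        assert biofilm_slope_limit(2.0, 0.03, 40.0) > 0  # r t = 1.2 < 2

    @pytest.mark.parametrize("r,t_end", [(0.1, 40.0), (0.04, 40.0), (0.08, 30.0)])
    def test_slope_limit_matches_finite_difference(self, r, t_end):
        P0 = 1.0
        h = r * 1e-6
        c0 = r * (1 - 1e-6)

        def B(c):
            return biofilm_at(WithinPatchParams(r=r, c=c, t_end=t_end, P0=P0), t_end)

        fd = (B(c0 + h) - B(c0 - h)) / (2 * h)
        assert biofilm_slope_limit(P0, r, t_end) == pytest.approx(fd, rel=1e-3, abs=1e-6)

    def test_total_size_derivative_zero_at_t_zero(self):
        assert total_size_derivative(1000.0, 0.05, 0.02, 0.0) == 0.0

    def test_total_size_derivative_negative_for_positive_time(self, rng):
        for _ in range(30):
            r = rng.uniform(0.01, 0.2)
            c = rng.uniform(0.0, 2 * r)
            t = rng.uniform(0.1, 60.0)
            assert total_size_derivative(100.0, r, c, t) < 0

    def test_total_size_derivative_matches_finite_difference(self):
        P0, r, c, t = 1000.0, 0.05, 0.02, 10.0
        h = 1e-6

        def total(cc):
            p = WithinPatchParams(r=r, c=cc, t_end=t, P0=P0)
            return planktonic_at(p, t) + biofilm_at(p, t)

        fd = (total(c + h) - total(c - h)) / (2 * h)
        assert total_size_derivative(P0, r, c, t) == pytest.approx(fd, rel=1e-6)

    def test_total_size_derivative_series_branch_continuous(self):
        # value just inside the series guard matches just outside
        P0, r, t = 1.0, 0.1, 10.0
        inside = total_size_derivative(P0, r, r - 5e-6, t)
        outside = total_size_derivative(P0, r, r - 2e-5, t)
        assert inside == pytest.approx(outside, rel=1e-3)


class TestBiofilmMaximizer:
    def test_boundary_when_patch_quality_low(self):
        # r t = 1.6 <= 2: biofilm maximized by full colonization
        assert biofilm_maximizing_colonization(0.04, 40.0) == 0.04

    def test_interior_optimum_declines_with_growth_rate(self):
        c1 = biofilm_maximizing_colonization(0.06, 40.0)
        c2 = biofilm_maximizing_colonization(0.12, 40.0)
        assert 0 < c2 / 0.12 < c1 / 0.06 < 1

    def test_inoculum_invariance(self):
        a = biofilm_maximizing_colonization(0.1, 40.0, P0=1.0)
        b = biofilm_maximizing_colonization(0.1, 40.0, P0=5e6)
        assert a == pytest.approx(b, rel=1e-6)

    @pytest.mark.parametrize("r,t_end", [(0.06, 40.0), (0.12, 40.0), (0.1, 25.0)])
    def test_agrees_with_dense_grid_oracle(self, r, t_end):
        grid = np.linspace(0.0, r, 10_001)
        vals = [biofilm_at(WithinPatchParams(r=r, c=c, t_end=t_end, P0=1.0), t_end) for c in grid]
        c_grid = grid[int(np.argmax(vals))]
        assert biofilm_maximizing_colonization(r, t_end) == pytest.approx(c_grid, abs=grid[1])

    def test_hump_condition_random_parameters(self, rng):
        for _ in range(15):
            r = rng.uniform(0.02, 0.2)
            t_end = rng.uniform(5.0, 60.0)
            c_star = biofilm_maximizing_colonization(r, t_end)
            if r * t_end <= 2.0:
                assert c_star == r
            else:
                assert 0 < c_star < r


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    r=st.floats(0.005, 0.2),
    c_rel=st.floats(0.0, 2.0),
    t=st.floats(0.5, 60.0),
)
def test_closed_forms_satisfy_the_odes(r, c_rel, t):
    """Numerical time-derivatives of the closed forms equal (r-c)P and cP."""
    c = c_rel * r
    p = WithinPatchParams(r=r, c=c, t_end=t, P0=1e4)
    h = 1e-5 * max(t, 1.0)
    dP = (planktonic_at(p, t + h) - planktonic_at(p, max(t - h, 0))) / (h + min(h, t))
    dB = (biofilm_at(p, t + h) - biofilm_at(p, max(t - h, 0))) / (h + min(h, t))
    P = planktonic_at(p, t)
    assert dP == pytest.approx((r - c) * P, rel=1e-4, abs=1e-8)
    assert dB == pytest.approx(c * P, rel=1e-4, abs=1e-8)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(r=st.floats(0.01, 0.15), t=st.floats(1.0, 50.0), frac=st.floats(0.05, 0.95))
def test_biofilm_positive_for_any_positive_colonization(r, t, frac):
    p = WithinPatchParams(r=r, c=frac * r, t_end=t, P0=1e3)
    assert biofilm_at(p, t) > 0
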