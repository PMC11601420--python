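"""Restitution-map machinery: spline, iteration, fixed points, sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eadsim.fixtures import (reverse_engineered_map, toy_restitution_points)
from eadsim.restitution import (cobweb_trajectory, fit_restitution_spline,
                                iterate_map, map_bifurcation_diagram,
                                phase_diagram, second_iterate_fixed_points)


def linear_map(a=150.0, b=0.4, di_lo=10.0, di_hi=600.0, n=12):
    di = np.linspace(di_lo, di_hi, n)
    return fit_restitution_spline(np.column_stack([di, a + b * di]))


class TestSplineFit:
    def test_interpolates_knots_exactly(self):
        pts = toy_restitution_points(n=15)
        rmap = fit_restitution_spline(pts)
        assert np.allclose(rmap(pts[:, 0]), pts[:, 1], atol=1e-10)

    def test_collinear_data_reproduces_line_at_midpoints(self):
        di = np.linspace(0.0, 500.0, 11)
        pts = np.column_stack([di, 100.0 + 0.5 * di])
        rmap = fit_restitution_spline(pts)
        mids = 0.5 * (di[:-1] + di[1:])
        assert np.allclose(rmap(mids), 100.0 + 0.5 * mids, atol=1e-9)

    def test_interior_error_shrinks_fast_with_knot_density(self):
        """Away from the boundary the natural-cubic interpolation error
        of a smooth curve drops by ~an order of magnitude per knot
        doubling (quartic convergence)."""
        poly = np.poly1d([1e-6, -4e-4, 0.5, 120.0])
        x = np.linspace(200.0, 300.0, 50)
        errs = []
        for n in (9, 17, 33):
            di = np.linspace(50.0, 450.0, n)
            rmap = fit_restitution_spline(np.column_stack([di, poly(di)]))
            errs.append(np.abs(rmap(x) - poly(x)).max())
        assert errs[1] < 0.15 * errs[0]
        assert errs[2] < 0.15 * errs[1]

    def test_duplicate_di_rejected(self):
        pts = np.array([[10, 100], [10, 110], [30, 120], [40, 130.0]])
        with pytest.raises(ValueError):
            fit_restitution_spline(pts)

    def test_extrapolation_is_clamped(self):
        rmap = linear_map()
        assert rmap(1e4) == pytest.approx(rmap(rmap.di_max))
        assert rmap(-50.0) == pytest.approx(rmap(rmap.di_min))


class TestIterateMap:
    def test_flat_map_is_period1(self):
        di = np.linspace(10.0, 600.0, 8)
        rmap = fit_restitution_spline(
            np.column_stack([di, np.full_like(di, 210.0)]))
        tr = iterate_map(rmap, period=500.0, di0=100.0, n_max=50)
        assert tr.status == "converged_period1"
        assert np.allclose(tr.apd, 210.0)
        assert np.allclose(tr.di[-5:], 290.0)

    @pytest.mark.parametrize("b,converges", [(0.4, True), (0.9, True)])
    def test_linear_map_fixed_point(self, b, converges):
        a = 150.0
        rmap = linear_map(a=a, b=b)
        period = 520.0
        tr = iterate_map(rmap, period, di0=200.0, n_max=400)
        di_star = (period - a) / (1.0 + b)
        assert tr.status == "converged_period1"
        assert tr.di[-1] == pytest.approx(di_star, abs=1e-3)

    def test_block_rule_fires_immediately(self):
        rmap = linear_map(a=400.0, b=0.5, di_lo=10.0, di_hi=400.0)
        rmap.di_block = 25.0
        # T - F(di0) far below the block threshold
        tr = iterate_map(rmap, period=420.0, di0=300.0, n_max=50)
        assert tr.status == "block"
        assert len(tr.di) == 1

    def test_out_of_domain_start_rejected(self):
        with pytest.raises(ValueError):
            iterate_map(linear_map(), 500.0, di0=1e4)


class TestSecondIterate:
    def test_linear_stable_map_has_single_period1_root(self):
        rmap = linear_map(b=0.4)
        fps = second_iterate_fixed_points(rmap, period=520.0)
        assert len(fps) == 1
        assert fps[0].kind == "period1" and fps[0].stability == "stable"
        assert fps[0].di == pytest.approx((520.0 - 150.0) / 1.4, abs=1e-4)

    def test_g_fixed_points_appear_among_g2_roots(self,
                                                  model_restitution_map):
        rmap = model_restitution_map
        for period in (450.0, 520.0, 600.0):
            grid = np.linspace(rmap.di_min, rmap.di_max, 2000)
            g_vals = rmap.g(grid, period) - grid
            g_roots = grid[:-1][np.sign(g_vals[:-1]) != np.sign(g_vals[1:])]
            g2 = second_iterate_fixed_points(rmap, period)
            for r in g_roots:
                assert min(abs(fp.di - r) for fp in g2) < 1.0

    def test_planted_period2_orbit_recovered(self):
        rmap, period = reverse_engineered_map(di_a=100.0, di_b=300.0,
                                              period=500.0)
        fps = second_iterate_fixed_points(rmap, period)
        dis = sorted(fp.di for fp in fps)
        assert any(abs(d - 100.0) < 1e-4 for d in dis)
        assert any(abs(d - 300.0) < 1e-4 for d in dis)

    def test_stability_labels_agree_with_iteration(self):
        """Each stable root attracts nearby initial conditions of the
        second-iterate dynamics; unstable roots repel them."""
        rng = np.random.default_rng(0)
        rmap, period = reverse_engineered_map()
        fps = second_iterate_fixed_points(rmap, period)
        for fp in fps:
            if fp.kind != "period1" and fp.stability == "stable":
                for _ in range(20):
                    di0 = np.clip(fp.di + rng.uniform(-2, 2),
                                  rmap.di_min, rmap.di_max)
                    tr = iterate_map(rmap, period, di0, n_max=500)
                    assert tr.status in ("period2", "converged_period1")
                    # even-step subsequence approaches the root
                    tail = tr.di[-2:]
                    assert min(abs(tail - fp.di)) < 5.0


class TestBifurcationDiagram:
    def test_linear_map_shows_no_hysteresis(self):
        rmap = linear_map(b=0.4)
        df = map_bifurcation_diagram(rmap, np.arange(420.0, 640.0, 10.0))
        up = df[df.direction == "up"].groupby("period").apd.mean()
        down = df[df.direction == "down"].groupby("period").apd.mean()
        assert np.allclose(up.to_numpy(), down.to_numpy(), atol=1e-3)

    def test_model_map_jump_and_hysteresis(self, model_restitution_map):
        """The model-derived map shows a discontinuous up-sweep jump
        (subcritical signature) and direction-dependent branches."""
        rmap = model_restitution_map
        periods = np.arange(440.0, 700.0, 2.0)
        df = map_bifurcation_diagram(rmap, periods)
        up = df[(df.direction == "up") & ~df.blocked]
        spread = up.groupby("period").apd.agg(np.ptp)
        onset_candidates = spread[spread > 20.0]
        assert len(onset_candidates), "no alternans found in sweep range"
        onset = onset_candidates.index.min()
        jump = spread.loc[onset]
        assert jump > 50.0
        down = df[(df.direction == "down") & ~df.blocked]
        spread_dn = down.groupby("period").apd.agg(np.ptp)
        dn_alt = set(spread_dn[spread_dn > 20.0].index)
        up_alt = set(spread[spread > 20.0].index)
        assert dn_alt - up_alt, "down-sweep alternans should persist " \
            "below the up-sweep onset (bistability)"


class TestPhaseDiagram:
    def test_linear_stable_map_is_all_period1(self):
        rmap = linear_map(b=0.4)
        labels = phase_diagram(rmap, np.linspace(430.0, 600.0, 6),
                               np.linspace(50.0, 500.0, 6), n_iter=200)
        assert (labels == 0).all()

    def test_block_region_nonempty_when_f_exceeds_t_minus_di(self):
        rmap = linear_map(a=380.0, b=0.3)
        rmap.di_block = 25.0
        labels = phase_diagram(rmap, np.linspace(400.0, 480.0, 8),
                               np.linspace(20.0, 500.0, 10))
        assert (labels == 2).any()

    def test_labels_independent_of_traversal_order(self):
        rmap, period = reverse_engineered_map()
        ps = np.linspace(420.0, 560.0, 7)
        dis = np.linspace(30.0, 420.0, 9)
        l1 = phase_diagram(rmap, ps, dis)
        l2 = phase_diagram(rmap, ps[::-1], dis[::-1])[::-1, ::-1]
        assert np.array_equal(l1, l2)


class TestCobweb:
    def test_fixed_point_start_is_degenerate(self):
        rmap = linear_map(b=0.4)
        period = 520.0
        di_star = (period - 150.0) / 1.4
        poly = cobweb_trajectory(rmap, period, di_star, 5)
        assert np.allclose(poly[1:, 0], di_star, atol=1e-9)

    def test_single_iteration_has_two_segments(self):
        poly = cobweb_trajectory(linear_map(), 520.0, 200.0, 1)
        assert poly.shape[0] == 3      # 3 vertices = 2 segments

    def test_endpoints_match_iterate_map(self):
        rmap = linear_map(b=0.7)
        period, di0, n = 540.0, 120.0, 6
        poly = cobweb_trajectory(rmap, period, di0, n)
        tr = iterate_map(rmap, period, di0, n_max=n)
        assert np.allclose(poly[2::2, 0], tr.di[:n])
        assert np.allclose(poly[1::2, 1], tr.apd[:n])


class TestPropertyInvariants:
    @settings(max_examples=25, deadline=None)
    @given(b=st.floats(0.05, 0.95), period=st.floats(420.0, 640.0),
           di0=st.floats(30.0, 500.0))
    def test_linear_map_always_converges_when_contractive(self, b, period,
                                                          di0):
        rmap = linear_map(a=150.0, b=b)
        di_star = (period - 150.0) / (1.0 + b)
        tr = iterate_map(rmap, period, di0, n_max=1000)
        if tr.status == "converged_period1" and \
                rmap.di_min < di_star < rmap.di_max:
            assert tr.di[-1] == pytest.approx(di_star, abs=0.1)
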