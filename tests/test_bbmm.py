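"""Brownian bridge model: variance estimation, UD construction, contours."""

import numpy as np
import pytest
from scipy.integrate import quad

from catscape.bbmm import (
    BrownianBridge,
    MotionVariance,
    _loo_triplets,
    _nll,
    compute_ud,
    estimate_motion_variance,
    home_range_summary,
    volume_contour,
)
from catscape.raster import GridSpec, UdRaster, contour_mask
from catscape.simulate import simulate_brownian_track

from conftest import make_track


def gaussian_ud(sigma, cell, half_extent, cat_id="gauss"):
    n = int(2 * half_extent / cell)
    g = GridSpec(-half_extent, -half_extent, cell, n, n)
    gx, gy = g.center_grids()
    v = np.exp(-(gx**2 + gy**2) / (2 * sigma**2))
    return UdRaster(g, v / v.sum(), cat_id)


class TestMotionVariance:
    def test_stationary_track_gives_zero_variance(self):
        tr = make_track(np.arange(0, 600, 30), xy=np.full((20, 2), 3.0))
        mv = estimate_motion_variance(tr, location_error=5.0)
        assert mv.sigma2_m == 0.0
        assert mv.n_triplets >= 1

    def test_too_few_fixes_rejected(self):
        with pytest.raises(ValueError):
            estimate_motion_variance(make_track([0, 120]))

    def test_matches_dense_grid_search(self):
        tr = simulate_brownian_track(25.0, 5.0, 300, 120.0, seed=7)
        mv = estimate_motion_variance(tr, location_error=5.0)
        t, xy = tr.times_s(), tr.xy()
        alpha, T, d2 = _loo_triplets(t, xy, 3600.0)
        dt = np.diff(t)
        disp2 = np.sum(np.diff(xy, axis=0) ** 2, axis=1)
        s2_max = disp2.max() / dt.min()
        grid = np.linspace(0.0, s2_max, 1001)
        nll = [_nll(s, alpha, T, d2, 5.0) for s in grid]
        best = grid[int(np.argmin(nll))]
        assert abs(mv.sigma2_m - best) <= s2_max / 1000

    def test_recovery_on_model_data(self):
        ests = []
        for seed in range(5):
            tr = simulate_brownian_track(25.0, 5.0, 1000, 120.0, seed=seed)
            ests.append(estimate_motion_variance(tr, location_error=5.0).sigma2_m_per_min)
        assert np.median(np.abs(np.array(ests) - 25.0) / 25.0) <= 0.2

    def test_classic_error_model_inflates_estimate(self):
        # the literature variance formula absorbs the withheld fix's own
        # measurement error into sigma_m^2; with delta^2 comparable to the
        # bridge variance the inflation is large and systematic
        tr = simulate_brownian_track(25.0, 5.0, 1000, 120.0, seed=0)
        full = estimate_motion_variance(tr, location_error=5.0, error_model="full")
        classic = estimate_motion_variance(tr, location_error=5.0, error_model="classic")
        assert classic.sigma2_m > full.sigma2_m * 1.3


class TestComputeUd:
    def _pair_track(self, p0, p1, T=600.0):
        return make_track([0.0, T], xy=np.array([p0, p1]))

    def test_mass_is_one_at_two_resolutions(self):
        tr = simulate_brownian_track(25.0, 5.0, 50, 120.0, seed=1)
        mv = estimate_motion_variance(tr, location_error=5.0)
        for cell in (5.0, 10.0):
            xy = tr.xy()
            g = GridSpec.from_extent(
                xy[:, 0].min() - 150, xy[:, 1].min() - 150,
                xy[:, 0].max() + 150, xy[:, 1].max() + 150, cell,
            )
            ud = compute_ud(tr, mv, location_error=5.0, grid=g)
            assert ud.total == pytest.approx(1.0, abs=1e-6)

    def test_mirror_symmetry(self):
        mv = MotionVariance("pair", 0.4, 1, 0.0)
        g = GridSpec(-100.0, -100.0, 10.0, 20, 20)
        ud = compute_ud(self._pair_track((-30.0, 0.0), (30.0, 0.0)), mv, 10.0, g)
        mirrored = compute_ud(self._pair_track((30.0, 0.0), (-30.0, 0.0)), mv, 10.0, g)
        np.testing.assert_allclose(ud.values, mirrored.values[:, ::-1], atol=1e-12)

    def test_translation_equivariance(self):
        mv = MotionVariance("pair", 0.4, 1, 0.0)
        g1 = GridSpec(-100.0, -100.0, 10.0, 20, 20)
        g2 = GridSpec(900.0, -600.0, 10.0, 20, 20)
        ud1 = compute_ud(self._pair_track((-30.0, 0.0), (30.0, 10.0)), mv, 10.0, g1)
        ud2 = compute_ud(
            self._pair_track((970.0, -500.0), (1030.0, -490.0)), mv, 10.0, g2
        )
        np.testing.assert_allclose(ud1.values, ud2.values, atol=1e-12)

    def test_gap_beyond_max_lag_rejected(self):
        tr = make_track([0.0, 7200.0], xy=np.array([[0.0, 0.0], [50.0, 0.0]]))
        with pytest.raises(ValueError):
            compute_ud(tr, MotionVariance("x", 0.4, 1, 0.0), 10.0,
                       GridSpec(-100, -100, 10, 20, 20), max_lag=3600.0)

    def test_default_discretisation_close_to_quadrature(self):
        # the 50-node midpoint rule tracks the exact bridge integral to
        # ~1e-5 per cell on a representative single bridge
        T, s2, d = 600.0, 0.4167, 10.0
        tr = self._pair_track((0.0, 0.0), (50.0, 30.0), T)
        g = GridSpec(-120.0, -120.0, 10.0, 30, 30)
        ud = compute_ud(tr, MotionVariance("pair", s2, 1, 0.0), d, g, n_alpha=50)
        oracle = _quadrature_bridge(g, T, s2, d, (0.0, 0.0), (50.0, 30.0))
        assert np.abs(ud.values - oracle).max() <= 2e-5

    def test_spread_monotone_in_motion_variance(self):
        xy = np.array([[0, 0], [40, 10], [10, 50], [-30, 20], [0, -40]], dtype=float)
        tr = make_track(np.arange(5) * 300.0, xy=xy)
        g = GridSpec(-400.0, -400.0, 10.0, 80, 80)
        areas = []
        for s2 in (0.05, 0.4, 2.0):
            ud = compute_ud(tr, MotionVariance("t", s2, 1, 0.0), 10.0, g)
            areas.append(volume_contour(ud, 0.95).area_ha)
        assert areas[0] <= areas[1] <= areas[2]


def _quadrature_bridge(g, T, s2, d, p0, p1):
    gx, gy = g.center_grids()
    vals = np.zeros_like(gx)
    for r in range(g.n_rows):
        for c in range(g.n_cols):
            def f(a):
                v = T * a * (1 - a) * s2 + ((1 - a) ** 2 + a**2) * d**2
                mx = p0[0] + a * (p1[0] - p0[0])
                my = p0[1] + a * (p1[1] - p0[1])
                return np.exp(
                    -((gx[r, c] - mx) ** 2 + (gy[r, c] - my) ** 2) / (2 * v)
                ) / (2 * np.pi * v)
            vals[r, c] = quad(f, 0.0, 1.0, epsabs=1e-13, limit=200)[0]
    vals *= g.cell_area
    return vals / vals.sum()


class TestVolumeContour:
    def test_level_one_selects_all_positive_mass(self):
        v = np.zeros((4, 4))
        v[1, 1], v[2, 2], v[0, 3] = 0.5, 0.3, 0.2
        ud = UdRaster(GridSpec(0, 0, 10, 4, 4), v)
        c = volume_contour(ud, 1.0)
        assert c.area_ha == pytest.approx(3 * 100 / 1e4)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.0001])
    def test_invalid_level_rejected(self, bad):
        ud = UdRaster(GridSpec(0, 0, 10, 2, 2), np.full((2, 2), 0.25))
        with pytest.raises(ValueError):
            volume_contour(ud, bad)

    def test_ties_included_in_full(self):
        ud = UdRaster(GridSpec(0, 0, 10, 2, 2), np.full((2, 2), 0.25))
        assert volume_contour(ud, 0.5).area_ha == pytest.approx(4 * 100 / 1e4)

    def test_matches_subset_sum_oracle_on_random_rasters(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            v = rng.random((8, 8))
            v /= v.sum()
            level = float(rng.uniform(0.05, 1.0))
            mask = contour_mask(v, level)
            # independent oracle: sort cells by value, take the smallest
            # prefix reaching the level, then widen to all tied values
            order = np.argsort(v.ravel())[::-1]
            csum = np.cumsum(v.ravel()[order])
            k = int(np.searchsorted(csum, level - 1e-12))
            thr = v.ravel()[order[k]]
            expected = (v >= thr) & (v > 0)
            np.testing.assert_array_equal(mask, expected)

    def test_gaussian_analytic_area(self):
        ud = gaussian_ud(50.0, 1.0, 200.0)
        hr = home_range_summary(ud, (0.5, 0.95, 0.99))
        a95 = hr[0.95].area_ha
        assert a95 == pytest.approx(2 * np.pi * 50**2 * np.log(20) / 1e4, rel=0.03)
        assert hr[0.5].area_ha / a95 == pytest.approx(np.log(2) / np.log(20), abs=0.01)
        assert hr[0.99].area_ha / a95 == pytest.approx(np.log(100) / np.log(20), rel=0.02)

    def test_polygon_area_matches_cell_count(self):
        ud = gaussian_ud(30.0, 5.0, 120.0)
        c = volume_contour(ud, 0.95)
        assert c.polygons.area / 1e4 == pytest.approx(c.area_ha, rel=1e-9)

    def test_areas_monotone_in_level(self):
        ud = gaussian_ud(40.0, 5.0, 160.0)
        hr = home_range_summary(ud, (0.5, 0.95, 0.99))
        assert hr[0.5].area_ha <= hr[0.95].area_ha <= hr[0.99].area_ha


class TestModelObjects:
    def test_fit_and_summary(self):
        tr = simulate_brownian_track(25.0, 5.0, 200, 120.0, seed=3)
        res = BrownianBridge(tr, location_error=5.0).fit()
        assert res.sigma2_m > 0
        s = res.summary()
        assert "sigma_m^2" in s and "bm" in s
        ud = res.compute_ud(cell_size=10.0)
        assert ud.total == pytest.approx(1.0, abs=1e-6)

    def test_from_dataframe(self):
        tr = simulate_brownian_track(25.0, 5.0, 100, 120.0, seed=4)
        res = BrownianBridge.from_dataframe(
            tr.fixes[["timestamp", "x", "y"]], cat_id="df", location_error=5.0
        ).fit()
        assert res.motion_variance.cat_id == "df"
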