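"""Log relative-risk surfaces, z statistics and tolerance contours."""

import numpy as np
import pytest
from scipy.special import ndtr
from shapely.geometry import Point

from spatrisk.density import DensitySurface, fixed_kde
from spatrisk.grids import RasterGrid, Window
from spatrisk.risk import (
    ONE_SIDED_Z_095,
    RelativeRiskModel,
    asymptotic_z,
    log_relative_risk,
    plugin_z,
    tolerance_contours,
)
from tests.conftest import gaussian_pattern


def surface(grid, values, n=100, variance=None):
    return DensitySurface(grid.like(values), n, 100.0, variance=variance)


class TestLogRelativeRisk:
    def test_identical_surfaces_give_zero(self, coarse_grid, rng):
        v = rng.uniform(1e-8, 1e-6, size=coarse_grid.shape)
        lr = log_relative_risk(surface(coarse_grid, v), surface(coarse_grid, v))
        np.testing.assert_allclose(lr.values, 0.0, atol=1e-14)

    def test_doubled_case_density_gives_log_two(self, coarse_grid, rng):
        v = rng.uniform(1e-8, 1e-6, size=coarse_grid.shape)
        lr = log_relative_risk(surface(coarse_grid, 2 * v), surface(coarse_grid, v))
        np.testing.assert_allclose(lr.values, np.log(2), rtol=1e-12)

    def test_scalar_cell_value(self, coarse_grid):
        f = surface(coarse_grid, np.full(coarse_grid.shape, 3e-8))
        g = surface(coarse_grid, np.full(coarse_grid.shape, 1e-8))
        lr = log_relative_risk(f, g)
        assert lr.values[0, 0] == pytest.approx(np.log(3.0), rel=1e-12)

    def test_grid_mismatch_rejected(self, coarse_grid):
        other = RasterGrid.full(Window(0, 0, 500, 500), 50.0)
        with pytest.raises(ValueError):
            log_relative_risk(surface(coarse_grid, np.ones(coarse_grid.shape)),
                              surface(other, np.ones(other.shape)))

    def test_antisymmetry_under_label_swap(self, coarse_grid, rng):
        a = rng.uniform(1e-8, 1e-6, size=coarse_grid.shape)
        b = rng.uniform(1e-8, 1e-6, size=coarse_grid.shape)
        fwd = log_relative_risk(surface(coarse_grid, a), surface(coarse_grid, b))
        rev = log_relative_risk(surface(coarse_grid, b), surface(coarse_grid, a))
        np.testing.assert_allclose(fwd.values, -rev.values, rtol=1e-12)


class TestAsymptoticZ:
    def test_zero_log_rr_gives_zero_z(self, coarse_grid, rng):
        v = rng.uniform(1e-8, 1e-6, size=coarse_grid.shape)
        f, g = surface(coarse_grid, v), surface(coarse_grid, v)
        lr = log_relative_risk(f, g)
        z = asymptotic_z(lr, f, g, 100, 100, 50.0, 50.0)
        np.testing.assert_allclose(z.values, 0.0, atol=1e-14)

    def test_doubling_both_sample_sizes_scales_z_by_sqrt2(self, coarse_grid, rng):
        a = rng.uniform(1e-8, 1e-6, size=coarse_grid.shape)
        b = rng.uniform(1e-8, 1e-6, size=coarse_grid.shape)
        f, g = surface(coarse_grid, a), surface(coarse_grid, b)
        lr = log_relative_risk(f, g)
        z1 = asymptotic_z(lr, f, g, 100, 100, 50.0, 50.0)
        z2 = asymptotic_z(lr, f, g, 200, 200, 50.0, 50.0)
        np.testing.assert_allclose(z2.values, np.sqrt(2) * z1.values, rtol=1e-12)

    def test_antisymmetry(self, coarse_grid, rng):
        a = rng.uniform(1e-8, 1e-6, size=coarse_grid.shape)
        b = rng.uniform(1e-8, 1e-6, size=coarse_grid.shape)
        f, g = surface(coarse_grid, a), surface(coarse_grid, b)
        z_fwd = asymptotic_z(log_relative_risk(f, g), f, g, 80, 120, 50.0, 60.0)
        z_rev = asymptotic_z(log_relative_risk(g, f), g, f, 120, 80, 60.0, 50.0)
        np.testing.assert_allclose(z_fwd.values, -z_rev.values, rtol=1e-12)

    def test_monotone_in_log_rr_at_equal_variance(self, coarse_grid):
        v = np.full(coarse_grid.shape, 1e-7)
        f = surface(coarse_grid, v)
        g = surface(coarse_grid, v)
        lr_small = coarse_grid.like(np.full(coarse_grid.shape, 0.1))
        lr_large = coarse_grid.like(np.full(coarse_grid.shape, 0.3))
        z_small = asymptotic_z(lr_small, f, g, 100, 100, 50.0, 50.0)
        z_large = asymptotic_z(lr_large, f, g, 100, 100, 50.0, 50.0)
        assert np.all(z_large.values > z_small.values)

    def test_both_floored_cells_masked(self, coarse_grid):
        v = np.full(coarse_grid.shape, 1e-7)
        v[0, 0] = 0.0
        f, g = surface(coarse_grid, v), surface(coarse_grid, v)
        z = asymptotic_z(log_relative_risk(f, g), f, g, 100, 100, 50.0, 50.0)
        assert np.isnan(z.values[0, 0])


class TestPluginZ:
    def test_agrees_with_asymptotic_in_dense_interior(self, unit_window):
        """The kernel second-moment variance converges to R(K)/(n h^2 f)."""
        rng = np.random.default_rng(7)
        grid = RasterGrid.full(unit_window, 50.0)
        f_pat = gaussian_pattern(4000, unit_window, rng, scale_frac=0.35)
        g_pat = gaussian_pattern(4000, unit_window, rng, scale_frac=0.35)
        f = fixed_kde(f_pat, 80.0, grid)
        g = fixed_kde(g_pat, 80.0, grid)
        lr = log_relative_risk(f, g)
        zp = plugin_z(lr, f, g)
        za = asymptotic_z(lr, f, g, 4000, 4000, 80.0, 80.0)
        dense = (f.values > 5e-7) & (g.values > 5e-7)
        ratio = zp.values[dense] / za.values[dense]
        assert np.nanmedian(np.abs(ratio - 1)) < 0.1

    def test_requires_variance_surfaces(self, coarse_grid):
        f = surface(coarse_grid, np.full(coarse_grid.shape, 1e-7))
        g = surface(coarse_grid, np.full(coarse_grid.shape, 1e-7))
        with pytest.raises(ValueError):
            plugin_z(log_relative_risk(f, g), f, g)


class TestToleranceContours:
    def radial_p(self, grid, r_star, z0=3.0):
        """p surface of a radial z bump crossing 1.645 at radius r_star."""
        X, Y = grid.cell_centers()
        cx = (grid.window.xmin + grid.window.xmax) / 2
        cy = (grid.window.ymin + grid.window.ymax) / 2
        r = np.hypot(X - cx, Y - cy)
        z = z0 - (z0 - ONE_SIDED_Z_095) * r / r_star
        return grid.like(1.0 - ndtr(z))

    def test_all_ones_give_empty_set(self, coarse_grid):
        p = coarse_grid.like(np.ones(coarse_grid.shape))
        assert tolerance_contours(p, 0.05) == []

    def test_alpha_one_sentinel_returns_window(self, coarse_grid):
        polys = tolerance_contours(coarse_grid.like(np.ones(coarse_grid.shape)),
                                   1.0)
        assert len(polys) == 1
        assert polys[0].area == pytest.approx(coarse_grid.window.area)

    def test_radial_bump_contour_is_a_circle(self):
        grid = RasterGrid.full(Window(0, 0, 1000, 1000), 10.0)
        r_star = 300.0
        polys = tolerance_contours(self.radial_p(grid, r_star), 0.05)
        assert len(polys) == 1
        assert polys[0].area == pytest.approx(np.pi * r_star ** 2, rel=0.05)
        assert polys[0].contains(Point(500, 500))

    def test_polygon_area_matches_raster_mask(self):
        grid = RasterGrid.full(Window(0, 0, 1000, 1000), 10.0)
        p = self.radial_p(grid, 280.0)
        polys = tolerance_contours(p, 0.05)
        mask_area = (p.values < 0.05).sum() * grid.cell_area
        poly_area = sum(pl.area for pl in polys)
        # round-trip mismatch below one cell per boundary cell
        boundary_cells = 2 * np.pi * 280.0 / grid.cell_size
        assert abs(poly_area - mask_area) < boundary_cells * grid.cell_area

    def test_hole_in_annulus_is_represented(self):
        grid = RasterGrid.full(Window(0, 0, 1000, 1000), 10.0)
        X, Y = grid.cell_centers()
        r = np.hypot(X - 500, Y - 500)
        p = grid.like(np.where((r > 150) & (r < 350), 0.01, 0.99))
        polys = tolerance_contours(p, 0.05)
        total = sum(pl.area for pl in polys)
        annulus = np.pi * (350 ** 2 - 150 ** 2)
        assert total == pytest.approx(annulus, rel=0.1)
        assert not any(pl.contains(Point(500, 500)) for pl in polys)

    def test_invalid_alpha_rejected(self, coarse_grid):
        with pytest.raises(ValueError):
            tolerance_contours(coarse_grid.like(np.ones(coarse_grid.shape)), 0.0)


@pytest.fixture(scope="module")
def fitted(small_study):
    rng = np.random.default_rng(5)
    cases, controls = small_study.sample_patterns(rng=rng, n_cases=300)
    model = RelativeRiskModel(cases, controls, estimator="adaptive",
                              grid=small_study.analysis_grid)
    return model.fit(), small_study


class TestRelativeRiskModel:
    def test_surfaces_share_grid_and_normalise(self, fitted):
        res, _ = fitted
        assert res.f_surface.integral() == pytest.approx(1.0, abs=0.02)
        assert res.g_surface.integral() == pytest.approx(1.0, abs=0.02)
        assert res.log_rr.shape == res.z.shape == res.p.shape

    def test_significant_mask_consistent_with_p(self, fitted):
        res, _ = fitted
        np.testing.assert_array_equal(res.significant_mask.values.astype(bool),
                                      res.p.values < res.alpha)

    def test_region_polygons_match_mask_area(self, fitted):
        res, _ = fitted
        poly_area = sum(pl.area for pl in res.significant_regions)
        mask_area = res.significant_area()
        boundary = sum(pl.exterior.length for pl in res.significant_regions)
        slack = max(2 * boundary / res.p.cell_size, 10) * res.p.cell_area
        assert abs(poly_area - mask_area) <= slack

    def test_summary_mentions_key_quantities(self, fitted):
        res, _ = fitted
        text = res.summary()
        assert "adaptive" in text and "alpha" in text
        assert f"{res.bandwidths.h0_global:.2f}" in text

    def test_geometric_mean_of_adaptive_bandwidths(self, fitted):
        res, _ = fitted
        h = res.f_surface.per_point_h
        assert np.exp(np.mean(np.log(h))) == pytest.approx(
            res.bandwidths.h0_global, rel=1e-6)

    def test_mismatched_windows_rejected(self, unit_window, rng):
        a = gaussian_pattern(30, unit_window, rng)
        other = Window(0, 0, 2000, 2000)
        b = gaussian_pattern(30, other, rng)
        with pytest.raises(ValueError):
            RelativeRiskModel(a, b)

    def test_from_dataframe_roundtrip(self, unit_window, rng):
        import pandas as pd

        cases = gaussian_pattern(30, unit_window, rng)
        controls = gaussian_pattern(40, unit_window, rng)
        df = pd.concat([
            pd.DataFrame({"x": cases.x, "y": cases.y, "label": "case"}),
            pd.DataFrame({"x": controls.x, "y": controls.y, "label": "control"}),
        ])
        model = RelativeRiskModel.from_dataframe(df, window=unit_window,
                                                 estimator="fixed")
        assert model.cases.n == 30 and model.controls.n == 40
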