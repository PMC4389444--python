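"""The dasymetric-bias generator: disaggregation, errors, risk areas, sampling."""

import numpy as np
import pytest
from scipy.stats import chisquare
from shapely.geometry import box

from spatrisk.grids import RasterGrid, Window
from spatrisk.synthetic import (
    PolygonLayer,
    RegionConfig,
    derive_risk_areas,
    disaggregate_population,
    generate_study,
    make_true_population,
    relative_error,
    sample_point_pattern,
)


def one_community(counts, sealing_row, cell=100.0):
    """A single rectangular community over a 1-row raster."""
    n = len(sealing_row)
    win = Window(0, 0, n * cell, cell)
    grid = RasterGrid(np.array([sealing_row], dtype=float), win, cell)
    layer = PolygonLayer(np.array([0]), [win.as_polygon()],
                         counts=np.array([counts], dtype=float))
    return layer, grid


class TestDisaggregation:
    @pytest.mark.parametrize("count,sealing,expected", [
        (100, [75, 25], [75, 25]),
        (0, [75, 25], [0, 0]),
        (50, [10, 10, 80], [5, 5, 40]),
    ])
    def test_proportional_split(self, count, sealing, expected):
        layer, grid = one_community(count, sealing)
        est = disaggregate_population(layer, grid).estimate
        np.testing.assert_allclose(est.values[0], expected, rtol=1e-12)

    def test_zero_sealing_with_population_is_an_error(self):
        layer, grid = one_community(10, [0, 0])
        with pytest.raises(ValueError, match="community 0"):
            disaggregate_population(layer, grid)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            one_community(-5, [50, 50])

    def test_mass_conserved_per_community(self, small_study):
        est = small_study.biased.estimate.values
        ids = small_study.region.community_id_raster
        counts = small_study.region.communities.counts
        sums = np.bincount(ids.ravel(), est.ravel(), minlength=len(counts))
        np.testing.assert_allclose(sums, counts, atol=0.5)


class TestTruePopulation:
    def test_height_one_reduces_to_disaggregation(self):
        layer, grid = one_community(80, [30, 50, 20])
        height = grid.like(np.ones(grid.shape))
        truth = make_true_population(layer, grid, height)
        est = disaggregate_population(layer, grid).estimate
        np.testing.assert_array_equal(truth.values, est.values)

    def test_height_four_holds_four_fifths(self):
        layer, grid = one_community(100, [40, 40])
        height = grid.like(np.array([[4.0, 1.0]]))
        truth = make_true_population(layer, grid, height)
        np.testing.assert_allclose(truth.values[0], [80.0, 20.0], rtol=1e-12)

    def test_uniform_height_rescaling_changes_nothing(self):
        layer, grid = one_community(100, [10, 30, 60])
        h1 = grid.like(np.full(grid.shape, 1.0))
        h2 = grid.like(np.full(grid.shape, 2.0))
        with pytest.raises(ValueError):
            make_true_population(layer, grid, grid.like(np.full(grid.shape, 0.5)))
        t1 = make_true_population(layer, grid, h1)
        t2 = make_true_population(layer, grid, h2)
        np.testing.assert_allclose(t1.values, t2.values, rtol=1e-12)


class TestRelativeError:
    @pytest.mark.parametrize("y_hat,y,expected", [
        (50.0, 100.0, -50.0),
        (100.0, 100.0, 0.0),
        (150.0, 100.0, 50.0),
    ])
    def test_percent_formula(self, y_hat, y, expected):
        assert relative_error(y_hat, y) == pytest.approx(expected)

    def test_zero_truth_flagged_and_nan(self):
        with pytest.warns(UserWarning, match="zero true population"):
            re = relative_error([10.0, 20.0], [0.0, 10.0])
        assert np.isnan(re[0]) and re[1] == pytest.approx(100.0)


class TestRiskAreas:
    def _tracts(self):
        polys = [box(0, 0, 1000, 1000), box(1000, 0, 2000, 1000),
                 box(2000, 0, 3000, 1000)]
        return PolygonLayer(np.arange(3), polys)

    def test_threshold_selects_only_deep_errors(self):
        tracts = self._tracts()
        grid = RasterGrid.full(Window(0, 0, 3000, 1000), 50.0)
        mask = derive_risk_areas(tracts, [-80.0, -30.0, 10.0], grid,
                                 threshold=-50.0, buffer_m=0.0)
        assert list(mask.selected_tracts) == [0]

    def test_zero_buffer_mask_equals_tract(self):
        tracts = self._tracts()
        grid = RasterGrid.full(Window(0, 0, 3000, 1000), 50.0)
        mask = derive_risk_areas(tracts, [-80.0, -30.0, 10.0], grid,
                                 threshold=-50.0, buffer_m=0.0)
        assert mask.area() == pytest.approx(1e6)

    def test_buffered_square_matches_minkowski_area(self):
        # 1 km x 1 km square + 500 m buffer: A + P*r + pi*r^2
        win = Window(0, 0, 4000, 4000)
        tracts = PolygonLayer(np.array([0]), [box(1500, 1500, 2500, 2500)])
        grid = RasterGrid.full(win, 25.0)
        mask = derive_risk_areas(tracts, [-90.0], grid, threshold=-50.0,
                                 buffer_m=500.0)
        expected = 1e6 + 4 * (1000 * 500) + np.pi * 500 ** 2
        assert mask.area() == pytest.approx(expected, rel=0.01)

    def test_no_selection_warns_and_returns_empty(self):
        tracts = self._tracts()
        grid = RasterGrid.full(Window(0, 0, 3000, 1000), 100.0)
        with pytest.warns(UserWarning, match="empty risk-area mask"):
            mask = derive_risk_areas(tracts, [-10.0, 0.0, 10.0], grid)
        assert mask.area() == 0.0 and mask.buffered is None

    def test_quantile_mode_uses_re_distribution(self):
        tracts = self._tracts()
        grid = RasterGrid.full(Window(0, 0, 3000, 1000), 100.0)
        mask = derive_risk_areas(tracts, [-80.0, -30.0, 10.0], grid,
                                 mode="quantile", quantile=0.5, buffer_m=0.0)
        assert mask.threshold == pytest.approx(-30.0)
        assert list(mask.selected_tracts) == [0]


class TestSampling:
    def test_single_positive_cell_gets_all_points(self, rng):
        win = Window(0, 0, 400, 400)
        w = np.zeros((4, 4))
        w[2, 1] = 5.0
        pat = sample_point_pattern(RasterGrid(w, win, 100.0), 10, rng)
        assert np.all((pat.x >= 100) & (pat.x <= 200))
        assert np.all((pat.y >= 100) & (pat.y <= 200))

    def test_uniform_weights_give_multinomial_quadrants(self, rng):
        win = Window(0, 0, 1000, 1000)
        grid = RasterGrid.full(win, 100.0, fill=1.0)
        pat = sample_point_pattern(grid, 10_000, rng)
        counts = [
            np.sum((pat.x < 500) & (pat.y < 500)),
            np.sum((pat.x >= 500) & (pat.y < 500)),
            np.sum((pat.x < 500) & (pat.y >= 500)),
            np.sum((pat.x >= 500) & (pat.y >= 500)),
        ]
        assert chisquare(counts).pvalue > 0.001

    def test_seed_determinism(self):
        win = Window(0, 0, 1000, 1000)
        grid = RasterGrid.full(win, 100.0, fill=1.0)
        a = sample_point_pattern(grid, 50, np.random.default_rng(5))
        b = sample_point_pattern(grid, 50, np.random.default_rng(5))
        c = sample_point_pattern(grid, 50, np.random.default_rng(6))
        np.testing.assert_array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)

    def test_all_zero_weights_rejected(self, rng):
        grid = RasterGrid.full(Window(0, 0, 100, 100), 50.0, fill=0.0)
        with pytest.raises(ValueError):
            sample_point_pattern(grid, 5, rng)

    def test_cell_frequencies_converge_to_weights(self, rng):
        # law of large numbers: total-variation distance below 1%
        win = Window(0, 0, 500, 500)
        w = rng.uniform(0.2, 2.0, size=(5, 5))
        grid = RasterGrid(w, win, 100.0)
        pat = sample_point_pattern(grid, 100_000, rng)
        row, col = grid.cell_index(pat.x, pat.y)
        emp = np.bincount(row * 5 + col, minlength=25) / pat.n
        tv = 0.5 * np.abs(emp - (w / w.sum()).ravel()).sum()
        assert tv < 0.01


class TestGeneratedRegion:
    def test_population_mass_matches_community_totals(self, small_study):
        region = small_study.region
        assert region.true_population.values.sum() == pytest.approx(
            region.communities.counts.sum(), abs=0.5)

    def test_tract_counts_nest_into_communities(self, small_study):
        t = small_study.tract_table
        per_comm = t.groupby("community_id")["y_true"].sum()
        counts = small_study.region.communities.counts
        np.testing.assert_allclose(per_comm.to_numpy(),
                                   counts[per_comm.index.to_numpy()], atol=0.5)

    def test_sealing_and_height_ranges(self, small_study):
        s = small_study.region.sealing.values
        h = small_study.region.height_factor.values
        assert s.min() >= 0.0 and s.max() <= 100.0
        assert h.min() >= 1.0

    def test_bias_direction_urban_under_rural_over(self, default_study):
        """High-rise tracts are underestimated, their flat neighbours
        overestimated — the systematic dasymetric error."""
        t = default_study.tract_table.copy()
        region = default_study.region
        tid = region.tract_id_raster.ravel()
        n = len(default_study.region.tracts)
        mean_h = (np.bincount(tid, region.height_factor.values.ravel(),
                              minlength=n)
                  / np.bincount(tid, minlength=n))
        urban = mean_h > 2.0
        mixed = np.isin(t["community_id"],
                        t.loc[urban, "community_id"].unique())
        rural_in_mixed = mixed & ~urban & (mean_h < 1.05)
        assert (t.loc[urban, "re_percent"] < 0).all()
        assert (t.loc[rural_in_mixed, "re_percent"] > 0).all()

    def test_flat_world_has_no_risk_areas(self, small_config):
        from dataclasses import replace

        flat = replace(small_config, height_peak=(1.0, 1.0))
        study = generate_study(flat, seed=3)
        assert np.nanmax(np.abs(study.tract_table["re_percent"])) < 1e-6
        assert study.risk_areas.area() == 0.0

    def test_default_study_has_deep_risk_tracts(self, default_study):
        re = default_study.tract_table["re_percent"]
        assert (re < -50).sum() >= 3
        assert default_study.risk_areas.area() > 0
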