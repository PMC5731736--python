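import numpy as np
import pandas as pd
import pytest

import pyrogrid as pg
from conftest import impulse_field


class TestMakeGrid:
    def test_small_lattice_cell_count(self):
        grid = pg.make_grid((0, 2, 0, 2), 1.0)
        assert grid.n_cells == 4

    def test_default_domain_dimensions(self):
        grid = pg.make_grid()
        assert (grid.n_lon, grid.n_lat, grid.n_cells) == (118, 47, 5546)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            pg.make_grid((0, 0, 0, 2))

    def test_boundary_point_assigned_to_exactly_one_cell(self, small_grid):
        # half-open convention: interior boundary point goes northeast
        cid = small_grid.cell_of(2.0, 3.0)
        assert cid == small_grid.cell_of(2.0 + 1e-9, 3.0 + 1e-9)
        west, east, south, north = small_grid.cell_bounds(cid)
        assert west == 2.0 and south == 3.0

    def test_center_roundtrip(self, small_grid):
        for cid in range(small_grid.n_cells):
            lon, lat = small_grid.cell_center(cid)
            assert small_grid.cell_of(lon, lat) == cid


class TestAssignFires:
    def test_two_fires_sum_in_cell_year(self, small_grid):
        recs = pd.DataFrame({"lon": [1.5, 1.2], "lat": [1.5, 1.8],
                             "year": [2000, 2000], "area_ha": [300.0, 700.0]})
        aab = pg.assign_fires_to_cells(recs, small_grid, (2000, 2001))
        assert aab.values[small_grid.cell_of(1.5, 1.5), 0] == 1000.0
        # no fires anywhere else / other year -> zero, not missing
        assert aab.values.sum() == 1000.0
        assert np.isfinite(aab.values).all()

    def test_negative_area_rejected(self, small_grid):
        recs = pd.DataFrame({"lon": [1.5], "lat": [1.5], "year": [2000],
                             "area_ha": [-5.0]})
        with pytest.raises(ValueError):
            pg.assign_fires_to_cells(recs, small_grid, (2000, 2000))

    def test_out_of_domain_and_period_dropped_with_warning(self, small_grid):
        recs = pd.DataFrame({"lon": [99.0, 1.5], "lat": [1.5, 1.5],
                             "year": [2000, 1950], "area_ha": [10.0, 10.0]})
        with pytest.warns(UserWarning, match="dropped 2"):
            aab = pg.assign_fires_to_cells(recs, small_grid, (2000, 2000))
        assert aab.values.sum() == 0.0

    def test_generator_bookkeeping_recovered(self, default_world):
        cfg = default_world.config
        aab = pg.assign_fires_to_cells(
            default_world.fire_records, default_world.grid,
            (int(cfg.years[0]), int(cfg.years[-1])))
        np.testing.assert_allclose(
            aab.values, default_world.truth["aab_target"].values, rtol=1e-9)


class TestNeighborFilter:
    def test_interior_impulse_shares(self, small_grid):
        out = pg.neighbor_filter(impulse_field(small_grid, small_grid.cell_of(2.5, 2.5)))
        raster = out.as_raster(2000)
        assert raster[2, 2] == pytest.approx(95.0)
        for r, c in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            assert raster[r, c] == pytest.approx(1.0)
        for r, c in [(1, 1), (1, 3), (3, 1), (3, 3)]:
            assert raster[r, c] == pytest.approx(0.25)
        assert raster.sum() == pytest.approx(100.0)

    def test_uniform_field_unchanged_at_interior(self, small_grid):
        field = pg.AnnualField(small_grid, [2000],
                               np.full((small_grid.n_cells, 1), 7.0))
        raster = pg.neighbor_filter(field).as_raster(2000)
        np.testing.assert_allclose(raster[1:-1, 1:-1], 7.0)

    def test_corner_impulse_drops_offgrid_mass(self, small_grid):
        out = pg.neighbor_filter(impulse_field(small_grid, 0))
        assert out.values.sum() == pytest.approx(95 + 2 * 1.0 + 0.25)

    def test_total_never_increases_and_scales_linearly(self, small_grid):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 50, (small_grid.n_cells, 3))
        field = pg.AnnualField(small_grid, [2000, 2001, 2002], vals)
        out = pg.neighbor_filter(field)
        assert out.values.sum() <= vals.sum() + 1e-9
        out2 = pg.neighbor_filter(field.copy_with(2 * vals))
        np.testing.assert_allclose(out2.values, 2 * out.values, rtol=1e-12)


class TestLogTransform:
    def test_zero_aab_maps_to_zero(self, small_grid):
        field = pg.AnnualField(small_grid, [2000], np.zeros((25, 1)))
        assert pg.log_transform_aab(field, 1.0).values[0, 0] == 0.0

    @pytest.mark.parametrize("a", [523.7, 1.0, 1e7])
    def test_roundtrip(self, a):
        assert pg.inverse_log_transform(np.log(a + 1.0), 1.0) == pytest.approx(a, rel=1e-9)

    def test_negative_input_rejected(self, small_grid):
        field = pg.AnnualField(small_grid, [2000], np.full((25, 1), -1.0))
        with pytest.raises(ValueError):
            pg.log_transform_aab(field)

    def test_offset_insensitivity_of_coefficients_at_large_aab(self):
        # slope of log(AAB+offset) on a driver barely moves with the offset
        # when AAB is large relative to it
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 200)
        aab = np.exp(10 + 0.5 * x + rng.normal(0, 0.1, 200))
        slopes = [np.polyfit(x, np.log(aab + off), 1)[0] for off in (0.1, 1, 10)]
        assert max(slopes) - min(slopes) < 1e-3


class TestRegrid:
    def test_block_average_of_nested_half_degree(self):
        src = pg.make_grid((0, 1, 0, 1), 0.5)
        dst = pg.make_grid((0, 1, 0, 1), 1.0)
        raster = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = pg.bilinear_regrid(raster, src, dst)
        assert out[0, 0] == pytest.approx(2.5)

    def test_constant_preserved(self):
        src = pg.make_grid((0, 4, 0, 4), 0.5)
        dst = pg.make_grid((0, 4, 0, 4), 1.0)
        out = pg.bilinear_regrid(np.full((8, 8), 3.3), src, dst)
        np.testing.assert_allclose(out, 3.3)

    def test_bilinear_exact_on_affine_field(self):
        src = pg.make_grid((0, 10, 0, 10), 0.25)
        dst = pg.make_grid((1, 9, 1, 9), 1.0)
        lon, lat = np.meshgrid(src.lon_centers(), src.lat_centers())
        out = pg.bilinear_regrid(2 * lon + 3 * lat, src, dst)
        dlon, dlat = np.meshgrid(dst.lon_centers(), dst.lat_centers())
        np.testing.assert_allclose(out, 2 * dlon + 3 * dlat, rtol=1e-12)

    def test_no_overlap_raises(self):
        src = pg.make_grid((0, 2, 0, 2), 0.5)
        dst = pg.make_grid((50, 52, 50, 52), 1.0)
        with pytest.raises(ValueError):
            pg.bilinear_regrid(np.ones((4, 4)), src, dst)


class TestSeasonalAggregate:
    def _monthly(self, grid, values, variable):
        return pg.MonthlySeries(grid, [2000], values, variable)

    def test_temperature_mean_and_precip_sum(self, small_grid):
        tvals = np.zeros((25, 1, 12))
        tvals[:, 0, :3] = [0.0, 0.0, 3.0]
        seas = pg.seasonal_aggregate(self._monthly(small_grid, tvals, "temperature"))
        assert seas["winter"].values[0, 0] == pytest.approx(1.0)
        pvals = np.zeros((25, 1, 12))
        pvals[:, 0, 3:6] = [10.0, 20.0, 30.0]
        seas = pg.seasonal_aggregate(self._monthly(small_grid, pvals, "precipitation"))
        assert seas["spring"].values[0, 0] == pytest.approx(60.0)

    def test_missing_month_blanks_season(self, small_grid):
        tvals = np.ones((25, 1, 12))
        tvals[0, 0, 1] = np.nan  # February missing
        seas = pg.seasonal_aggregate(self._monthly(small_grid, tvals, "temperature"))
        assert np.isnan(seas["winter"].values[0, 0])
        assert seas["winter"].values[1, 0] == pytest.approx(1.0)

    def test_lag_field_shifts_one_year(self, small_grid):
        vals = np.tile(np.arange(3.0), (25, 1))
        field = pg.AnnualField(small_grid, [2000, 2001, 2002], vals)
        lagged = pg.lag_field(field)
        assert np.isnan(lagged.values[0, 0])
        np.testing.assert_allclose(lagged.values[:, 1:], vals[:, :2])
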