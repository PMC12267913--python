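import numpy as np
import pytest
from scipy import stats

from canopyflux.raster_io import RasterGrid, tile_cells
from canopyflux.terrain import (
    _d8_receivers,
    aggregate_dtm,
    cell_topography,
    fill_pits,
    flow_accumulation,
    resample_mean,
    slope,
    twi,
)


def iterative_fill_oracle(z: np.ndarray) -> np.ndarray:
    """Independent depression-filling oracle by fixpoint relaxation."""
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    w = np.full_like(z, np.inf, dtype=float)
    w[0, :] = z[0, :]
    w[-1, :] = z[-1, :]
    w[:, 0] = z[:, 0]
    w[:, -1] = z[:, -1]
    changed = True
    while changed:
        changed = False
        for r in range(z.shape[0]):
            for c in range(z.shape[1]):
                lowest_nb = min(
                    w[r + dr, c + dc]
                    for dr, dc in nbrs
                    if 0 <= r + dr < z.shape[0] and 0 <= c + dc < z.shape[1]
                )
                new = max(z[r, c], lowest_nb)
                if new < w[r, c]:
                    w[r, c] = new
                    changed = True
    return w


class TestAggregate:
    def test_constant_surface(self, grid_factory):
        g = grid_factory(np.full((50, 50), 100.0))
        out = aggregate_dtm(g, 10)
        assert out.shape == (5, 5)
        assert out.pixel_size == 10.0
        np.testing.assert_allclose(out.values, 100.0)

    def test_block_mean(self, grid_factory):
        g = grid_factory([[1, 2], [3, 4]])
        assert aggregate_dtm(g, 2).values[0, 0] == pytest.approx(2.5)

    def test_nodata_poisons_block(self, grid_factory):
        v = np.full((4, 4), 10.0)
        v[0, 0] = -9999.0
        out = aggregate_dtm(grid_factory(v), 2)
        assert out.values[0, 0] == out.nodata
        assert out.values[1, 1] == pytest.approx(10.0)

    def test_non_divisible_edge_dropped_with_warning(self, grid_factory):
        g = grid_factory(np.zeros((25, 25)))
        with pytest.warns(UserWarning, match="dropping"):
            out = aggregate_dtm(g, 10)
        assert out.shape == (2, 2)

    def test_fractional_resample_10_to_25(self, grid_factory):
        g = grid_factory(np.full((10, 10), 7.0), pixel_size=10.0)
        out = resample_mean(g, 25.0)
        assert out.pixel_size == 25.0
        assert out.shape == (4, 4)
        np.testing.assert_allclose(out.values, 7.0)


class TestSlope:
    def test_flat_plane_is_zero(self, grid_factory):
        s = slope(grid_factory(np.full((8, 8), 42.0), pixel_size=10.0))
        np.testing.assert_allclose(s.values[1:-1, 1:-1], 0.0, atol=1e-6)
        assert (s.values[0] == s.nodata).all()

    @pytest.mark.parametrize("gradient,expected", [(1.0, 45.0), (0.1, np.degrees(np.arctan(0.1)))])
    def test_inclined_plane_closed_form(self, grid_factory, gradient, expected):
        x = np.arange(10) * 10.0 * gradient
        g = grid_factory(np.tile(x, (10, 1)), pixel_size=10.0)
        s = slope(g)
        np.testing.assert_allclose(s.values[1:-1, 1:-1], expected, rtol=1e-5)

    def test_translation_invariance(self, grid_factory):
        rng = np.random.default_rng(2)
        z = rng.uniform(0, 50, (12, 12))
        s1 = slope(grid_factory(z, pixel_size=10.0))
        s2 = slope(grid_factory(z + 500.0, pixel_size=10.0))
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-3)

    def test_tiny_grid_rejected(self, grid_factory):
        with pytest.raises(ValueError, match="3x3"):
            slope(grid_factory(np.zeros((2, 5))))


class TestFillPits:
    def test_monotone_plane_unchanged(self, grid_factory):
        z = np.add.outer(np.arange(6) * 0.5, np.arange(6) * 1.0) + 10
        out = fill_pits(grid_factory(z))
        np.testing.assert_allclose(out.values, z, atol=1e-4)

    def test_single_depression_raised_to_spill(self, grid_factory):
        z = np.full((5, 5), 10.0) + np.arange(5)[None, :] * 0.1
        z[2, 2] -= 2.0
        filled = fill_pits(grid_factory(z))
        oracle = iterative_fill_oracle(z)
        np.testing.assert_allclose(filled.values, oracle, atol=1e-3)
        assert filled.values[2, 2] >= z[2, 2] + 1.9

    def test_bowl_matches_oracle(self, grid_factory):
        yy, xx = np.mgrid[0:7, 0:7]
        z = 20.0 - 3.0 * np.exp(-((yy - 3) ** 2 + (xx - 3) ** 2) / 4.0)
        filled = fill_pits(grid_factory(z))
        np.testing.assert_allclose(filled.values, iterative_fill_oracle(z), atol=1e-3)

    def test_never_lowers_and_idempotent(self, grid_factory):
        rng = np.random.default_rng(5)
        g = grid_factory(rng.uniform(0, 10, (15, 15)))
        f1 = fill_pits(g)
        assert (f1.values >= g.values - 1e-9).all()
        f2 = fill_pits(f1)
        np.testing.assert_allclose(f2.values, f1.values, atol=1e-3)


class TestFlowAccumulation:
    def test_descending_chain(self, grid_factory):
        z = np.array([[10.0, 9.0, 8.0, 7.0, 6.0]])
        acc = flow_accumulation(grid_factory(z, pixel_size=1.0))
        np.testing.assert_allclose(acc.values[0], [1, 2, 3, 4, 5])

    def test_tilted_plane_linear_columns(self, grid_factory):
        z = np.tile(np.arange(10, 0, -1, dtype=float), (10, 1))
        acc = flow_accumulation(grid_factory(z, pixel_size=1.0))
        expected = np.tile(np.arange(1, 11, dtype=float), (10, 1))
        np.testing.assert_allclose(acc.values, expected)

    def test_local_maximum_accumulates_only_itself(self, grid_factory):
        z = np.zeros((5, 5))
        z[2, 2] = 5.0
        acc = flow_accumulation(fill_pits(grid_factory(z, pixel_size=1.0)))
        assert acc.values[2, 2] == pytest.approx(1.0)

    def test_area_conservation(self, grid_factory):
        rng = np.random.default_rng(9)
        g = fill_pits(grid_factory(rng.uniform(0, 30, (20, 20)), pixel_size=10.0))
        acc = flow_accumulation(g)
        receivers = _d8_receivers(g.values.astype(float), g.valid_mask())
        outlet_total = acc.values[receivers == -1].sum()
        assert outlet_total == pytest.approx(20 * 20 * 100.0)


class TestTwi:
    def test_translation_invariance(self, grid_factory):
        rng = np.random.default_rng(3)
        z = rng.uniform(0, 40, (20, 20))
        t1 = twi(grid_factory(z, pixel_size=10.0), 20.0)
        t2 = twi(grid_factory(z + 123.0, pixel_size=10.0), 20.0)
        m = t1.valid_mask() & t2.valid_mask()
        np.testing.assert_allclose(t1.values[m], t2.values[m], atol=1e-3)

    def test_steeper_plane_lower_twi(self, grid_factory):
        base = np.tile(np.arange(20, dtype=float), (20, 1))
        gentle = twi(grid_factory(base * 2.0, pixel_size=10.0), 10.0)
        steep = twi(grid_factory(base * 8.0, pixel_size=10.0), 10.0)
        m = gentle.valid_mask() & steep.valid_mask()
        assert (steep.values[m] < gentle.values[m]).all()

    def test_valley_wetter_than_ridge(self, grid_factory):
        # V-valley along the column axis with a gentle down-valley tilt
        xx = np.abs(np.arange(20) - 10.0)
        z = np.tile(xx * 5.0, (20, 1)) + np.arange(20)[:, None] * 0.5
        t = twi(grid_factory(z, pixel_size=10.0), 10.0)
        valley = t.values[10, 10]
        ridge = t.values[10, 2]
        assert valley > ridge

    def test_twi_slope_negatively_correlated_across_cells(self):
        from canopyflux.synthetic_landscape import LandscapeConfig, gen_terrain

        cfg = LandscapeConfig(seed=1)
        dtm = gen_terrain(cfg)
        t = twi(aggregate_dtm(dtm, 10), 25.0)
        cells = [w.cell for w in tile_cells(dtm, 100.0) if not w.partial]
        topo = cell_topography(dtm, t, cells)
        sl = np.array([c.slope_mean for c in topo])
        tw = np.array([c.twi_mean for c in topo])
        assert stats.pearsonr(tw, sl)[0] < 0


class TestCellTopography:
    def test_constant_layers(self, grid_factory):
        dtm = grid_factory(np.full((100, 100), 150.0))
        twi_map = RasterGrid(np.full((4, 4), 6.0, dtype=np.float32), y_origin=0.0, pixel_size=25.0)
        cells = [w.cell for w in tile_cells(dtm, 100.0)]
        topo = cell_topography(dtm, twi_map, cells)[0]
        assert topo.elevation_mean == pytest.approx(150.0)
        assert topo.slope_mean == pytest.approx(0.0, abs=1e-6)
        assert topo.twi_mean == pytest.approx(6.0)

    def test_linear_plane_mean_is_centroid_value(self, grid_factory):
        x = (np.arange(200) + 0.5) * 1.0
        dtm = grid_factory(np.tile(x, (200, 1)))
        twi_map = RasterGrid(np.zeros((8, 8), dtype=np.float32), pixel_size=25.0)
        cells = [w.cell for w in tile_cells(dtm, 100.0)]
        topo = cell_topography(dtm, twi_map, cells)
        by_col = {c.cell.col: c for c in topo}
        assert by_col[0].elevation_mean == pytest.approx(50.0)
        assert by_col[1].elevation_mean == pytest.approx(150.0)

    def test_half_and_half_cell(self, grid_factory):
        v = np.full((100, 100), 100.0)
        v[:, 50:] = 200.0
        dtm = grid_factory(v)
        twi_map = RasterGrid(np.zeros((4, 4), dtype=np.float32), pixel_size=25.0)
        cells = [w.cell for w in tile_cells(dtm, 100.0)]
        assert cell_topography(dtm, twi_map, cells)[0].elevation_mean == pytest.approx(150.0)
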