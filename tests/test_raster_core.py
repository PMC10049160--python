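"""Raster data model, I/O round-trips and area bookkeeping."""

import numpy as np
import pytest

from carbonscape.raster_core import (
    LandUseGrid,
    block_aggregate,
    buffer_mask,
    class_areas,
    crosstab,
    read_landuse,
    write_landuse,
)
from carbonscape.synthetic import SyntheticSpec, make_initial


def _write_ascii(path, body):
    path.write_text(body)
    return path


class TestLandUseGrid:
    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            LandUseGrid(np.array([[1, 9]]), cell_size=30.0)  # out of legend
        with pytest.raises(ValueError):
            LandUseGrid(np.array([[1, 2]]), cell_size=0.0)

    def test_cell_area(self):
        g = LandUseGrid(np.ones((2, 2), int), cell_size=30.0)
        assert g.cell_area_ha == pytest.approx(0.09)
        g = LandUseGrid(np.ones((2, 2), int), cell_size=100.0)
        assert g.cell_area_ha == pytest.approx(1.0)


class TestIO:
    def test_uniform_ascii_grid(self, tmp_path):
        p = _write_ascii(tmp_path / "u.asc",
                         "ncols 3\nnrows 3\nxllcorner 0\nyllcorner 0\n"
                         "cellsize 100\nNODATA_value -9999\n"
                         "2 2 2\n2 2 2\n2 2 2\n")
        g = read_landuse(p)
        assert g.class_counts()[2] == 9
        assert class_areas(g).total_ha() == pytest.approx(9.0)

    def test_out_of_legend_becomes_nodata(self, tmp_path, caplog):
        p = _write_ascii(tmp_path / "bad.asc",
                         "ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\n"
                         "cellsize 30\nNODATA_value -9999\n9 1\n")
        with caplog.at_level("WARNING"):
            g = read_landuse(p)
        assert g.codes[0, 0] == g.nodata_code
        assert g.codes[0, 1] == 1
        assert any("outside legend" in r.message for r in caplog.records)

    def test_all_nodata_rejected(self, tmp_path):
        p = _write_ascii(tmp_path / "empty.asc",
                         "ncols 1\nnrows 1\nxllcorner 0\nyllcorner 0\n"
                         "cellsize 30\nNODATA_value -9999\n-9999\n")
        with pytest.raises(ValueError, match="nodata"):
            read_landuse(p)

    @pytest.mark.parametrize("ext", [".asc", ".tif"])
    def test_round_trip_bit_exact(self, tmp_path, ext):
        rng = np.random.default_rng(4)
        codes = rng.integers(1, 8, size=(17, 13)).astype(np.int32)
        codes[0, 0] = -9999
        g = LandUseGrid(codes, cell_size=30.0, origin=(1000.0, 2000.0))
        path = tmp_path / f"rt{ext}"
        write_landuse(g, path)
        back = read_landuse(path)
        np.testing.assert_array_equal(back.codes, g.codes)
        assert back.cell_size == pytest.approx(g.cell_size)
        assert back.origin == pytest.approx(g.origin)


class TestClassAreas:
    def test_forced_arithmetic_30m(self):
        codes = np.full((10, 10), 2, dtype=int)
        codes.flat[:40] = 1
        g = LandUseGrid(codes, cell_size=30.0)
        areas = class_areas(g)
        assert areas.ha()[1] == pytest.approx(40 * 0.09)  # 3.6 ha
        assert areas.km2()[1] == pytest.approx(0.036)

    def test_nodata_excluded(self):
        g = LandUseGrid(np.array([[-9999, -9999], [2, 2]]), cell_size=100.0)
        areas = class_areas(g)
        assert areas.ha()[2] == pytest.approx(2.0)
        assert areas.total_ha() == pytest.approx(2.0)

    def test_matches_enumeration_on_synthetic(self):
        g = make_initial(SyntheticSpec(shape=(100, 100), seed=5))
        areas = class_areas(g)
        for code in g.legend:
            brute = sum(
                1 for v in g.codes.ravel() if v == code) * g.cell_area_ha
            assert areas.ha()[code] == pytest.approx(brute)


class TestCrosstab:
    def test_identity_is_diagonal(self, toy_grid):
        xt = crosstab(toy_grid, toy_grid)
        off = xt.matrix - np.diag(np.diag(xt.matrix))
        assert np.all(off == 0)
        assert xt.total() == pytest.approx(25.0)

    def test_enumerated_two_by_two(self):
        a = LandUseGrid(np.array([[1, 1], [2, 2]]), cell_size=100.0)
        b = LandUseGrid(np.array([[1, 6], [2, 6]]), cell_size=100.0)
        xt = crosstab(a, b)
        f = xt.to_frame()
        assert f.loc["farmland", "farmland"] == pytest.approx(1.0)
        assert f.loc["farmland", "construction"] == pytest.approx(1.0)
        assert f.loc["forests", "forests"] == pytest.approx(1.0)
        assert f.loc["forests", "construction"] == pytest.approx(1.0)
        assert xt.total() == pytest.approx(4.0)

    def test_row_sums_equal_class_areas(self, synthetic_triplet):
        _, maps, _, _ = synthetic_triplet
        xt = crosstab(maps[0], maps[1])
        areas = class_areas(maps[0]).ha()
        for i, code in enumerate(xt.codes):
            assert xt.matrix[i].sum() == pytest.approx(areas[code])

    def test_transpose_symmetry(self, synthetic_triplet):
        _, maps, _, _ = synthetic_triplet
        ab = crosstab(maps[0], maps[1]).matrix
        ba = crosstab(maps[1], maps[0]).matrix
        np.testing.assert_allclose(ab, ba.T)


class TestBufferMask:
    def test_radius_zero_is_class_mask(self, toy_grid):
        m = buffer_mask(toy_grid, 6, 0.0)
        np.testing.assert_array_equal(m, toy_grid.codes == 6)

    def test_single_cell_two_cell_radius(self):
        codes = np.ones((9, 9), dtype=int)
        codes[4, 4] = 6
        g = LandUseGrid(codes, cell_size=30.0)
        m = buffer_mask(g, 6, 2 * 30.0)
        # brute force: center-to-center distance <= 2 cells
        rows, cols = np.indices(codes.shape)
        brute = np.hypot(rows - 4, cols - 4) <= 2.0
        np.testing.assert_array_equal(m, brute)
        assert m.sum() == 13

    def test_monotone_in_radius(self, toy_grid):
        m1 = buffer_mask(toy_grid, 6, 100.0)
        m2 = buffer_mask(toy_grid, 6, 250.0)
        assert np.all(m2[m1])

    def test_absent_class_empty_with_warning(self, toy_grid, caplog):
        with caplog.at_level("WARNING"):
            m = buffer_mask(toy_grid, 7, 100.0)
        assert not m.any()
        assert any("absent" in r.message for r in caplog.records)


class TestBlockAggregate:
    def test_identity_when_block_equals_cell(self):
        vals = np.arange(12.0).reshape(3, 4)
        coarse, _ = block_aggregate(vals, cell_size=30.0, block=30.0)
        np.testing.assert_allclose(coarse, vals)

    def test_six_by_six_ones(self):
        coarse, bounds = block_aggregate(np.ones((6, 6)), 30.0, 90.0, how="sum")
        np.testing.assert_allclose(coarse, np.full((2, 2), 9.0))
        assert tuple(bounds[0, 0]) == (0, 3, 0, 3)

    def test_sum_conservation_with_partial_edge_blocks(self):
        rng = np.random.default_rng(0)
        vals = rng.random((17, 23))
        coarse, _ = block_aggregate(vals, 30.0, 150.0, how="sum")
        assert np.nansum(coarse) == pytest.approx(vals.sum())

    def test_block_smaller_than_cell_rejected(self):
        with pytest.raises(ValueError):
            block_aggregate(np.ones((2, 2)), 30.0, 10.0)
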