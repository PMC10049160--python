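"""Carbon bookkeeping against the published basin tables, and GM(1,1)."""

import numpy as np
import pandas as pd
import pytest

from carbonscape import datasets
from carbonscape.carbon import (
    CarbonDensityTable,
    compute_cs,
    cs_change,
    gm11_fit,
    gm11_predict,
    transition_cs_flows,
)
from carbonscape.raster_core import AreaTable, LandUseGrid, TransitionCrosstab


@pytest.fixture(scope="module")
def dens2020():
    return datasets.load_dlb_density("2020")


@pytest.fixture(scope="module")
def dens2030():
    return datasets.load_dlb_density("2030")


class TestComputeCS:
    def test_published_farmland_2020(self, dens2020):
        """73,615.78 km² of farmland at 63.56 Mg/ha is 467.90 Tg."""
        areas = AreaTable.from_dict({1: 73615.78 * 100})
        r = compute_cs(areas, dens2020)
        assert r.total_tg == pytest.approx(467.90, abs=0.05)

    def test_all_waters_map_stores_nothing(self, dens2020):
        g = LandUseGrid(np.full((10, 10), 5), cell_size=100.0)
        assert compute_cs(g, dens2020).total_tg == 0.0

    def test_published_2030_natural_evolution(self, dens2030):
        areas = datasets.load_dlb_areas("2030_nes")
        r = compute_cs(areas, dens2030)
        assert r.per_class_tg[2] == pytest.approx(2434.01, abs=0.05)
        assert r.total_tg == pytest.approx(3125.70, abs=0.05)

    def test_linearity_in_areas(self, dens2020):
        a = AreaTable.from_dict({1: 100.0, 2: 50.0})
        b = AreaTable.from_dict({1: 30.0, 2: 70.0})
        ab = AreaTable.from_dict({1: 130.0, 2: 120.0})
        total_sum = compute_cs(a, dens2020).total_tg + compute_cs(b, dens2020).total_tg
        assert compute_cs(ab, dens2020).total_tg == pytest.approx(total_sum, rel=1e-12)

    def test_cell_map_total_matches_area_path(self, dens2020, synthetic_triplet):
        _, maps, _, _ = synthetic_triplet
        r = compute_cs(maps[0], dens2020, cell_map=True)
        assert np.nansum(r.cell_map_mg) / 1e6 == pytest.approx(r.total_tg, rel=1e-6)

    def test_missing_class_rejected(self):
        dens = CarbonDensityTable.from_records({1: (1, 1, 1, 0)})
        areas = AreaTable.from_dict({1: 10.0, 2: 10.0})
        with pytest.raises(ValueError, match="lacks classes"):
            compute_cs(areas, dens)

    def test_waters_row_must_be_zero(self):
        with pytest.raises(ValueError, match="waters"):
            CarbonDensityTable.from_records({5: (1.0, 0, 0, 0)})


class TestCSChange:
    def test_identical_results_zero(self, dens2020):
        areas = datasets.load_dlb_areas("2020")
        r = compute_cs(areas, dens2020)
        assert cs_change(r, r).abs().max() == 0.0

    def test_published_decade_change(self, dens2020, dens2030):
        r0 = compute_cs(datasets.load_dlb_areas("2020"), dens2020)
        r1 = compute_cs(datasets.load_dlb_areas("2030_nes"), dens2030)
        assert cs_change(r0, r1)["total"] == pytest.approx(120.41, abs=0.05)

    def test_total_is_sum_of_classes(self, dens2020, dens2030):
        r0 = compute_cs(datasets.load_dlb_areas("2020"), dens2020)
        r1 = compute_cs(datasets.load_dlb_areas("2030_eds"), dens2030)
        d = cs_change(r0, r1)
        assert d["total"] == pytest.approx(d.drop("total").sum(), rel=1e-12)


class TestTransitionFlows:
    def test_diagonal_only_crosstab_is_zero(self, dens2020, dens2030):
        xt = TransitionCrosstab(np.diag([10.0] * 7))
        flows = transition_cs_flows(xt, dens2020, dens2030)
        assert flows.abs().to_numpy().max() == 0.0

    def test_farmland_to_forests_100ha(self, dens2020, dens2030):
        """100 ha at the 2030 densities: (151.78 − 68.37) × 100 Mg = 0.8341e4 Mg."""
        M = np.zeros((7, 7))
        M[0, 1] = 100.0
        flows = transition_cs_flows(TransitionCrosstab(M), dens2020, dens2030)
        assert flows.loc[1, 2] == pytest.approx(0.8341, abs=1e-4)

    def test_per_ha_antisymmetry(self, dens2020, dens2030):
        M = np.zeros((7, 7))
        M[0, 1] = 1.0
        M[1, 0] = 1.0
        flows = transition_cs_flows(TransitionCrosstab(M), dens2020, dens2030)
        assert flows.loc[1, 2] == pytest.approx(-flows.loc[2, 1], rel=1e-12)

    def test_start_density_flag(self, dens2020, dens2030):
        M = np.zeros((7, 7))
        M[0, 1] = 100.0
        at_start = transition_cs_flows(
            TransitionCrosstab(M), dens2020, dens2030, from_at_start=True)
        d30 = dens2030.total_density()
        d20 = dens2020.total_density()
        assert at_start.loc[1, 2] == pytest.approx(100 * (d30[2] - d20[1]) / 1e4)


class TestGM11:
    @pytest.mark.parametrize("c, r", [(1.0, 2.0), (3.5, 1.2), (10.0, 0.8)])
    def test_geometric_closed_form(self, c, r):
        """Geometric input c·r^(k−1) gives a = −2(r−1)/(r+1), b = 2c/(r+1)."""
        series = c * r ** np.arange(6)
        m = gm11_fit(series)
        assert m.a == pytest.approx(-2 * (r - 1) / (r + 1), abs=1e-9)
        assert m.b == pytest.approx(2 * c / (r + 1), abs=1e-9)

    def test_constant_series_limit(self):
        m = gm11_fit([7.0, 7.0, 7.0, 7.0])
        assert m.a == pytest.approx(0.0, abs=1e-9)
        assert m.b == pytest.approx(7.0, abs=1e-9)
        assert gm11_predict(m, 5) == pytest.approx(7.0)

    def test_least_squares_orthogonality(self):
        x0 = np.array([3.0, 4.1, 5.7, 7.2, 10.1])
        m = gm11_fit(x0)
        x1 = np.cumsum(x0)
        z = 0.5 * (x1[1:] + x1[:-1])
        resid = x0[1:] - (-m.a * z + m.b)
        assert abs(resid @ z) < 1e-9 * np.abs(z).sum()
        assert abs(resid.sum()) < 1e-9

    def test_predict_anchors_first_observation(self):
        m = gm11_fit([1, 2, 4, 8, 16])
        assert gm11_predict(m, 1) == 1.0

    def test_predict_matches_scalar_oracle(self):
        m = gm11_fit([1, 2, 4, 8, 16])
        a, b = -2.0 / 3.0, 2.0 / 3.0
        oracle = (1.0 - b / a) * (1.0 - np.exp(a)) * np.exp(-a * 5)
        assert gm11_predict(m, 6) == pytest.approx(oracle, rel=1e-9)

    def test_one_step_error_vanishes_toward_geometric(self):
        """In-sample restored values approach the data as it turns geometric."""
        rng = np.random.default_rng(1)
        base = 2.0 * 1.3 ** np.arange(8)
        errs = []
        for noise in (0.2, 0.02, 0.0):
            series = base * (1 + noise * rng.standard_normal(8))
            m = gm11_fit(series)
            rest = np.array([gm11_predict(m, k) for k in range(1, 9)])
            errs.append(np.abs(rest - series)[1:].mean() / base[1:].mean())
        assert errs[2] < errs[0]
        assert errs[2] < 0.05

    @pytest.mark.parametrize("series", [[1.0, 2.0, 3.0], [1.0, -1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0]])
    def test_invalid_series_rejected(self, series):
        with pytest.raises(ValueError):
            gm11_fit(series)


class TestDensityIO:
    def test_round_trip(self, tmp_path, dens2020):
        p = tmp_path / "dens.csv"
        dens2020.write(p)
        back = CarbonDensityTable.read(p, year="2020")
        pd.testing.assert_frame_equal(back.table, dens2020.table)
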