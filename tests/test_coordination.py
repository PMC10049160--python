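"""Land-use intensity, coordination index, classification and SDE."""

import numpy as np
import pytest

from carbonscape import datasets
from carbonscape.coordination import (
    IntensityLevels,
    annual_growth,
    classify_coordination,
    coordination_grid,
    coordination_index,
    lui,
    sde,
)


class TestLUI:
    def test_pure_construction_block(self):
        assert lui({6: 7.5}) == pytest.approx(4 * 7.5)

    def test_two_term_sum(self):
        # 4 km² construction + 5 km² forests -> 4*4 + 2*5 = 26
        assert lui({6: 4.0, 2: 5.0}) == pytest.approx(26.0)

    def test_order_invariance(self):
        a = {1: 2.0, 2: 3.0, 6: 1.0}
        b = {6: 1.0, 1: 2.0, 2: 3.0}
        assert lui(a) == lui(b)

    def test_normalized_variant(self):
        assert lui({6: 4.0, 2: 5.0}, normalize=True) == pytest.approx(26.0 / 9.0)

    def test_default_levels_cover_all_classes(self):
        levels = IntensityLevels()
        assert sorted(levels.levels) == [1, 2, 3, 4, 5, 6, 7]
        assert levels[7] == 1 and levels[1] == 3 and levels[6] == 4


class TestAnnualGrowth:
    def test_no_change_is_zero(self):
        assert annual_growth(5.0, 5.0, 10.0) == 0.0

    def test_forced_arithmetic(self):
        assert annual_growth(100.0, 110.0, 10.0) == pytest.approx(0.01)

    def test_scale_invariance(self):
        assert annual_growth(100.0, 120.0, 5.0) == pytest.approx(
            annual_growth(200.0, 240.0, 5.0))

    def test_zero_base_cases(self):
        assert annual_growth(0.0, 0.0, 10.0) == 0.0
        assert np.isnan(annual_growth(0.0, 3.0, 10.0))


class TestCoordinationIndex:
    def test_balanced_growth(self):
        assert coordination_index(0.03, 0.03) == pytest.approx(np.sqrt(2) / 2)

    def test_opposed_growth(self):
        assert coordination_index(0.02, -0.02) == 0.0

    def test_one_sided_growth(self):
        assert coordination_index(0.05, 0.0) == pytest.approx(0.5)

    def test_scale_invariance_over_rate_grid(self):
        rates = np.linspace(-0.05, 0.05, 11)
        for a in rates:
            for b in rates:
                if a == 0 and b == 0:
                    continue
                assert coordination_index(3 * a, 3 * b) == pytest.approx(
                    coordination_index(a, b), abs=1e-12)

    def test_maximum_attained_only_at_equal_rates(self):
        """The index tops out at sqrt(2)/2, and only where ALUI == ACS."""
        rates = np.linspace(-0.05, 0.05, 41)
        top = np.sqrt(2) / 2
        best = 0.0
        for a in rates:
            for b in rates:
                if a == 0 and b == 0:
                    continue
                o = coordination_index(a, b)
                assert o <= top + 1e-12
                if o > top - 1e-9:
                    assert a == pytest.approx(b, abs=1e-12)
                best = max(best, o)
        assert best == pytest.approx(top, abs=1e-12)

    def test_rms_variant_reaches_one_at_equal_rates(self):
        assert coordination_index(0.03, 0.03, rms=True) == pytest.approx(1.0)
        assert coordination_index(0.05, 0.0, rms=True) == pytest.approx(np.sqrt(2) / 2)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            coordination_index(0.0, 0.0)


class TestClassification:
    def test_adapted_ahead(self):
        o = coordination_index(0.01, 0.01)
        assert classify_coordination(o, 0.01, 0.02) == "adapted/ahead"

    def test_uncoordinated_any_sublabel(self):
        assert classify_coordination(0.2, 0.02, 0.01).startswith("uncoordinated")

    @pytest.mark.parametrize("o, expected", [
        (0.499999, "uncoordinated"), (0.5, "adapted"),
        (0.799999, "adapted"), (0.8, "coordinated"), (1.0, "coordinated"),
    ])
    def test_boundaries(self, o, expected):
        assert classify_coordination(o, 0.01, 0.02).split("/")[0] == expected

    def test_tie_goes_ahead(self):
        assert classify_coordination(0.9, 0.01, 0.01).endswith("ahead")


class TestSDE:
    def test_symmetric_four_points(self):
        pts = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], float)
        e = sde(pts)
        assert e.center == pytest.approx((0.0, 0.0))
        assert e.major == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert e.minor == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert e.area == pytest.approx(np.pi / 2, abs=1e-12)

    def test_collinear_degenerate(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        e = sde(pts)
        assert e.degenerate
        assert e.minor == pytest.approx(0.0, abs=1e-12)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((50, 2)) @ np.diag([3.0, 1.0])
        base = sde(pts)
        phi = np.radians(30.0)
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        rot = sde(pts @ R.T)
        assert rot.major == pytest.approx(base.major, abs=1e-9)
        assert rot.minor == pytest.approx(base.minor, abs=1e-9)
        # counterclockwise point rotation decreases the clockwise-from-north angle
        assert (base.angle_deg - rot.angle_deg) % 180.0 == pytest.approx(30.0, abs=1e-6)

    def test_weights_equal_replication(self):
        pts = np.array([[0, 0], [2, 1], [1, 3], [4, 2]], float)
        w = np.array([1, 3, 2, 1], float)
        weighted = sde(pts, w)
        replicated = sde(np.repeat(pts, w.astype(int), axis=0))
        assert weighted.center == pytest.approx(replicated.center, abs=1e-12)
        assert weighted.major == pytest.approx(replicated.major, abs=1e-12)
        assert weighted.minor == pytest.approx(replicated.minor, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sde(np.array([[0, 0], [1, 1]], float))


class TestCoordinationGrid:
    def test_blocks_and_labels(self, synthetic_triplet):
        _, maps, _, _ = synthetic_triplet
        d20 = datasets.load_dlb_density("2020")
        d30 = datasets.load_dlb_density("2030")
        table = coordination_grid(maps[0], maps[1], d20, d30, years=10.0, block=900.0)
        assert len(table) > 0
        defined = table.dropna(subset=["o"])
        assert ((defined["o"] >= 0) & (defined["o"] <= 1)).all()
        for _, row in defined.iterrows():
            assert row["label"] == classify_coordination(row["o"], row["alui"], row["acs"])

    def test_order_invariant_counts(self, synthetic_triplet):
        _, maps, _, _ = synthetic_triplet
        d20 = datasets.load_dlb_density("2020")
        d30 = datasets.load_dlb_density("2030")
        t1 = coordination_grid(maps[0], maps[1], d20, d30, years=10.0, block=900.0)
        counts1 = t1["label"].value_counts().to_dict()
        t2 = coordination_grid(maps[0], maps[1], d20, d30, years=10.0, block=900.0)
        counts2 = t2.sample(frac=1, random_state=0)["label"].value_counts().to_dict()
        assert counts1 == counts2
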