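"""Detection matching, Accuracy Index, delineation stats, canopy cover."""

import math

import numpy as np
import pytest

from parkland_crowns.accuracy import (ReferenceTree, accuracy_index,
                                      canopy_cover, cluster_reference_area,
                                      crown_area, delineation_stats,
                                      match_detections, read_trees_csv,
                                      write_trees_csv)
from parkland_crowns.raster import BAND_ROLES, SceneRaster


def frame(shape=(40, 40), pixel_size=0.5):
    """Minimal scene carrying only the coordinate transform."""
    return SceneRaster(np.zeros((8, *shape)), BAND_ROLES, pixel_size,
                       (pixel_size, 0, 0, 0, -pixel_size,
                        shape[0] * pixel_size))


def tree(tid, x, y, d1=4.0, d2=4.0, **kw):
    return ReferenceTree(tree_id=tid, x=x, y=y, d1_m=d1, d2_m=d2,
                         dbh_cm=20.0, height_m=5.0, **kw)


class TestCrownArea:
    @pytest.mark.parametrize("d1,d2,expected", [
        (2.0, 2.0, math.pi),
        (10.0, 6.0, 15 * math.pi),
        (0.0, 5.0, 0.0),
    ])
    def test_closed_form(self, d1, d2, expected):
        assert crown_area(d1, d2) == pytest.approx(expected, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            crown_area(-1.0, 2.0)

    def test_d1_d2_swapped_on_construction(self):
        t = tree(1, 0, 0, d1=3.0, d2=5.0)
        assert t.d1_m == 5.0 and t.d2_m == 3.0


class TestAccuracyIndex:
    def test_perfect(self):
        assert accuracy_index(10, 0, 0) == 100.0

    def test_direct(self):
        assert accuracy_index(10, 2, 3) == pytest.approx(50.0)

    def test_negative_allowed(self):
        assert accuracy_index(10, 8, 5) == pytest.approx(-30.0)

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            accuracy_index(0, 0, 0)


class TestMatchDetections:
    def _labels(self, shape, boxes):
        lab = np.zeros(shape, np.int32)
        for i, (r0, r1, c0, c1) in enumerate(boxes, 1):
            lab[r0:r1, c0:c1] = i
        return lab

    def test_single_tree_single_crown(self):
        f = frame()
        lab = self._labels((40, 40), [(10, 20, 10, 20)])
        # crown pixels rows 10..19, cols 10..19 -> map x ~5-10, y ~10-15
        res = match_detections(lab, [tree(1, 7.5, 12.5)], f)
        s = res.summary()
        assert s["ITD_pct"] == 100.0 and s["OE_pct"] == 0.0 \
            and s["CE_pct"] == 0.0 and s["AI_pct"] == 100.0

    def test_two_trees_one_crown_ccd(self):
        f = frame()
        lab = self._labels((40, 40), [(5, 35, 5, 35)])
        res = match_detections(lab, [tree(1, 7.0, 10.0),
                                     tree(2, 12.0, 14.0)], f)
        assert res.ccd == 2 and res.itd == 0
        assert res.crown_trees[1] == [1, 2]

    def test_toy_layout_ai_60(self):
        # 10 trees / 8 crowns; 1 crown treeless, 3 trees uncovered:
        # O = 3, C = 1, AI = (10 - 4)/10 * 100 = 60
        f = frame((60, 60))
        boxes = [(2 + 7 * i, 7 + 7 * i, 2, 7) for i in range(8)]
        lab = self._labels((60, 60), boxes)
        trees = []
        for i in range(7):          # trees 1..7 inside crowns 1..7
            r = 4 + 7 * i
            x, y = 2.25, 30.0 - (r + 0.5) * 0.5
            trees.append(tree(i + 1, x, y, d1=1.0, d2=1.0))
        for i in range(3):          # trees 8..10 far away, no crowns
            trees.append(tree(8 + i, 25.0, 25.0 - 2 * i, d1=1.0, d2=1.0))
        res = match_detections(lab, trees, f)
        assert res.omissions == 3 and res.commissions == 1
        assert res.accuracy_index == pytest.approx(60.0)

    def test_gps_offset_fallback_via_ellipse(self):
        f = frame()
        lab = self._labels((40, 40), [(10, 20, 10, 20)])
        # stem reported 2 m off the crown; 6 m crown footprint still overlaps
        res = match_detections(lab, [tree(1, 3.6, 12.5, d1=6.0, d2=6.0)], f)
        assert res.itd == 1

    def test_duplicate_ids_rejected(self):
        f = frame()
        lab = self._labels((40, 40), [(10, 20, 10, 20)])
        with pytest.raises(ValueError):
            match_detections(lab, [tree(1, 5, 5), tree(1, 6, 6)], f)

    def test_count_conservation(self):
        f = frame((60, 60))
        rng = np.random.default_rng(0)
        lab = self._labels((60, 60), [(5, 20, 5, 20), (25, 40, 25, 40)])
        trees = [tree(i, rng.uniform(0, 30), rng.uniform(0, 30))
                 for i in range(1, 13)]
        res = match_detections(lab, trees, f)
        assert res.itd + res.ccd + res.omissions == res.n == 12


class TestDelineationStats:
    def test_identical_pairs(self):
        st = delineation_stats([(10, 10), (20, 20), (30, 30)])
        assert st.mae_m2 == 0 and st.mre_pct == 0 and st.mbe_m2 == 0
        assert st.r_s == 1.0

    def test_hand_computed_three_pairs(self):
        st = delineation_stats([(10, 12), (20, 18), (30, 33)])
        assert st.mae_m2 == pytest.approx(7 / 3, abs=1e-9)
        assert st.mre_pct == pytest.approx(
            (2 / 10 + 2 / 20 + 3 / 30) / 3 * 100, abs=1e-9)  # ~13.33
        assert st.mbe_m2 == pytest.approx(1.0, abs=1e-9)
        assert st.r_s == pytest.approx(1.0)

    def test_reversed_ranks(self):
        st = delineation_stats([(10, 30), (20, 20), (30, 10)])
        assert st.r_s == pytest.approx(-1.0)

    def test_mae_bounds_mbe_property(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pairs = rng.uniform(1, 100, (6, 2)).tolist()
            st = delineation_stats(pairs)
            assert st.mae_m2 >= abs(st.mbe_m2) - 1e-12

    def test_spearman_monotone_invariance(self):
        pairs = [(3, 5), (8, 2), (15, 40), (30, 22), (50, 90)]
        st1 = delineation_stats(pairs)
        st2 = delineation_stats([(f**2, np.exp(d / 50)) for f, d in pairs])
        assert st1.r_s == pytest.approx(st2.r_s)

    def test_zero_field_pair_excluded_from_mre(self):
        st = delineation_stats([(0.0, 5.0), (10.0, 12.0), (20.0, 18.0)])
        assert st.excluded_pairs == 1
        assert st.mre_pct == pytest.approx((0.2 + 0.1) / 2 * 100)


class TestEq2Identity:
    def test_ai_equals_100_minus_oe_minus_ce(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(10, 500))
            o = int(rng.integers(0, n))
            c = int(rng.integers(0, n))
            ai = accuracy_index(n, o, c)
            assert ai == pytest.approx(100 - o / n * 100 - c / n * 100)


class TestClusterReferenceArea:
    def test_plain_sum(self):
        a = tree(1, 0, 0, d1=math.sqrt(30 * 4 / math.pi),
                 d2=math.sqrt(30 * 4 / math.pi))
        b = tree(2, 0, 0, d1=math.sqrt(50 * 4 / math.pi),
                 d2=math.sqrt(50 * 4 / math.pi))
        assert cluster_reference_area([a, b]) == pytest.approx(80.0)

    def test_three_trees(self):
        ts = [tree(i, 0, 0, d1=2 * math.sqrt(a / math.pi),
                   d2=2 * math.sqrt(a / math.pi))
              for i, a in [(1, 10), (2, 20), (3, 30)]]
        assert cluster_reference_area(ts) == pytest.approx(60.0)


class TestCanopyCover:
    def test_no_crowns(self):
        f = frame((100, 100))
        lab = np.zeros((100, 100), np.int32)
        assert canopy_cover(None, (0, 0, 50, 50), scene=f, labels=lab) == 0.0

    def test_fraction_of_plot(self):
        f = frame((100, 100))
        lab = np.zeros((100, 100), np.int32)
        lab[10:30, 10:60] = 1        # 1000 px = 250 m2 inside 2500 m2 plot
        cc = canopy_cover(None, (0, 0, 50, 50), scene=f, labels=lab)
        assert cc == pytest.approx(10.0)

    def test_clipping_halves_boundary_crown(self):
        f = frame((100, 100))
        lab = np.zeros((100, 100), np.int32)
        lab[40:60, 80:100] = 1       # x in [40,50): half in a 0-45 m plot
        full = 400 * 0.25
        cc = canopy_cover(None, (0, 0, 45, 50), scene=f, labels=lab)
        assert cc == pytest.approx(full / 2 / (45 * 50) * 100)

    def test_reference_side_unclipped(self):
        trees = [tree(1, 10, 10, d1=10.0, d2=10.0)]   # CA = 25 pi
        cc = canopy_cover(trees, (0, 0, 50, 50))
        assert cc == pytest.approx(25 * math.pi / 2500 * 100)


class TestTreeCsv:
    def test_roundtrip_and_dbh_filter(self, tmp_path):
        trees = [tree(1, 5, 5, land_use="fallow", plot_id=3),
                 tree(2, 8, 8)]
        trees[1].dbh_cm = 3.0       # below the 5 cm survey floor
        p = tmp_path / "t.csv"
        write_trees_csv(p, trees)
        back = read_trees_csv(p)
        assert [t.tree_id for t in back] == [1]
        assert back[0].land_use == "fallow" and back[0].plot_id == 3

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("tree_id,x,y\n1,2,3\n")
        with pytest.raises(ValueError, match="missing col"):
            read_trees_csv(p)
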