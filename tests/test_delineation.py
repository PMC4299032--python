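"""Seeding, region growing, cluster splitting and finalisation."""

import heapq

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk
from skimage.feature import peak_local_max

from parkland_crowns.delineation import (CrownObject, Seed,
                                         SpeciesThresholds, SplitConfig,
                                         classify_crown, classify_seed,
                                         delineate_object, delineate_scene,
                                         finalize, find_seed, region_grow,
                                         split_clusters_watershed)
from parkland_crowns.raster import aggregate_to_coarse

from conftest import scene_from_fields


def grow_oracle(seed_ndvi, seed_nir, footprint, ndvi, nir, allowed,
                nd_max, ni_max):
    """Fixpoint iteration with array dilation — independent of the BFS."""
    H, W = allowed.shape
    claimed = np.zeros((H, W), bool)
    for r, c in zip(*footprint):
        if 0 <= r < H and 0 <= c < W and allowed[r, c]:
            claimed[r, c] = True
    admissible = allowed & (seed_ndvi - ndvi < nd_max) & (seed_nir - nir < ni_max)
    struct = np.ones((3, 3), bool)
    while True:
        grown = (ndi.binary_dilation(claimed, struct) & admissible) | claimed
        if np.array_equal(grown, claimed):
            return np.nonzero(claimed)
        claimed = grown


class TestClassifySeed:
    @pytest.mark.parametrize("ndvi,expected", [
        (0.15, 1), (0.20, 1),      # closed upper bound of bin 1
        (0.25, 2), (0.30, 2),      # closed upper bound of bin 2
        (0.35, 3), (0.95, 3),
        (0.10, 1),
    ])
    def test_bins(self, ndvi, expected):
        assert classify_seed(ndvi) == expected

    def test_below_floor_rejected(self):
        with pytest.raises(ValueError):
            classify_seed(0.08)

    def test_thresholds_per_type(self):
        th = SpeciesThresholds()
        assert th.deltas[1] == (0.08, 30.0)
        assert th.deltas[2] == (0.15, 40.0)
        assert th.deltas[3] == (0.18, 50.0)


class TestFindSeed:
    def test_max_cell_and_species(self):
        coarse = np.full((4, 4), 0.05)
        coarse[2, 1] = 0.35
        allowed = np.ones((16, 16), bool)
        s = find_seed(allowed, coarse, np.full((4, 4), 100.0))
        assert s.coarse_cell == (2, 1)
        assert s.species_type == 3

    def test_all_below_floor_none(self):
        coarse = np.full((4, 4), 0.08)
        assert find_seed(np.ones((16, 16), bool), coarse,
                         np.zeros((4, 4))) is None

    def test_tie_break_row_major(self):
        coarse = np.full((4, 4), 0.05)
        coarse[1, 3] = coarse[2, 0] = 0.3
        s = find_seed(np.ones((16, 16), bool), coarse, np.zeros((4, 4)))
        assert s.coarse_cell == (1, 3)


class TestRegionGrow:
    def _seed(self, r, c, ndvi_val, nir_val, species):
        rows = np.repeat(np.arange(r * 4, r * 4 + 4), 4)
        cols = np.tile(np.arange(c * 4, c * 4 + 4), 4)
        return Seed((r, c), (rows, cols), ndvi_val, nir_val, species)

    def test_uniform_plateau_claims_whole_mask(self):
        ndvi = np.full((20, 20), 0.35)
        nir = np.full((20, 20), 150.0)
        allowed = np.zeros((20, 20), bool)
        allowed[4:16, 4:16] = True
        seed = self._seed(2, 2, 0.35, 150.0, 3)
        rr, cc = region_grow(seed, ndvi, nir, allowed, SpeciesThresholds())
        assert len(rr) == allowed.sum()

    def test_blocked_neighbors_footprint_only(self):
        ndvi = np.zeros((12, 12))
        ndvi[4:8, 4:8] = 0.4
        nir = np.zeros((12, 12))
        nir[4:8, 4:8] = 150.0
        allowed = np.ones((12, 12), bool)
        seed = self._seed(1, 1, 0.4, 150.0, 3)
        rr, cc = region_grow(seed, ndvi, nir, allowed, SpeciesThresholds())
        assert sorted(zip(rr, cc)) == sorted(
            (r, c) for r in range(4, 8) for c in range(4, 8))

    def test_radial_ramp_matches_flood_fill(self):
        # NDVI cone from 0.35: admitted iff 0.35 - v < 0.18 -> v > 0.17
        gy, gx = np.mgrid[0:32, 0:32]
        r = np.hypot(gy - 16, gx - 16)
        ndvi = np.clip(0.35 - 0.02 * r, 0.0, None)
        nir = np.full((32, 32), 150.0)
        allowed = np.ones((32, 32), bool)
        seed = self._seed(4, 4, 0.35, 150.0, 3)
        got = set(zip(*region_grow(seed, ndvi, nir, allowed,
                                   SpeciesThresholds())))
        exp = set(zip(*grow_oracle(0.35, 150.0, seed.fine_footprint,
                                   ndvi, nir, allowed, 0.18, 50.0)))
        assert got == exp

    @pytest.mark.parametrize("seed_idx", range(25))
    def test_random_fields_match_oracle(self, seed_idx):
        rng = np.random.default_rng(100 + seed_idx)
        ndvi = ndi.gaussian_filter(rng.uniform(0, 0.5, (64, 64)), 2)
        nir = ndi.gaussian_filter(rng.uniform(50, 170, (64, 64)), 2)
        allowed = ndi.binary_dilation(rng.random((64, 64)) < 0.4)
        R, C = rng.integers(0, 16), rng.integers(0, 16)
        sv = float(aggregate_to_coarse(ndvi, 4)[R, C])
        sn = float(aggregate_to_coarse(nir, 4)[R, C])
        rows = np.repeat(np.arange(R * 4, R * 4 + 4), 4)
        cols = np.tile(np.arange(C * 4, C * 4 + 4), 4)
        st = 1 + int(rng.integers(0, 3))
        seed = Seed((R, C), (rows, cols), sv, sn, st)
        th = SpeciesThresholds()
        got = set(zip(*region_grow(seed, ndvi, nir, allowed, th)))
        exp = set(zip(*grow_oracle(sv, sn, (rows, cols), ndvi, nir, allowed,
                                   th.ndvi_delta(st), th.nir_delta(st))))
        assert got == exp

    def test_threshold_decay_nesting(self):
        rng = np.random.default_rng(5)
        ndvi = ndi.gaussian_filter(rng.uniform(0, 0.5, (48, 48)), 2)
        nir = ndi.gaussian_filter(rng.uniform(60, 170, (48, 48)), 2)
        allowed = np.ones((48, 48), bool)
        sv = float(aggregate_to_coarse(ndvi, 4)[5, 5])
        rows = np.repeat(np.arange(20, 24), 4)
        cols = np.tile(np.arange(20, 24), 4)
        seed = Seed((5, 5), (rows, cols), sv,
                    float(aggregate_to_coarse(nir, 4)[5, 5]), 2)
        th = SpeciesThresholds()
        prev = None
        for scale in (1.0, 0.75, 0.75**2):
            cur = set(zip(*region_grow(seed, ndvi, nir, allowed, th,
                                       scale=scale)))
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestDelineateObject:
    def _grids(self, ndvi, nir):
        return (ndvi, nir, aggregate_to_coarse(ndvi, 4),
                aggregate_to_coarse(nir, 4))

    def test_two_peaks_two_crowns(self):
        gy, gx = np.mgrid[0:24, 0:48]
        p1 = 0.45 - 0.025 * np.hypot(gy - 12, gx - 12)
        p2 = 0.45 - 0.025 * np.hypot(gy - 12, gx - 36)
        ndvi = np.clip(np.maximum(p1, p2), 0, None)
        nir = np.full((24, 48), 150.0)
        mask = ndvi > 0.17
        f, n, cf, cn = self._grids(ndvi, nir)
        crowns, residual = delineate_object(mask, f, n, cf, cn,
                                            SpeciesThresholds())
        assert len(crowns) == 2
        assert not residual.any()
        total = sum(c.n_pixels for c in crowns)
        assert total == int(mask.sum())       # exclusivity + coverage

    def test_single_peak_one_crown(self):
        gy, gx = np.mgrid[0:24, 0:24]
        ndvi = np.clip(0.45 - 0.02 * np.hypot(gy - 12, gx - 12), 0, None)
        nir = np.full((24, 24), 150.0)
        mask = ndvi > 0.2
        f, n, cf, cn = self._grids(ndvi, nir)
        crowns, _ = delineate_object(mask, f, n, cf, cn, SpeciesThresholds())
        assert len(crowns) == 1

    def test_below_seed_floor_no_crowns(self):
        ndvi = np.full((16, 16), 0.07)
        nir = np.full((16, 16), 80.0)
        mask = np.ones((16, 16), bool)
        f, n, cf, cn = self._grids(ndvi, nir)
        crowns, residual = delineate_object(mask, f, n, cf, cn,
                                            SpeciesThresholds())
        assert crowns == []
        assert residual.sum() == 256


class TestClassifyCrown:
    def _obj(self, mask):
        return CrownObject(*np.nonzero(mask))

    def test_compact_blob_itc(self):
        m = np.zeros((30, 30), bool)
        rr, cc = disk((15, 15), 10)
        m[rr, cc] = True
        assert classify_crown(self._obj(m), SplitConfig()) == "itc"

    def test_elongated_is_cluster(self):
        m = np.zeros((20, 80), bool)
        m[5:15, 5:75] = True        # lw = 7 > 1.7
        assert classify_crown(self._obj(m), SplitConfig()) == "crown_cluster"

    def test_oversized_is_cluster(self):
        m = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 29)
        m[rr, cc] = True            # ~660 m2... enlarge via pixel size
        o = self._obj(m)
        assert classify_crown(o, SplitConfig(), pixel_size=0.6) == \
            "crown_cluster"         # 2642 px * 0.36 m2 = 951 m2 > 700


class TestDecayValues:
    def test_species_thresholds_times_decay(self):
        th = SpeciesThresholds()
        assert th.ndvi_delta(2) * 0.75 == pytest.approx(0.1125)
        assert th.nir_delta(2) * 0.75 == pytest.approx(30.0)
        assert th.ndvi_delta(2) * 0.75**2 == pytest.approx(0.084375)
        assert th.nir_delta(2) * 0.75**2 == pytest.approx(22.5)


def watershed_oracle(mask):
    """Priority flood from distance-transform maxima (heap-based)."""
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=3, exclude_border=False,
                           labels=mask)
    lab = np.zeros(mask.shape, np.int32)
    heap, order = [], 0
    for i, (r, c) in enumerate(peaks, 1):
        lab[r, c] = i
        heapq.heappush(heap, (-dist[r, c], order, r, c, i))
        order += 1
    while heap:
        _, _, r, c, i = heapq.heappop(heap)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < mask.shape[0] and 0 <= c2 < mask.shape[1] \
                        and mask[r2, c2] and lab[r2, c2] == 0:
                    lab[r2, c2] = i
                    heapq.heappush(heap, (-dist[r2, c2], order, r2, c2, i))
                    order += 1
    return lab


class TestWatershed:
    def test_convex_blob_unchanged(self):
        m = np.zeros((40, 40), bool)
        rr, cc = disk((20, 20), 15)
        m[rr, cc] = True
        cl = CrownObject(*np.nonzero(m), label="crown_cluster")
        out = split_clusters_watershed([cl], m.shape)
        assert len(out) == 1 and out[0] is cl

    def test_dumbbell_matches_flood_oracle(self):
        m = np.zeros((60, 100), bool)
        rr, cc = disk((30, 34), 20)
        m[rr, cc] = True
        rr, cc = disk((30, 66), 20)
        m[rr, cc] = True
        cl = CrownObject(*np.nonzero(m), label="crown_cluster")
        out = split_clusters_watershed([cl], m.shape)
        assert len(out) == 2
        oracle = watershed_oracle(m)
        got = {frozenset(zip(o.rows.tolist(), o.cols.tolist())) for o in out}
        exp = {frozenset(zip(*np.nonzero(oracle == i)))
               for i in (1, 2)}
        assert got == exp
        # cut through the neck: disk centres end in different regions
        lab_of = {}
        for i, o in enumerate(out):
            for rc in zip(o.rows.tolist(), o.cols.tolist()):
                lab_of[rc] = i
        assert lab_of[(30, 34)] != lab_of[(30, 66)]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((50, 50), bool)
        for _ in range(3):
            rr, cc = disk((rng.integers(12, 38), rng.integers(12, 38)),
                          rng.integers(6, 12), shape=m.shape)
            m[rr, cc] = True
        cl = CrownObject(*np.nonzero(m), label="crown_cluster")
        out = split_clusters_watershed([cl], m.shape)
        rebuilt = np.zeros_like(m)
        total = 0
        for o in out:
            rebuilt[o.rows, o.cols] = True
            total += o.n_pixels
        assert np.array_equal(rebuilt, m)
        assert total == int(m.sum())


class TestFinalize:
    def test_flat_object_false_detection(self):
        scene = scene_from_fields(np.full((20, 20), 0.2),
                                  np.full((20, 20), 90.0))
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        obj = CrownObject(*np.nonzero(m))
        crowns, false_dets = finalize([obj], scene, SplitConfig())
        assert crowns == [] and len(false_dets) == 1
        assert false_dets[0].label == "false_detection"

    def test_heterogeneous_itc_retained(self):
        rng = np.random.default_rng(0)
        nir = 150 + rng.normal(0, 10, (30, 30))
        scene = scene_from_fields(np.full((30, 30), 0.3), nir)
        m = np.zeros((30, 30), bool)
        rr, cc = disk((15, 15), 9)
        m[rr, cc] = True
        obj = CrownObject(*np.nonzero(m))
        crowns, false_dets = finalize([obj], scene, SplitConfig())
        assert len(crowns) == 1 and false_dets == []

    def test_touching_clusters_merged_area_conserved(self):
        rng = np.random.default_rng(1)
        nir = 150 + rng.normal(0, 10, (30, 80))
        scene = scene_from_fields(np.full((30, 80), 0.3), nir)
        m1 = np.zeros((30, 80), bool)
        m1[5:25, 5:40] = True
        m2 = np.zeros((30, 80), bool)
        m2[5:25, 40:75] = True       # touches m1 at column 39/40
        o1 = CrownObject(*np.nonzero(m1), label="crown_cluster")
        o2 = CrownObject(*np.nonzero(m2), label="crown_cluster")
        crowns, _ = finalize([o1, o2], scene, SplitConfig())
        clusters = [c for c in crowns if c.label == "crown_cluster"]
        assert len(clusters) == 1
        assert clusters[0].n_pixels == int(m1.sum() + m2.sum())


class TestDelineateScene:
    def test_blank_scene_zero_crowns(self):
        scene = scene_from_fields(np.zeros((40, 40)), np.zeros((40, 40)))
        cmap = delineate_scene(scene)
        assert cmap.crowns == []
        assert not cmap.labels.any()

    def test_label_raster_matches_objects_and_exclusivity(self, easy_crown_map):
        cmap = easy_crown_map
        seen = np.zeros(cmap.labels.shape, bool)
        for o in cmap.crowns:
            assert not seen[o.rows, o.cols].any()     # no double claim
            seen[o.rows, o.cols] = True
            assert (cmap.labels[o.rows, o.cols] == o.crown_id).all()
        # every crown pixel lies inside the tree mask
        assert cmap.tree_mask.grid[seen].all()

    def test_itc_gates_hold_on_outputs(self, easy_crown_map):
        cfg = SplitConfig()
        for o in easy_crown_map.crowns:
            if o.label == "itc":
                assert o.features["length_width"] <= cfg.lw_max
                assert o.features["roundness"] <= cfg.roundness_max
                assert o.area_m2(0.5) <= cfg.area_max_m2

    def test_determinism(self, easy_scene):
        _, scene, _ = easy_scene
        a = delineate_scene(scene)
        b = delineate_scene(scene)
        assert np.array_equal(a.labels, b.labels)
        assert a.feature_table().equals(b.feature_table())
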