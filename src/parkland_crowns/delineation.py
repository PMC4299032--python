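"""Crown delineation: from tree mask to individual tree crowns.

The delineation stage turns each connected tree-mask object into one or more
crown objects:

1. **Seeding** — within each mask object the radiometric maximum of the
   coarse-grid (2 m) NDVI is taken as the tree top.  Seeds with mean NDVI
   below 0.1 are rejected (sparse field-layer vegetation and bare ground
   produce spurious maxima below that level).
2. **Species typing** — seed mean NDVI classifies the seed into one of three
   spectral species types with type-specific growth thresholds
   (NDVI delta 0.08/0.15/0.18, NIR delta 30/40/50): low-LAI crowns contrast
   less with the background and need tighter thresholds.
3. **Region growing** — breadth-first expansion from the seed footprint into
   8-connected unclaimed mask pixels.  A pixel is admitted while the drop
   from the seed stays below both thresholds (seed minus pixel, one-sided: a
   sharp decrease in NDVI and NIR marks the crown edge; brighter pixels are
   always admitted).  Seeding/growth repeats until no seed qualifies.
4. **Geometric classification** — elongated (length/width > 1.7), irregular
   (roundness > 0.6) or oversized (> 700 m2) objects are crown clusters;
   the rest are individual tree crowns (ITC).
5. **Spectral cluster splitting** — two cycles re-run seeding + growth on
   each cluster with thresholds decayed by 0.75 per cycle, resolving subtle
   internal crown edges; newly qualifying ITCs leave the splitting pool.
6. **Watershed splitting** — clusters that survive both cycles are split on
   shape alone: marker-based watershed on the inverted interior distance
   transform (local maxima of the distance to the object border seed a
   flood that stops where regions meet).
7. **Finalisation** — spectrally flat objects (NIR s.d. < 4 and red-edge
   s.d. < 3) are false detections and removed; survivors are re-classified
   and adjacent crown clusters merged.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .mask import MaskConfig, TreeMask, UnderstoryRule, build_tree_mask
from .objects import ImageObject, compute_features, connected_components
from .raster import SceneRaster, aggregate_to_coarse, compute_ndvi

__all__ = [
    "Seed",
    "SpeciesThresholds",
    "CrownObject",
    "SplitConfig",
    "CrownMap",
    "find_seed",
    "classify_seed",
    "region_grow",
    "delineate_object",
    "classify_crown",
    "split_clusters_spectral",
    "split_clusters_watershed",
    "finalize",
    "delineate_scene",
]

SEED_NDVI_MIN = 0.1


@dataclass
class Seed:
    """A coarse-grid radiometric maximum assumed to mark a tree top."""

    coarse_cell: tuple          # (row, col) on the coarse grid
    fine_footprint: tuple       # (rows, cols) arrays of covered fine pixels
    mean_ndvi: float
    mean_nir: float
    species_type: int


@dataclass
class SpeciesThresholds:
    """Region-growing thresholds per spectral species type.

    Keys are species types 1..3; values are (ndvi_delta, nir_delta).
    Defaults: type 1 (seed NDVI 0.1-0.2) -> (0.08, 30); type 2 (>0.2-0.3)
    -> (0.15, 40); type 3 (>0.3) -> (0.18, 50).
    """

    deltas: dict = field(default_factory=lambda: {
        1: (0.08, 30.0), 2: (0.15, 40.0), 3: (0.18, 50.0)})

    def __post_init__(self):
        for t, (nd, ni) in self.deltas.items():
            if nd <= 0 or ni <= 0:
                raise ValueError(f"thresholds for type {t} must be > 0")

    def ndvi_delta(self, species_type: int) -> float:
        return self.deltas[species_type][0]

    def nir_delta(self, species_type: int) -> float:
        return self.deltas[species_type][1]


@dataclass
class SplitConfig:
    """Cluster-splitting and finalisation parameters."""

    decay_factor: float = 0.75
    cycles: int = 2
    lw_max: float = 1.7
    roundness_max: float = 0.6
    area_max_m2: float = 700.0
    false_nir_sd_max: float = 4.0
    false_re_sd_max: float = 3.0
    false_rule_combine: str = "and"   # "and" (conservative) | "or"
    # crowns smaller than one coarse seed cell (2 m pixel) are below the
    # resolving power of the seeding grid
    min_crown_area_m2: float = 4.0

    def __post_init__(self):
        if not 0 < self.decay_factor < 1:
            raise ValueError("decay_factor must be in (0, 1)")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")


@dataclass
class CrownObject:
    """A delineated crown region: ITC, crown cluster or false detection."""

    rows: np.ndarray
    cols: np.ndarray
    label: str = "itc"            # itc | crown_cluster | false_detection
    generation: str = "initial"   # initial | split_cycle_1 | split_cycle_2
    #                             # | watershed | merged
    species_type: int | None = None
    seed_ndvi: float | None = None
    crown_id: int = 0
    features: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)

    def area_m2(self, pixel_size: float = 0.5) -> float:
        return self.n_pixels * pixel_size**2

    def as_image_object(self, pixel_size: float = 0.5) -> ImageObject:
        return ImageObject(self.rows, self.cols, pixel_size=pixel_size,
                           label=self.crown_id)


def classify_seed(mean_ndvi: float) -> int:
    """Species type from seed mean NDVI (bins with closed upper bounds).

    Raises ValueError below the 0.1 seed floor.
    """
    if mean_ndvi < SEED_NDVI_MIN:
        raise ValueError(f"seed NDVI {mean_ndvi} below the 0.1 floor")
    if mean_ndvi <= 0.2:
        return 1
    if mean_ndvi <= 0.3:
        return 2
    return 3


def find_seed(allowed: np.ndarray, coarse_ndvi: np.ndarray,
              coarse_nir: np.ndarray, factor: int = 4,
              obj_mask: np.ndarray | None = None) -> Seed | None:
    """Locate the best seed for the unclaimed region ``allowed``.

    Scans coarse cells whose fine footprint intersects the region and
    returns the radiometric maximum: the cell with maximal mean NDVI that
    is also a local NDVI maximum among the coarse cells of the containing
    mask object (``obj_mask``, default: the region itself) — a tree top,
    not the shoulder of an already-claimed crown.  Ties break to the lower
    row, then lower column.  Returns None when no cell qualifies at the
    0.1 NDVI floor.
    """
    rr, cc = np.nonzero(allowed)
    if rr.size == 0:
        return None
    if obj_mask is None:
        obj_mask = allowed
    orr, occ = np.nonzero(obj_mask)
    obj_cells = set(map(tuple, np.unique(
        np.stack([orr // factor, occ // factor], axis=1), axis=0).tolist()))
    cells = np.unique(np.stack([rr // factor, cc // factor], axis=1), axis=0)
    best = None
    for R, C in cells:
        v = coarse_ndvi[R, C]
        if v < SEED_NDVI_MIN:
            continue
        is_peak = all(
            v >= coarse_ndvi[R + dR, C + dC] - 1e-12
            for dR in (-1, 0, 1) for dC in (-1, 0, 1)
            if (dR, dC) != (0, 0) and (R + dR, C + dC) in obj_cells)
        if not is_peak:
            continue
        if best is None or v > best[0] + 1e-12:
            best = (v, int(R), int(C))
    if best is None:
        return None
    v, R, C = best
    fr = np.arange(R * factor, min((R + 1) * factor, allowed.shape[0]))
    fc = np.arange(C * factor, min((C + 1) * factor, allowed.shape[1]))
    rows = np.repeat(fr, len(fc))
    cols = np.tile(fc, len(fr))
    return Seed((R, C), (rows, cols), float(v), float(coarse_nir[R, C]),
                classify_seed(float(v)))


def region_grow(seed: Seed, ndvi_fine: np.ndarray, nir_fine: np.ndarray,
                allowed: np.ndarray, th: SpeciesThresholds,
                scale: float = 1.0) -> tuple:
    """Constrained breadth-first growth from the seed footprint.

    A neighbouring unclaimed pixel is admitted iff
    ``seed_ndvi - ndvi[pixel] < ndvi_delta * scale`` and
    ``seed_nir - nir[pixel] < nir_delta * scale`` (one-sided: pixels
    brighter/greener than the seed always pass).  Returns ``(rows, cols)``
    of the claimed pixels; at minimum the seed footprint within ``allowed``.
    """
    nd_max = th.ndvi_delta(seed.species_type) * scale
    ni_max = th.nir_delta(seed.species_type) * scale
    H, W = allowed.shape
    claimed = np.zeros((H, W), dtype=bool)
    q = deque()
    fr, fc = seed.fine_footprint
    for r, c in zip(fr, fc):
        if 0 <= r < H and 0 <= c < W and allowed[r, c]:
            claimed[r, c] = True
            q.append((int(r), int(c)))
    while q:
        r, c = q.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < H and 0 <= c2 < W):
                    continue
                if claimed[r2, c2] or not allowed[r2, c2]:
                    continue
                if (seed.mean_ndvi - ndvi_fine[r2, c2] < nd_max
                        and seed.mean_nir - nir_fine[r2, c2] < ni_max):
                    claimed[r2, c2] = True
                    q.append((r2, c2))
    return np.nonzero(claimed)


def delineate_object(obj_mask: np.ndarray, ndvi_fine: np.ndarray,
                     nir_fine: np.ndarray, coarse_ndvi: np.ndarray,
                     coarse_nir: np.ndarray, th: SpeciesThresholds,
                     scale: float = 1.0, factor: int = 4,
                     generation: str = "initial"):
    """Repeated seeding + growth until a mask object is fully covered.

    Returns ``(crowns, unclaimed_mask)``.  Residual pixels below the seed
    floor are attached to the adjacent crown whose seed NDVI is closest to
    the residual's mean NDVI; residuals with no adjacent crown stay
    unclaimed.
    """
    allowed = obj_mask.copy()
    crowns: list[CrownObject] = []
    while True:
        seed = find_seed(allowed, coarse_ndvi, coarse_nir, factor,
                         obj_mask=obj_mask)
        if seed is None:
            break
        rr, cc = region_grow(seed, ndvi_fine, nir_fine, allowed, th, scale)
        if rr.size == 0:
            # seed footprint no longer intersects the unclaimed set; mark the
            # cell's pixels as unusable to guarantee termination
            fr, fc = seed.fine_footprint
            ok = (fr < allowed.shape[0]) & (fc < allowed.shape[1])
            allowed[fr[ok], fc[ok]] = False
            continue
        allowed[rr, cc] = False
        crowns.append(CrownObject(rr, cc, generation=generation,
                                  species_type=seed.species_type,
                                  seed_ndvi=seed.mean_ndvi))
    # attach residual unclaimed components to the most similar adjacent crown
    residual = allowed & obj_mask
    if residual.any() and crowns:
        lab, n = ndi.label(residual, structure=np.ones((3, 3), dtype=bool))
        claim_map = np.zeros(obj_mask.shape, dtype=np.int64)
        for i, cr in enumerate(crowns, start=1):
            claim_map[cr.rows, cr.cols] = i
        for j in range(1, n + 1):
            rr, cc = np.nonzero(lab == j)
            mean_nd = float(ndvi_fine[rr, cc].mean())
            dil = ndi.binary_dilation(lab == j,
                                      structure=np.ones((3, 3), dtype=bool))
            neighbours = np.unique(claim_map[dil & (claim_map > 0)])
            if neighbours.size == 0:
                continue
            best = min(neighbours,
                       key=lambda i: (abs(crowns[i - 1].seed_ndvi - mean_nd),
                                      int(i)))
            cr = crowns[best - 1]
            cr.rows = np.concatenate([cr.rows, rr])
            cr.cols = np.concatenate([cr.cols, cc])
            residual[rr, cc] = False
    return crowns, residual


def classify_crown(obj: CrownObject, cfg: SplitConfig,
                   pixel_size: float = 0.5) -> str:
    """ITC vs crown cluster from geometry: a cluster is elongated
    (length/width > 1.7) OR irregular (roundness > 0.6) OR oversized
    (area > 700 m2)."""
    f = obj.features
    if "length_width" not in f or "roundness" not in f:
        io = obj.as_image_object(pixel_size)
        f.update(compute_features(io))
    if (f["length_width"] > cfg.lw_max or f["roundness"] > cfg.roundness_max
            or obj.area_m2(pixel_size) > cfg.area_max_m2):
        return "crown_cluster"
    return "itc"


def _featureize(obj: CrownObject, scene: SceneRaster, ndvi) -> None:
    io = obj.as_image_object(scene.pixel_size)
    obj.features = compute_features(io, scene, ndvi)


def split_clusters_spectral(clusters, ndvi_fine, nir_fine, coarse_ndvi,
                            coarse_nir, th: SpeciesThresholds,
                            cfg: SplitConfig, scene: SceneRaster,
                            ndvi_for_features=None, factor: int = 4):
    """Two decay cycles of re-seeding and re-growth inside crown clusters.

    Cycle c uses thresholds scaled by ``decay_factor ** c``; results that
    classify as ITC leave the splitting pool.  Returns
    ``(itcs, remaining_clusters)``.
    """
    shape = ndvi_fine.shape
    itcs: list[CrownObject] = []
    pool = list(clusters)
    for c in range(1, cfg.cycles + 1):
        scale = cfg.decay_factor**c
        nxt = []
        for cl in pool:
            m = np.zeros(shape, dtype=bool)
            m[cl.rows, cl.cols] = True
            parts, residual = delineate_object(
                m, ndvi_fine, nir_fine, coarse_ndvi, coarse_nir, th,
                scale=scale, factor=factor, generation=f"split_cycle_{c}")
            if residual.any():
                # below-seed residual with no adjacent crown: keep with the
                # largest part so splitting conserves the cluster's pixels
                rr, cc = np.nonzero(residual)
                if parts:
                    big = max(parts, key=lambda p: p.n_pixels)
                    big.rows = np.concatenate([big.rows, rr])
                    big.cols = np.concatenate([big.cols, cc])
                else:
                    parts = [CrownObject(rr, cc, generation=f"split_cycle_{c}",
                                         species_type=cl.species_type,
                                         seed_ndvi=cl.seed_ndvi)]
            # fringe parts below the seeding-grid resolution fold into the
            # largest part rather than becoming crowns of their own
            min_px = cfg.min_crown_area_m2 / scene.pixel_size**2
            if len(parts) > 1:
                parts.sort(key=lambda p: p.n_pixels, reverse=True)
                keep_parts, fringe = [parts[0]], []
                for p in parts[1:]:
                    (keep_parts if p.n_pixels >= min_px else fringe).append(p)
                for p in fringe:
                    keep_parts[0].rows = np.concatenate(
                        [keep_parts[0].rows, p.rows])
                    keep_parts[0].cols = np.concatenate(
                        [keep_parts[0].cols, p.cols])
                parts = keep_parts
            if len(parts) == 1:
                # no split achieved; keep original object and label
                parts[0].generation = cl.generation
            for p in parts:
                _featureize(p, scene, ndvi_for_features)
                p.label = classify_crown(p, cfg, scene.pixel_size)
                if p.label == "itc":
                    itcs.append(p)
                else:
                    nxt.append(p)
        pool = nxt
    return itcs, pool


def _absorb_small_regions(lab: np.ndarray, min_px: int) -> np.ndarray:
    """Merge labelled regions smaller than ``min_px`` into the neighbouring
    region with the longest shared border (iteratively, smallest first)."""
    lab = lab.copy()
    struct = np.ones((3, 3), dtype=bool)
    while True:
        ids, counts = np.unique(lab[lab > 0], return_counts=True)
        if len(ids) <= 1:
            break
        small = ids[counts < min_px]
        if small.size == 0:
            break
        j = small[np.argmin(counts[counts < min_px])]
        sel = lab == j
        ring = ndi.binary_dilation(sel, structure=struct) & ~sel
        neigh = lab[ring]
        neigh = neigh[neigh > 0]
        if neigh.size == 0:
            break
        vals, vc = np.unique(neigh, return_counts=True)
        lab[sel] = vals[np.argmax(vc)]
    return lab


def split_clusters_watershed(clusters, shape, pixel_size: float = 0.5,
                             min_region_px: int | None = None):
    """Shape-based splitting of the remaining clusters.

    For each cluster the Euclidean distance to the object border is
    computed; its local maxima (minima of the inverted distance) seed a
    marker-based watershed that floods until regions meet.  The output
    regions partition the cluster exactly; single-marker clusters pass
    through unchanged.  Pieces smaller than ``min_region_px`` (default: one
    2 m seed cell) merge into their largest neighbour.
    """
    if min_region_px is None:
        min_region_px = int(round(4.0 / pixel_size**2))
    out: list[CrownObject] = []
    for cl in clusters:
        m = np.zeros(shape, dtype=bool)
        m[cl.rows, cl.cols] = True
        sl = ndi.find_objects(m.astype(np.int8))[0]
        pad = (slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, shape[0])),
               slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, shape[1])))
        sub = m[pad]
        dist = ndi.distance_transform_edt(sub)
        peaks = peak_local_max(dist, min_distance=3, exclude_border=False,
                               labels=sub)
        if len(peaks) <= 1:
            out.append(cl)
            continue
        markers = np.zeros(sub.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        lab = watershed(-dist, markers, mask=sub)
        lab = _absorb_small_regions(lab, min_region_px)
        pieces = [np.nonzero(lab == i) for i in np.unique(lab[lab > 0])]
        if len(pieces) == 1:
            out.append(cl)
            continue
        for rr, cc in pieces:
            out.append(CrownObject(
                rr + pad[0].start, cc + pad[1].start, generation="watershed",
                species_type=cl.species_type, seed_ndvi=cl.seed_ndvi))
    return out


def finalize(objects, scene: SceneRaster, cfg: SplitConfig, ndvi=None):
    """False-detection removal, re-classification and cluster merging.

    Objects with NIR s.d. below 4 and red-edge s.d. below 3 are spectrally
    flat field-layer patches: labelled false_detection and excluded (but
    returned for logging).  Survivors are re-classified geometrically and
    adjacent crown clusters merged (8-connectivity) to undo
    over-segmentation of compact clusters.
    Returns ``(crowns, false_detections)``.
    """
    nir = scene.band("nir1")
    re_ = scene.band("red_edge")
    keep, false_dets = [], []
    min_px = cfg.min_crown_area_m2 / scene.pixel_size**2
    for obj in objects:
        nir_sd = float(nir[obj.rows, obj.cols].std(ddof=0))
        re_sd = float(re_[obj.rows, obj.cols].std(ddof=0))
        flat_nir = nir_sd < cfg.false_nir_sd_max
        flat_re = re_sd < cfg.false_re_sd_max
        is_false = (flat_nir and flat_re) if cfg.false_rule_combine == "and" \
            else (flat_nir or flat_re)
        if obj.n_pixels < min_px:
            is_false = True
        if is_false:
            obj.label = "false_detection"
            false_dets.append(obj)
        else:
            keep.append(obj)
    for obj in keep:
        _featureize(obj, scene, ndvi)
        obj.label = classify_crown(obj, cfg, scene.pixel_size)
    # merge adjacent crown clusters
    clusters = [o for o in keep if o.label == "crown_cluster"]
    itcs = [o for o in keep if o.label == "itc"]
    if len(clusters) >= 2:
        cl_map = np.zeros(scene.shape, dtype=np.int64)
        for i, o in enumerate(clusters, start=1):
            cl_map[o.rows, o.cols] = i
        lab, n = ndi.label(cl_map > 0, structure=np.ones((3, 3), dtype=bool))
        merged = []
        for j in range(1, n + 1):
            members = np.unique(cl_map[lab == j])
            members = members[members > 0]
            if len(members) == 1:
                merged.append(clusters[members[0] - 1])
                continue
            rr, cc = np.nonzero(lab == j)
            mo = CrownObject(rr, cc, label="crown_cluster",
                             generation="merged",
                             species_type=clusters[members[0] - 1].species_type,
                             seed_ndvi=clusters[members[0] - 1].seed_ndvi)
            _featureize(mo, scene, ndvi)
            merged.append(mo)
        clusters = merged
    crowns = itcs + clusters
    for i, o in enumerate(crowns, start=1):
        o.crown_id = i
    return crowns, false_dets


@dataclass
class CrownMap:
    """Final delineation product: labelled raster + crown objects."""

    labels: np.ndarray            # 0 = background, i = crown_id
    crowns: list
    false_detections: list
    tree_mask: TreeMask
    scene: SceneRaster

    def feature_table(self) -> pd.DataFrame:
        rows = []
        for o in self.crowns:
            rec = {"crown_id": o.crown_id, "label": o.label,
                   "generation": o.generation,
                   "species_type": o.species_type,
                   "seed_ndvi": o.seed_ndvi,
                   "area_m2": o.area_m2(self.scene.pixel_size)}
            rec.update({k: v for k, v in o.features.items()
                        if isinstance(v, (int, float))})
            rows.append(rec)
        return pd.DataFrame(rows)


def delineate_scene(scene: SceneRaster, mask_cfg: MaskConfig | None = None,
                    split_cfg: SplitConfig | None = None,
                    th: SpeciesThresholds | None = None,
                    understory_rule: UnderstoryRule | None = None,
                    nir_role: str = "nir1", red_role: str = "red") -> CrownMap:
    """Run the full pipeline on one scene; deterministic given the config."""
    mask_cfg = mask_cfg or MaskConfig()
    split_cfg = split_cfg or SplitConfig()
    th = th or SpeciesThresholds()
    factor = max(1, round(2.0 / scene.pixel_size))  # coarse grid = 2 m cells

    ndvi = compute_ndvi(scene, nir_role, red_role)
    nir_fine = scene.band(nir_role)
    tree_mask = build_tree_mask(scene, ndvi, mask_cfg, understory_rule)
    coarse_ndvi = aggregate_to_coarse(ndvi.values, factor)
    coarse_nir = aggregate_to_coarse(nir_fine, factor)

    itcs: list[CrownObject] = []
    clusters: list[CrownObject] = []
    for mobj in connected_components(tree_mask.grid, mask_cfg.connectivity,
                                     scene.pixel_size):
        m = np.zeros(scene.shape, dtype=bool)
        m[mobj.rows, mobj.cols] = True
        crowns, _residual = delineate_object(
            m, ndvi.values, nir_fine, coarse_ndvi, coarse_nir, th,
            scale=1.0, factor=factor)
        for cr in crowns:
            _featureize(cr, scene, ndvi)
            cr.label = classify_crown(cr, split_cfg, scene.pixel_size)
            (itcs if cr.label == "itc" else clusters).append(cr)

    new_itcs, clusters = split_clusters_spectral(
        clusters, ndvi.values, nir_fine, coarse_ndvi, coarse_nir, th,
        split_cfg, scene, ndvi, factor)
    itcs.extend(new_itcs)
    pieces = split_clusters_watershed(clusters, scene.shape,
                                      scene.pixel_size)
    crowns, false_dets = finalize(itcs + pieces, scene, split_cfg, ndvi)

    labels = np.zeros(scene.shape, dtype=np.int32)
    for o in crowns:
        labels[o.rows, o.cols] = o.crown_id
    return CrownMap(labels, crowns, false_dets, tree_mask, scene)
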