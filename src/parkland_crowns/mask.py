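"""Tree-cover mask extraction.

Separates tree cover from the field layer (bare soil, crops, grass, shrubs,
tree re-growth) in four stages:

1. **Iterative NDVI object extraction** — thresholds the NDVI image at an
   increasing sequence of cut-offs (0.05 to 0.2 in 0.05 steps); at each step
   connected candidate objects below a 1500 m2 area gate are accepted into
   the mask when their shape is crown-like (low roundness, high elliptical
   fit) and their NIR variability is high (s.d. > 8, crowns mix leaf and
   branch reflectance).  Accepted objects are frozen: their pixels are not
   re-litigated at higher thresholds.  This catches low-LAI crowns whose
   NDVI never reaches the final threshold.
2. **Large-object refinement** — objects that stay above the area gate are
   partitioned by a region-merging segmentation whose merge-cost ceiling is
   the scale parameter; homogeneous sub-objects (NIR s.d. < 4 — grass and
   crop patches) are discarded, heterogeneous ones join the mask.
3. **ISODATA refinement** — unsupervised clustering of the 8-band values
   inside the mask (many clusters to limit class mixing); clusters matching
   the understory rule (spectrally flat regrowth/shrub signatures) are
   removed.
4. **Hole filling** — small enclosed background objects (< 50 m2: hollow,
   shadowed or sun-lit crown sections) are reintegrated.

Stages 1–2 only add pixels, stage 3 only removes, stage 4 only adds; every
change is recorded in a provenance log so pixel accounting can be audited.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from sklearn.cluster import KMeans

from .objects import (ImageObject, band_stats, connected_components,
                      elliptical_fit, roundness)

__all__ = [
    "MaskConfig",
    "TreeMask",
    "UnderstoryRule",
    "iterative_ndvi_extraction",
    "refine_oversize",
    "isodata_refinement",
    "fill_small_holes",
    "build_tree_mask",
    "region_merge_segmentation",
]


@dataclass
class MaskConfig:
    """Thresholds governing tree-mask extraction (defaults calibrated for
    WorldView-2-style imagery on a TOA-radiance scale)."""

    min_thresh: float = 0.05          # NDVI start threshold
    step: float = 0.05                # NDVI increment
    max_thresh: float = 0.2           # NDVI stop threshold
    max_candidate_area_m2: float = 1500.0
    roundness_max: float = 0.6
    elliptical_fit_min: float = 0.7
    nir_sd_min: float = 8.0
    large_object_area_m2: float = 700.0
    mr_scale: float = 20.0            # region-merging cost ceiling
    isodata_clusters: int = 50
    nir_sd_background_max: float = 4.0
    hole_fill_area_m2: float = 50.0
    connectivity: int = 8
    ellipse_gate_inverted: bool = False  # True = literal "< 0.7" reading
    gate_combine: str = "and"            # "and" | "or" for the shape gates
    rng_seed: int = 0

    def __post_init__(self):
        if not self.min_thresh < self.max_thresh:
            raise ValueError("min_thresh must be < max_thresh")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        for name in ("max_candidate_area_m2", "large_object_area_m2",
                     "hole_fill_area_m2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def thresholds(self):
        ts = []
        t = self.min_thresh
        while t <= self.max_thresh + 1e-9:
            ts.append(round(t, 9))
            t += self.step
        return ts


@dataclass
class TreeMask:
    """Boolean tree-cover grid plus a per-stage provenance log."""

    grid: np.ndarray
    provenance: list = field(default_factory=list)

    def log(self, stage: str, added: int, removed: int):
        self.provenance.append(
            {"stage": stage, "added": int(added), "removed": int(removed),
             "total": int(self.grid.sum())}
        )

    def audit_balanced(self) -> bool:
        """True when the provenance log accounts for every pixel change."""
        total = 0
        for rec in self.provenance:
            total += rec["added"] - rec["removed"]
            if rec["total"] != total:
                return False
        return total == int(self.grid.sum())


def _shape_gate(obj: ImageObject, nir_grid, cfg: MaskConfig) -> bool:
    """Crown candidate gate: crown-like shape AND heterogeneous NIR.

    The NIR test runs first (cheap); the enclosing/enclosed-ellipse
    roundness runs last (expensive).
    """
    _, nir_sd = band_stats(obj, nir_grid)
    if nir_sd <= cfg.nir_sd_min:
        return False
    ef = elliptical_fit(obj)
    ef_ok = (ef < cfg.elliptical_fit_min) if cfg.ellipse_gate_inverted \
        else (ef > cfg.elliptical_fit_min)
    if cfg.gate_combine == "or" and ef_ok:
        return True
    if cfg.gate_combine == "and" and not ef_ok:
        return False
    return roundness(obj) < cfg.roundness_max


def iterative_ndvi_extraction(ndvi, scene, cfg: MaskConfig):
    """Stage 1: threshold-sweep object extraction.

    Returns ``(mask, oversize)`` where ``mask`` is a TreeMask of accepted
    (frozen) crown-like objects and ``oversize`` the objects that still
    exceed the candidate-area gate at the final threshold.
    """
    vals = ndvi.values if hasattr(ndvi, "values") else np.asarray(ndvi)
    nir = scene.band("nir1")
    accepted = np.zeros(vals.shape, dtype=bool)
    oversize = []
    last_t = cfg.thresholds()[-1]
    for t in cfg.thresholds():
        candidate = (vals >= t) & ~accepted
        if not candidate.any():
            continue
        for obj in connected_components(candidate, cfg.connectivity,
                                        scene.pixel_size):
            if obj.area_m2 < cfg.max_candidate_area_m2:
                if _shape_gate(obj, nir, cfg):
                    accepted[obj.rows, obj.cols] = True
            elif t == last_t:
                oversize.append(obj)
    mask = TreeMask(accepted)
    mask.log("iterative_ndvi", added=int(accepted.sum()), removed=0)
    return mask, oversize


# ---------------------------------------------------------------------------
# Region-merging segmentation (stage 2)
# ---------------------------------------------------------------------------

class _RegionStats:
    """Incremental per-band sum/sum-of-squares for merge-cost evaluation."""

    __slots__ = ("n", "s", "ss")

    def __init__(self, v):
        self.n = 1
        self.s = v.copy()
        self.ss = v * v

    def heterogeneity(self):
        # n * sd summed over bands (area-weighted spectral heterogeneity)
        var = np.maximum(self.ss / self.n - (self.s / self.n) ** 2, 0.0)
        return self.n * np.sqrt(var).sum()

    def merged_heterogeneity(self, other):
        n = self.n + other.n
        s = self.s + other.s
        ss = self.ss + other.ss
        var = np.maximum(ss / n - (s / n) ** 2, 0.0)
        return n * np.sqrt(var).sum()

    def absorb(self, other):
        self.n += other.n
        self.s += other.s
        self.ss += other.ss


def region_merge_segmentation(values: np.ndarray, mask: np.ndarray,
                              scale: float) -> np.ndarray:
    """Greedy pairwise region merging on the 4-connected pixel graph.

    ``values`` is (bands, rows, cols); merging proceeds cheapest-first while
    the merge cost — the increase in area-weighted per-band standard
    deviation — stays below ``scale`` squared (the usual convention: region
    size grows roughly linearly with the scale parameter).  Returns an int
    label grid (0 outside the mask), labels compacted in row-major order of
    first pixel.
    """
    ceiling = float(scale) ** 2
    rr, cc = np.nonzero(mask)
    n = rr.size
    if n == 0:
        return np.zeros(mask.shape, dtype=np.int32)
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[rr, cc] = np.arange(n)
    vecs = np.asarray(values, dtype=np.float64)[:, rr, cc].T  # (n, bands)

    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    stats = [_RegionStats(vecs[i]) for i in range(n)]
    het = [0.0] * n
    adj = [set() for _ in range(n)]
    for k in range(n):
        r, c = rr[k], cc[k]
        if r + 1 < mask.shape[0] and idx[r + 1, c] >= 0:
            adj[k].add(int(idx[r + 1, c]))
            adj[int(idx[r + 1, c])].add(k)
        if c + 1 < mask.shape[1] and idx[r, c + 1] >= 0:
            adj[k].add(int(idx[r, c + 1]))
            adj[int(idx[r, c + 1])].add(k)

    heap = []
    for a in range(n):
        for b in adj[a]:
            if a < b:
                cost = stats[a].merged_heterogeneity(stats[b]) - het[a] - het[b]
                heapq.heappush(heap, (cost, a, b))

    while heap:
        cost, a, b = heapq.heappop(heap)
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        # stale entry: re-evaluate at current roots
        cur = stats[ra].merged_heterogeneity(stats[rb]) - het[ra] - het[rb]
        if cur > cost + 1e-12:
            if cur < ceiling:
                heapq.heappush(heap, (cur, ra, rb))
            continue
        if cost >= ceiling:
            break
        # merge rb into ra
        stats[ra].absorb(stats[rb])
        het[ra] = stats[ra].heterogeneity()
        parent[rb] = ra
        adj[ra] |= adj[rb]
        adj[ra].discard(ra)
        adj[ra].discard(rb)
        for nb in list(adj[ra]):
            rn = find(nb)
            if rn == ra:
                continue
            c2 = stats[ra].merged_heterogeneity(stats[rn]) - het[ra] - het[rn]
            if c2 < ceiling:
                heapq.heappush(heap, (c2, ra, rn))

    labels = np.zeros(mask.shape, dtype=np.int32)
    root_label = {}
    order = np.argsort(rr * mask.shape[1] + cc)  # row-major
    nxt = 1
    for k in order:
        r = find(int(k))
        if r not in root_label:
            root_label[r] = nxt
            nxt += 1
        labels[rr[k], cc[k]] = root_label[r]
    return labels


def refine_oversize(oversize, scene, cfg: MaskConfig) -> np.ndarray:
    """Stage 2: segment large objects; keep heterogeneous sub-objects.

    Returns the boolean mask increment contributed by the surviving
    sub-objects (NIR s.d. >= the background ceiling).
    """
    increment = np.zeros(scene.shape, dtype=bool)
    nir = scene.band("nir1")
    for obj in oversize:
        if obj.area_m2 <= cfg.large_object_area_m2:
            # below the size constraint: keep whole if heterogeneous
            _, sd = band_stats(obj, nir)
            if sd >= cfg.nir_sd_background_max:
                increment[obj.rows, obj.cols] = True
            continue
        sub = np.zeros(scene.shape, dtype=bool)
        sub[obj.rows, obj.cols] = True
        labels = region_merge_segmentation(scene.values, sub, cfg.mr_scale)
        for lab in range(1, labels.max() + 1):
            r, c = np.nonzero(labels == lab)
            if r.size == 0:
                continue
            sd = float(nir[r, c].std(ddof=0))
            if sd >= cfg.nir_sd_background_max:
                increment[r, c] = True
    return increment


# ---------------------------------------------------------------------------
# ISODATA refinement (stage 3)
# ---------------------------------------------------------------------------

@dataclass
class UnderstoryRule:
    """Decides which spectral clusters are understory and leave the mask.

    Automated default: flag clusters whose NIR s.d. falls below
    ``nir_sd_max``.  The s.d. fed to the rule is the cluster mean of the
    *local* (spatial 5x5 window) NIR standard deviation: understory and
    crop patches are spatially flat while crown canopies are textured, and
    the spatial measure keeps its meaning regardless of how finely the
    spectral space is clustered.  Setting ``ndvi_quantile`` > 0 additionally
    flags clusters whose centroid NDVI is below that quantile of
    cluster-centroid NDVIs.  ``cluster_ids`` gives fully manual mode
    (explicit cluster labels), mirroring interactive labelling.
    """

    nir_sd_max: float = 4.0
    ndvi_quantile: float = 0.0
    cluster_ids: list | None = None

    def flag(self, cluster_ids, centroid_ndvi, cluster_nir_sd):
        if self.cluster_ids is not None:
            sel = set(self.cluster_ids)
            return [cid in sel for cid in cluster_ids]
        flags = [sd < self.nir_sd_max for sd in cluster_nir_sd]
        if self.ndvi_quantile > 0 and len(centroid_ndvi) > 1:
            q = np.quantile(centroid_ndvi, self.ndvi_quantile)
            flags = [f or (nd < q) for f, nd in zip(flags, centroid_ndvi)]
        return flags


def _isodata(X: np.ndarray, k: int, seed: int, min_size: int = 5,
             split_sd: float = 25.0, merge_dist: float = 2.0,
             max_cycles: int = 3):
    """ISODATA clustering: k-means with split/merge heuristics.

    Clusters with fewer than ``min_size`` members are dissolved into their
    nearest cluster; clusters whose largest per-dimension s.d. exceeds
    ``split_sd`` are split along that dimension; centroid pairs closer than
    ``merge_dist`` are merged.  Deterministic for a fixed seed.
    """
    k = max(1, min(k, len(X)))
    km = KMeans(n_clusters=k, random_state=seed, n_init=2).fit(X)
    labels, centers = km.labels_, km.cluster_centers_
    for _ in range(max_cycles):
        changed = False
        # dissolve tiny clusters
        sizes = np.bincount(labels, minlength=len(centers))
        keep = sizes >= min_size
        if (~keep).any() and keep.sum() >= 1:
            remap = centers[keep]
            d = ((X[:, None, :] - remap[None]) ** 2).sum(-1)
            labels = d.argmin(1)
            centers = remap
            changed = True
        # split heterogeneous clusters
        new_centers = []
        for j in range(len(centers)):
            pts = X[labels == j]
            if len(pts) >= 2 * min_size:
                sd = pts.std(axis=0)
                if sd.max() > split_sd:
                    dim = int(sd.argmax())
                    c1, c2 = centers[j].copy(), centers[j].copy()
                    c1[dim] -= sd[dim]
                    c2[dim] += sd[dim]
                    new_centers.extend([c1, c2])
                    changed = True
                    continue
            new_centers.append(centers[j])
        centers = np.asarray(new_centers)
        # merge close centroids
        merged = []
        used = np.zeros(len(centers), dtype=bool)
        for j in range(len(centers)):
            if used[j]:
                continue
            group = [centers[j]]
            used[j] = True
            for l in range(j + 1, len(centers)):
                if not used[l] and np.linalg.norm(centers[j] - centers[l]) < merge_dist:
                    group.append(centers[l])
                    used[l] = True
                    changed = True
            merged.append(np.mean(group, axis=0))
        centers = np.asarray(merged)
        d = ((X[:, None, :] - centers[None]) ** 2).sum(-1)
        labels = d.argmin(1)
        # one Lloyd step to settle centroids
        for j in range(len(centers)):
            pts = X[labels == j]
            if len(pts):
                centers[j] = pts.mean(axis=0)
        if not changed:
            break
    return labels, centers


def isodata_refinement(scene, mask: TreeMask, cfg: MaskConfig,
                       understory_rule: UnderstoryRule | None = None,
                       ndvi=None) -> TreeMask:
    """Stage 3: cluster the 8-band values inside the mask and strip clusters
    flagged as understory.  Only removes pixels; logs the removal."""
    rule = understory_rule or UnderstoryRule(
        nir_sd_max=cfg.nir_sd_background_max)
    rr, cc = np.nonzero(mask.grid)
    if rr.size == 0:
        mask.log("isodata", 0, 0)
        return mask
    X = scene.values[:, rr, cc].T
    k = min(cfg.isodata_clusters, len(X))
    labels, centers = _isodata(X, k, seed=cfg.rng_seed)
    nir_grid = scene.band("nir1")
    # local (5x5) NIR s.d.: texture measure, robust to cluster granularity
    mean = ndi.uniform_filter(nir_grid, size=5)
    sq = ndi.uniform_filter(nir_grid**2, size=5)
    local_sd_grid = np.sqrt(np.maximum(sq - mean**2, 0.0))
    local_sd = local_sd_grid[rr, cc]
    nir = nir_grid[rr, cc]
    if ndvi is not None:
        nd = (ndvi.values if hasattr(ndvi, "values") else ndvi)[rr, cc]
    else:
        red = scene.band("red")[rr, cc]
        nirv = nir
        denom = np.where(nirv + red == 0, 1, nirv + red)
        nd = np.where(nirv + red == 0, 0.0, (nirv - red) / denom)
    ids = sorted(set(labels.tolist()))
    centroid_ndvi = [float(nd[labels == j].mean()) for j in ids]
    cluster_nir_sd = [float(local_sd[labels == j].mean()) for j in ids]
    flags = rule.flag(ids, centroid_ndvi, cluster_nir_sd)
    remove = np.zeros(rr.size, dtype=bool)
    for j, fl in zip(ids, flags):
        if fl:
            remove |= labels == j
    mask.grid[rr[remove], cc[remove]] = False
    mask.log("isodata", added=0, removed=int(remove.sum()))
    return mask


def fill_small_holes(mask: TreeMask, cfg: MaskConfig,
                     pixel_size: float = 0.5) -> TreeMask:
    """Stage 4: reintegrate enclosed background objects below the hole-area
    threshold.  Holes touching the scene edge are not enclosed and stay."""
    bg, nlab = ndi.label(~mask.grid)
    if nlab == 0:
        mask.log("fill_holes", 0, 0)
        return mask
    border = np.zeros(nlab + 1, dtype=bool)
    border[np.unique(bg[0, :])] = True
    border[np.unique(bg[-1, :])] = True
    border[np.unique(bg[:, 0])] = True
    border[np.unique(bg[:, -1])] = True
    sizes = np.bincount(bg.ravel(), minlength=nlab + 1)
    max_px = cfg.hole_fill_area_m2 / pixel_size**2
    fill_ids = [i for i in range(1, nlab + 1)
                if not border[i] and sizes[i] < max_px]
    added = 0
    for i in fill_ids:
        sel = bg == i
        added += int(sel.sum())
        mask.grid[sel] = True
    mask.log("fill_holes", added=added, removed=0)
    return mask


def build_tree_mask(scene, ndvi, cfg: MaskConfig | None = None,
                    understory_rule: UnderstoryRule | None = None) -> TreeMask:
    """Run all four mask stages in order; provenance-audited TreeMask."""
    cfg = cfg or MaskConfig()
    mask, oversize = iterative_ndvi_extraction(ndvi, scene, cfg)
    inc = refine_oversize(oversize, scene, cfg)
    new = inc & ~mask.grid
    mask.grid |= inc
    mask.log("refine_oversize", added=int(new.sum()), removed=0)
    mask = isodata_refinement(scene, mask, cfg, understory_rule, ndvi)
    mask = fill_small_holes(mask, cfg, scene.pixel_size)
    return mask
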