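"""Synthetic parkland scenes with exact ground truth.

Real reference imagery (proprietary satellite data) and the field inventory
are not redistributable, so the package ships a deterministic generator of
parkland-like scenes: scattered elliptical tree crowns of three spectral
"species types" over an active-field (bright bare soil) or fallow (darker,
with grass/shrub understory and tree regrowth) field layer.

Rendering model
---------------
Each crown is an ellipse with a radial NDVI/NIR profile peaking at the
centre::

    NDVI(r) = peak - (peak - edge) * (r / R)**2

with the edge value above the mask threshold and within the species'
region-growing NDVI delta of the peak, while the crown-to-background NDVI
step at the boundary far exceeds the delta: crown edges are recoverable by
construction, not luck, and crown-to-crown saddles fall between the full
and the decayed growth thresholds so clusters remain splittable.
Within-crown Gaussian texture gives crowns the high NIR standard
deviation the mask gates rely on; the field layer is
spectrally flat.  A depressed-brightness crescent displaced by the sun
offset emulates crown-edge shadowing.  Fallow scenes add (i) irregular flat
understory patches (NDVI 0.05-0.2) and (ii) small textured regrowth crowns
(stem diameter below the 5 cm survey floor, absent from the reference list)
— the main commission-error source in fallows.

Reported stem positions are jittered by a GPS-like error; the exact
positions (the analogue of manually corrected field points) are kept
alongside.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy import (ReferenceTree, canopy_cover, delineation_pairs,
                       delineation_stats, match_detections, write_trees_csv)
from .raster import (BAND_ROLES, SceneRaster, write_label_raster, write_scene)

__all__ = ["SceneSpec", "SceneTruth", "generate_scene", "scene_to_fixtures",
           "benchmark_suite"]

#: per species type: (NDVI peak, NDVI edge, NIR peak, NIR edge drop).
#: The edge NDVI sits within 0.9x the species' region-growing delta of the
#: peak, so a single seed can claim the whole crown; the crown-to-background
#: step at the boundary far exceeds the delta, which is what stops growth.
#: At crown-to-crown contacts the saddle (0.9 delta below the peaks) blocks
#: growth once thresholds decay by 0.75, so touching crowns remain splittable.
SPECIES_PROFILES = {
    1: (0.20, 0.128, 130.0, 24.0),
    2: (0.30, 0.165, 150.0, 32.0),
    3: (0.45, 0.288, 170.0, 40.0),
}

#: field-layer radiance (NIR level, NDVI) per land use
BACKGROUND = {"active_field": (95.0, 0.02), "fallow": (70.0, 0.04)}


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene (all lengths in metres)."""

    extent_m: float = 80.0
    pixel_size: float = 0.5
    n_trees: int = 20
    species_mix: tuple = (1 / 3, 1 / 3, 1 / 3)
    d1_log_mu: float = math.log(6.0)   # log-normal crown diameter D1
    d1_log_sigma: float = 0.35
    d1_min_m: float = 2.5
    d1_max_m: float = 16.0
    eccentricity_range: tuple = (0.6, 1.0)  # D2 = D1 * U(range)
    cluster_fraction: float = 0.3
    land_use: str = "active_field"     # active_field | fallow
    understory_density: float = 0.0    # fraction of background in patches
    regrowth_per_100m2: float = 0.0    # small non-surveyed crowns
    within_crown_sd: float = 6.0       # NIR texture (radiance units)
    shadow_offset_px: int = 2
    gps_jitter_sd: float = 3.0
    rng_seed: int = 0

    def __post_init__(self):
        if abs(sum(self.species_mix) - 1.0) > 1e-9:
            raise ValueError("species_mix proportions must sum to 1")
        if self.land_use not in BACKGROUND:
            raise ValueError(f"unknown land_use {self.land_use!r}")
        for name in ("within_crown_sd", "gps_jitter_sd",
                     "understory_density", "regrowth_per_100m2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def fallow(cls, **kw):
        """Fallow study conditions: denser, smaller trees, touching crowns,
        dense understory with regrowth."""
        defaults = dict(land_use="fallow", cluster_fraction=0.5,
                        understory_density=0.25, regrowth_per_100m2=0.2,
                        d1_log_mu=math.log(5.0))
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class SceneTruth:
    """Exact ground truth for a generated scene."""

    trees: list                      # ReferenceTree with exact positions
    gps_positions: dict              # tree_id -> (x, y) jittered
    crown_labels: np.ndarray         # per-pixel crown id (0 = background)
    cluster_group: dict              # tree_id -> group id (0 = isolated)
    n_requested: int = 0
    n_placed: int = 0
    warnings: list = field(default_factory=list)


def _place_trees(spec: SceneSpec, rng) -> list:
    """Sample crown geometries; returns records
    (x, y, r1, r2, species_type, group)."""
    lo, hi = spec.eccentricity_range
    records = []
    n_cluster = int(round(spec.cluster_fraction * spec.n_trees))
    margin = 2.0

    def sample_geom():
        d1 = float(np.clip(rng.lognormal(spec.d1_log_mu, spec.d1_log_sigma),
                           spec.d1_min_m, spec.d1_max_m))
        d2 = d1 * rng.uniform(lo, hi)
        st = int(rng.choice([1, 2, 3], p=spec.species_mix))
        return d1 / 2, d2 / 2, st

    def fits(x, y, r1, r2, min_gap):
        if not (margin + r1 <= x <= spec.extent_m - r1 - margin):
            return False
        if not (margin + r2 <= y <= spec.extent_m - r2 - margin):
            return False
        for (px, py, pr1, pr2, _st, _g) in records:
            d = math.hypot(x - px, y - py)
            if d < r1 + pr1 + min_gap:
                return False
        return True

    group_id = 0
    # clustered trees: groups of 2-3 touching crowns
    placed_cluster = 0
    attempts = 0
    while placed_cluster < n_cluster and attempts < 300:
        attempts += 1
        size = min(int(rng.integers(2, 4)), n_cluster - placed_cluster)
        if size < 2:
            size = 2
        r1, r2, st = sample_geom()
        x = rng.uniform(margin + r1, spec.extent_m - r1 - margin)
        y = rng.uniform(margin + r2, spec.extent_m - r2 - margin)
        if not fits(x, y, r1, r2, min_gap=2.0):
            continue
        group_id += 1
        members = [(x, y, r1, r2, st, group_id)]
        ok = True
        for _ in range(size - 1):
            placed = False
            for _try in range(40):
                q1, q2, qst = sample_geom()
                ang = rng.uniform(0, 2 * np.pi)
                dist = (members[-1][2] + q1) * rng.uniform(0.75, 0.95)
                qx = members[-1][0] + dist * math.cos(ang)
                qy = members[-1][1] + dist * math.sin(ang)
                if not (margin + q1 <= qx <= spec.extent_m - q1 - margin
                        and margin + q2 <= qy <= spec.extent_m - q2 - margin):
                    continue
                clash = False
                for (px, py, pr1, pr2, _s, g) in records:
                    if math.hypot(qx - px, qy - py) < q1 + pr1 + 2.0:
                        clash = True
                        break
                if not clash:
                    members.append((qx, qy, q1, q2, qst, group_id))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok and len(members) >= 2:
            records.extend(members)
            placed_cluster += len(members)
        else:
            group_id -= 1
    # isolated trees
    n_isolated = spec.n_trees - len(records)
    for _ in range(n_isolated):
        for _try in range(200):
            r1, r2, st = sample_geom()
            x = rng.uniform(margin + r1, spec.extent_m - r1 - margin)
            y = rng.uniform(margin + r2, spec.extent_m - r2 - margin)
            if fits(x, y, r1, r2, min_gap=2.0):
                records.append((x, y, r1, r2, st, 0))
                break
    return records


def _irregular_blob(rng, grid_shape, n_seeds=3, radius_px=4):
    """Random irregular patch mask (union of small offset disks)."""
    H, W = grid_shape
    cr = rng.integers(radius_px, H - radius_px)
    cc = rng.integers(radius_px, W - radius_px)
    m = np.zeros(grid_shape, dtype=bool)
    rr, cols = np.mgrid[0:H, 0:W]
    for _ in range(n_seeds):
        dr = cr + rng.integers(-radius_px, radius_px + 1)
        dc = cc + rng.integers(-radius_px, radius_px + 1)
        rad = rng.uniform(1.5, radius_px)
        m |= (rr - dr) ** 2 + (cols - dc) ** 2 <= rad**2
    return m


def generate_scene(spec: SceneSpec):
    """Render a scene and its exact truth; same seed -> identical output."""
    rng = np.random.default_rng(spec.rng_seed)
    n_px = int(round(spec.extent_m / spec.pixel_size))
    shape = (n_px, n_px)
    geotransform = (spec.pixel_size, 0.0, 0.0, 0.0, -spec.pixel_size,
                    spec.extent_m)

    records = _place_trees(spec, rng)
    warnings = []
    if len(records) < spec.n_trees:
        warnings.append(
            f"placed {len(records)} of {spec.n_trees} requested trees")

    # pixel centre map coordinates
    rr, cc = np.mgrid[0:n_px, 0:n_px]
    px_x = (cc + 0.5) * spec.pixel_size
    px_y = spec.extent_m - (rr + 0.5) * spec.pixel_size

    nir_bg, ndvi_bg = BACKGROUND[spec.land_use]
    ndvi = np.full(shape, ndvi_bg) + rng.normal(0, 0.008, shape)
    nir = np.full(shape, nir_bg) + rng.normal(0, 1.5, shape)

    # understory patches: flat, moderately green, below tree-crown texture
    if spec.understory_density > 0:
        target = spec.understory_density * n_px * n_px
        covered = 0
        for _ in range(400):
            if covered >= target:
                break
            blob = _irregular_blob(rng, shape,
                                   n_seeds=int(rng.integers(2, 5)),
                                   radius_px=int(rng.integers(3, 7)))
            lvl = rng.uniform(0.06, 0.18)
            ndvi[blob] = lvl + rng.normal(0, 0.01, int(blob.sum()))
            nir[blob] = nir_bg * 0.9 + rng.normal(0, 1.5, int(blob.sum()))
            covered += int(blob.sum())

    crown_labels = np.zeros(shape, dtype=np.int32)
    norm_dist = np.full(shape, np.inf)
    crown_meta = []
    for i, (x, y, r1, r2, st, group) in enumerate(records, start=1):
        d = np.sqrt(((px_x - x) / r1) ** 2 + ((px_y - y) / r2) ** 2)
        inside = d <= 1.0
        closer = inside & (d < norm_dist)
        crown_labels[closer] = i
        norm_dist[closer] = d[closer]
        crown_meta.append((x, y, r1, r2, st, group))

    # regrowth: small crowns below the survey floor (never in the truth list)
    regrowth_labels = np.zeros(shape, dtype=np.int32)
    n_regrowth = int(round(spec.regrowth_per_100m2 * spec.extent_m**2 / 100.0))
    regrowth_meta = []
    for j in range(1, n_regrowth + 1):
        for _try in range(50):
            r1 = rng.uniform(0.6, 1.3)
            r2 = r1 * rng.uniform(0.7, 1.0)
            x = rng.uniform(2 + r1, spec.extent_m - r1 - 2)
            y = rng.uniform(2 + r2, spec.extent_m - r2 - 2)
            d = np.sqrt(((px_x - x) / r1) ** 2 + ((px_y - y) / r2) ** 2)
            inside = (d <= 1.0)
            if not (inside & (crown_labels > 0)).any():
                regrowth_labels[inside & (regrowth_labels == 0)] = j
                regrowth_meta.append((x, y, r1, r2))
                break

    # render crown radial profiles (trees, then regrowth as type-1-like)
    for labels, metas, texture in (
            (crown_labels, crown_meta, spec.within_crown_sd),
            (regrowth_labels, regrowth_meta, spec.within_crown_sd)):
        for i, meta in enumerate(metas, start=1):
            x, y, r1, r2 = meta[:4]
            st = meta[4] if len(meta) > 4 else 1
            peak, edge, nir_peak, nir_drop = SPECIES_PROFILES[st]
            sel = labels == i
            if not sel.any():
                continue
            d = np.sqrt(((px_x[sel] - x) / r1) ** 2
                        + ((px_y[sel] - y) / r2) ** 2)
            d = np.clip(d, 0, 1)
            ndvi[sel] = (peak - (peak - edge) * d**2
                         + rng.normal(0, 0.01, int(sel.sum())))
            nir[sel] = (nir_peak - nir_drop * d**2
                        + rng.normal(0, texture, int(sel.sum())))

    # shadows: crescent displaced from each crown, darkening the field layer
    if spec.shadow_offset_px > 0:
        off = spec.shadow_offset_px
        any_crown = (crown_labels > 0) | (regrowth_labels > 0)
        shifted = np.zeros(shape, dtype=bool)
        shifted[off:, :n_px - off] = any_crown[:n_px - off, off:]
        shadow = shifted & ~any_crown
        nir[shadow] *= 0.55

    # derive the 8 bands from the NDVI/NIR fields
    # red is derived from the post-shadow NIR, so shadow darkens both bands
    # coherently and leaves the NDVI of shadowed ground unchanged
    ndvi_c = np.clip(ndvi, -0.99, 0.99)
    red = nir * (1 - ndvi_c) / (1 + ndvi_c)
    noise = lambda s: rng.normal(0, s, shape)
    bands = {
        "coastal": 0.85 * red + 8 + noise(0.5),
        "blue": 0.90 * red + 5 + noise(0.5),
        "green": 0.95 * red + 10 + 0.05 * nir + noise(0.5),
        "yellow": 1.00 * red + 5 + noise(0.5),
        "red": red,
        "red_edge": 0.40 * red + 0.60 * nir + noise(0.8),
        "nir1": nir,
        "nir2": 0.95 * nir + noise(0.8),
    }
    values = np.stack([bands[b] for b in BAND_ROLES])
    scene = SceneRaster(values, BAND_ROLES, spec.pixel_size, geotransform)

    trees, gps = [], {}
    for i, (x, y, r1, r2, st, group) in enumerate(crown_meta, start=1):
        d1, d2 = 2 * max(r1, r2), 2 * min(r1, r2)
        dbh = max(5.0, 4.5 * d1**1.15 + rng.normal(0, 2))
        trees.append(ReferenceTree(
            tree_id=i, x=x, y=y, species=f"species_type_{st}", dbh_cm=dbh,
            height_m=2.0 + 0.8 * d1 + rng.normal(0, 0.5), d1_m=d1, d2_m=d2,
            land_use=spec.land_use, plot_id=1))
        jx = x + rng.normal(0, spec.gps_jitter_sd)
        jy = y + rng.normal(0, spec.gps_jitter_sd)
        gps[i] = (jx, jy)
    cluster_group = {t.tree_id: crown_meta[t.tree_id - 1][5] for t in trees}
    truth = SceneTruth(trees=trees, gps_positions=gps,
                       crown_labels=crown_labels,
                       cluster_group=cluster_group,
                       n_requested=spec.n_trees, n_placed=len(trees),
                       warnings=warnings)
    return scene, truth


def _spec_to_toml(spec: SceneSpec) -> str:
    lines = ["[scene]"]
    for f in dataclasses.fields(spec):
        v = getattr(spec, f.name)
        if isinstance(v, str):
            lines.append(f'{f.name} = "{v}"')
        elif isinstance(v, tuple):
            lines.append(f"{f.name} = {list(v)}")
        else:
            lines.append(f"{f.name} = {v}")
    return "\n".join(lines) + "\n"


def scene_to_fixtures(scene: SceneRaster, truth: SceneTruth, spec: SceneSpec,
                      out_dir) -> dict:
    """Write a complete end-to-end fixture: scene.tif, truth_labels.tif,
    trees.csv (corrected positions; GPS-jittered ones in x_gps/y_gps) and
    spec.toml.  Returns the path map."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scene": out / "scene.tif",
        "truth_labels": out / "truth_labels.tif",
        "trees": out / "trees.csv",
        "spec": out / "spec.toml",
    }
    write_scene(paths["scene"], scene)
    write_label_raster(paths["truth_labels"], truth.crown_labels,
                       scene.pixel_size, scene.geotransform)
    write_trees_csv(paths["trees"], truth.trees)
    df = pd.read_csv(paths["trees"])
    df["x_gps"] = [truth.gps_positions[t][0] for t in df["tree_id"]]
    df["y_gps"] = [truth.gps_positions[t][1] for t in df["tree_id"]]
    df.to_csv(paths["trees"], index=False)
    paths["spec"].write_text(_spec_to_toml(spec))
    return paths


def benchmark_suite(seeds, active_spec: SceneSpec | None = None,
                    fallow_spec: SceneSpec | None = None,
                    mask_cfg=None, split_cfg=None) -> pd.DataFrame:
    """Paired active-field / fallow evaluation across seeds.

    For each seed, generates both scene types, runs the full delineation
    pipeline, matches detections against the (corrected) reference
    positions and reports detection + delineation accuracy per stratum.
    """
    from .delineation import delineate_scene

    rows = []
    for seed in seeds:
        for land_use in ("active_field", "fallow"):
            if land_use == "active_field":
                base = active_spec or SceneSpec()
            else:
                base = fallow_spec or SceneSpec.fallow()
            spec = dataclasses.replace(base, rng_seed=int(seed),
                                       land_use=land_use)
            scene, truth = generate_scene(spec)
            cmap = delineate_scene(scene, mask_cfg, split_cfg)
            row = {"seed": int(seed), "land_use": land_use,
                   "n_trees": truth.n_placed,
                   "n_crowns": len(cmap.crowns)}
            if truth.n_placed == 0:
                row.update({k: 0.0 for k in
                            ("ITD_pct", "CCD_pct", "DR_pct", "OE_pct",
                             "CE_pct", "AI_pct", "r_s", "MAE_m2", "MRE_pct",
                             "MBE_m2")})
                rows.append(row)
                continue
            res = match_detections(cmap.labels, truth.trees, scene)
            s = res.summary()
            row.update({"ITD_pct": s["ITD_pct"], "CCD_pct": s["CCD_pct"],
                        "DR_pct": s["DR_pct"], "OE_pct": s["OE_pct"],
                        "CE_pct": s["CE_pct"], "AI_pct": s["AI_pct"]})
            pairs = delineation_pairs(res, truth.trees, cmap.labels, scene)
            if len(pairs) >= 2:
                st = delineation_stats(pairs)
                row.update({"r_s": st.r_s, "MAE_m2": st.mae_m2,
                            "MRE_pct": st.mre_pct, "MBE_m2": st.mbe_m2})
            bounds = (0.0, 0.0, spec.extent_m, spec.extent_m)
            row["cc_delineated_pct"] = canopy_cover(
                None, bounds, scene=scene, labels=cmap.labels)
            row["cc_reference_pct"] = canopy_cover(truth.trees, bounds)
            rows.append(row)
    return pd.DataFrame(rows)
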