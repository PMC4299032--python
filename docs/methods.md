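# Methods

This note records the models, parameter choices and numerical decisions
behind the package, in the spirit of a methods appendix: what is computed,
why the defaults are what they are, and what the synthetic experiments do
and do not demonstrate.

## Problem setting and assumptions

The pipeline targets semi-arid parkland: scattered trees (crown areas from
a few m² to ~600 m²) over bright bare-soil fields or darker fallows with
grass, shrub and tree-regrowth understory. It assumes

- an 8-band image on a fine (0.5 m) grid, values on a top-of-atmosphere
  radiance scale; band roles follow the WorldView-2 layout (coastal, blue,
  green, yellow, red, red-edge, NIR1, NIR2);
- crowns are approximately elliptical, brightest/greenest near the top,
  with NDVI and NIR decreasing toward the edge ("a sharp decrease marks the
  crown edge");
- crowns are spectrally *heterogeneous* (leaf + branch + shadow mixing),
  while field-layer vegetation is comparatively flat — the single most
  load-bearing assumption, since both the mask gates (NIR s.d. > 8) and
  false-detection removal (NIR s.d. < 4 ∧ red-edge s.d. < 3) rest on it;
- tree tops are resolvable as local NDVI maxima at a 2 m cell size.

All spectral thresholds are interpreted on the TOA-radiance scale and are
configuration values; they are sensor- and season-specific and should be
re-tuned for other data sources. The single TOML config file is the only
place thresholds live.

## Parameters that matter

| parameter | default | unit | role |
|---|---|---|---|
| NDVI sweep | 0.05→0.20 step 0.05 | – | iterative mask extraction |
| candidate area gate | < 1500 | m² | objects above are refined, not gated |
| roundness / elliptical fit | < 0.6 / > 0.7 | – | crown-likeness |
| NIR s.d. (crown / background) | > 8 / < 4 | radiance | heterogeneity gates |
| red-edge s.d. (false detection) | < 3 | radiance | with NIR s.d., flags flat objects |
| region-merge scale | 20 | – | cost ceiling = scale² (see below) |
| ISODATA clusters | 50 | – | spectral understory removal |
| hole-fill area | < 50 | m² | enclosed background reintegration |
| seed NDVI floor | 0.1 | – | rejects field-layer maxima |
| growth deltas (type 1/2/3) | 0.08/0.15/0.18 NDVI, 30/40/50 NIR | – | species-typed edge detection |
| split decay | ×0.75, 2 cycles | – | resolves subtle internal edges |
| cluster gates | l/w > 1.7, roundness > 0.6, area > 700 m² | – | ITC vs cluster |
| minimum crown area | 4 | m² | one 2 m seed cell (resolution floor) |

Species-type bins on seed mean NDVI are 0.1–0.2, >0.2–0.3 and >0.3, with
closed upper bounds (0.2 → type 1, 0.3 → type 2).

## Numerical and design choices

**Shape features.** Roundness is the radius of the smallest enclosing
ellipse minus the radius of the largest enclosed ellipse, both normalised
by the object's equal-area-circle radius (0 = perfect ellipse). The
enclosing ellipse is the minimum-volume enclosing ellipse of the convex
hull (Khachiyan iteration, tolerance 1e-3); the enclosed ellipse is found
by a distance-transform-guided search (candidate centres at the strongest
interior points, 6 orientations, aspect ratios 1.0–0.2, binary search on
size) under a grid-native containment rule: every pixel centre covered by
the ellipse must belong to the object. The commercial definitions these
features originate from are proprietary; the approximations here are fixed
as contracts by brute-force oracle tests on small shapes, not claimed to be
bit-equivalent. The coarse orientation/aspect grids bias roundness upward
by ≲0.15 for eccentric ellipses — far from the 0.6 gate, so immaterial for
classification. Elliptical fit superimposes the moment-derived equal-area
ellipse and maps the inside fraction to [0, 1] via max(0, 2·inside/n − 1);
length/width is the square-rooted eigenvalue ratio of the pixel covariance
(plus 1/12 per-pixel variance so one-pixel-wide shapes stay finite).
Object standard deviations use divisor n (population form). Degenerate
objects: roundness capped at 5.0, elliptical fit 0, length/width capped at
100.

**Region-merging refinement.** Commercial multiresolution segmentation is
replaced by greedy cheapest-first pairwise merging on the 4-connected pixel
graph; the merge cost is the increase in area-weighted per-band standard
deviation, and merging stops at cost ≥ scale². The squared ceiling follows
the usual convention that segment size grows roughly linearly with the
scale parameter; with a raw ceiling of 20 summed over 8 bands, even
singleton merges inside textured canopy would be blocked. Cheapest-first
order also protects boundaries: homogeneous interiors coalesce before any
cross-boundary merge is considered, and by then the cross cost is
prohibitive.

**ISODATA understory rule.** The original procedure labelled understory
clusters manually. The automated default flags clusters whose *local*
(5×5 window) NIR standard deviation, averaged over members, falls below 4.
Within-cluster spectral s.d. is deliberately not used: with 50 clusters,
k-means makes every cluster spectrally tight regardless of what it
represents, whereas spatial texture keeps its meaning at any cluster
granularity. A centroid-NDVI quantile rule and an explicit cluster-id list
(manual mode) are available through configuration. Clustering is k-means
plus split/merge heuristics (dissolve clusters < 5 members; split when a
per-dimension s.d. exceeds 25; merge centroids closer than 2), seeded from
the config for determinism.

**Seeding.** A seed is the coarse cell of maximal mean NDVI intersecting
the unclaimed region *that is also a local maximum among the object's
coarse cells*. The local-maximum requirement operationalises "radiometric
maximum": without it, the thin above-floor ring left outside a grown
region re-seeds into spurious fragment crowns. Ties break row-major.
Seed mean NIR is taken at coarse resolution (more representative of the
crown than any single fine pixel).

**Region growing.** One-sided test, seed-minus-pixel: pixels greener or
brighter than the seed are always admitted; growth is 8-connected and
confined to unclaimed mask pixels, so no pixel ever belongs to two crowns.
Residual pixels below the seed floor attach to the adjacent crown whose
seed NDVI is closest to the residual's mean NDVI (the source method is
silent here); residuals with no adjacent crown stay unclaimed and are
reported.

**Minimum crown area.** Crowns below one 2 m seed cell (4 m²) are below
the resolving power of the seeding grid: watershed pieces that small are
absorbed into their largest neighbour, sub-minimum parts produced by the
decay cycles fold into the largest sibling, and sub-minimum survivors are
classed as false detections. (Omission of trees with crown area under a
few coarse pixels is a documented failure mode of this family of methods,
not something the implementation can avoid.)

**Watershed.** Marker-based watershed on the negated interior Euclidean
distance transform; markers are distance maxima at least 3 px apart.
Output regions partition the cluster exactly; single-marker clusters pass
through unchanged. Plateau ties on symmetric necks are broken by the
flooding order and may differ between equally valid implementations by a
one-pixel band.

**False detections and merging.** The NIR/red-edge flatness gates combine
with AND by default (conservative: low-LAI crowns are often flat in one
band but rarely in both); OR is reachable via config. Adjacent surviving
crown clusters merge under 8-connectivity, consistent with region
connectivity elsewhere.

**Detection matching.** A tree matches the crown containing its stem; if
the stem lands on background (GPS error), the fallback is the crown with
the largest overlap with the tree's elliptical footprint (axis-aligned —
crown orientation is not surveyed). Reference canopy cover is a plain sum
of elliptical crown areas, deliberately *not* overlap-corrected, so the
known overestimation bias of field-based cover aggregates is reproduced.
MRE is reported in percent.

## The synthetic scenes

The generator renders what the mask and growth stages are built to
exploit, with exact truth:

- crowns as ellipses with quadratic radial NDVI/NIR profiles. Peak/edge
  NDVI per species type: 0.20/0.128, 0.30/0.165, 0.45/0.288. The edge sits
  0.9× the species' growth delta below the peak, so one seed can claim one
  crown, while the crown-to-background step (background NDVI 0.02–0.04)
  far exceeds the delta and stops growth at the boundary. At crown-crown
  contacts the saddle (0.9δ below both peaks) passes the full threshold
  but blocks the 0.75-decayed one — clusters form at scale 1 and split in
  cycle 1, which is precisely the designed role of the decay cycles;
- within-crown Gaussian NIR texture (default s.d. 6 radiance units) which,
  combined with the radial gradient, puts crown NIR s.d. comfortably above
  the 8 gate while flat backgrounds (noise s.d. 1.5) stay below 4;
- fallow scenes add irregular flat understory patches (NDVI 0.06–0.18,
  default 25% cover) and small textured regrowth crowns (stem diameter
  below the 5 cm survey floor, 0.2 per 100 m², absent from the reference
  list) — the documented source of fallow commission error;
- crown-edge shadows as a darkening (×0.55) of NIR displaced by the sun
  offset; the derived red band darkens coherently, so shadow NDVI equals
  the underlying ground's and shadows stay out of the mask while
  depressing NIR at crown edges;
- reported stem positions jittered by a 3 m-s.d. GPS error. The exact
  positions are kept alongside (the analogue of the manual GPS correction
  applied to real inventories) and are what `trees.csv` carries in the
  `x`/`y` columns; the jittered ones sit in `x_gps`/`y_gps` and exercise
  the ellipse-overlap matching fallback.

Scenes default to 80 m × 80 m (160×160 fine pixels) with 20 trees of
log-normal crown diameter (median 6 m active field, 5 m fallow, σ_log
0.35, clipped to 2.5–16 m) and D2/D1 ∈ [0.6, 1]; these sizes keep a full
paired five-seed benchmark under a few minutes on one core while leaving
every behaviour of interest (clusters, understory, regrowth, shadows)
represented.

**What passing synthetic tests shows — and what it does not.** The scenes
are *designed to be recoverable*: their crowns obey the radial-profile and
heterogeneity assumptions exactly, their background contrast is generous,
and their noise is Gaussian. Success demonstrates the pipeline implements
its stated logic (near-perfect recovery in the easy regime; commission
errors ordered fallow ≥ active field, as in real parklands). It does not
demonstrate performance on real imagery, where crown profiles are
irregular, species mixtures are continuous, atmospheric and phenological
effects shift every threshold, and position errors correlate with canopy
density.

## Known limitations

- Thresholds are not auto-tuned; transferring to another sensor or season
  requires re-calibration against training areas.
- Compact multi-crown clusters whose geometry passes the ITC gates are
  reported as single crowns (under-segmentation by design: splitting them
  is taken to be beyond the data's resolving power).
- The watershed stage over-segments compact clusters with ragged borders;
  the sub-minimum absorption and the final adjacent-cluster merge mitigate
  but do not eliminate this.
- Crown areas of small trees are measured over few pixels, so the relative
  error of small-crown delineation is intrinsically high.
- The TIFF writer stores band roles and the affine geotransform as JSON in
  the image description tag rather than full GeoTIFF geo-keys; any
  GIS-side consumption should go through the GeoJSON export.
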