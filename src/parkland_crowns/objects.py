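"""Image objects: connected pixel regions and their geometric and spectral
features.

Object-based analysis classifies connected regions rather than single pixels.
The features implemented here drive every classification gate in the
pipeline:

* ``area_m2`` — pixel count times pixel area.
* ``roundness`` — difference between the radius of the smallest enclosing
  ellipse and the radius of the largest enclosed ellipse, both normalised by
  the object's equal-area-circle radius.  0 for a perfect ellipse, larger for
  irregular shapes.
* ``elliptical_fit`` — how much of the object falls inside its moment-fitted
  equal-area ellipse, mapped to [0, 1] with 1 for a perfect ellipse.
* ``length_width`` — elongation, the ratio of the square roots of the two
  eigenvalues of the pixel-coordinate covariance matrix.
* per-band mean and population standard deviation (divisor n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull

__all__ = [
    "ImageObject",
    "connected_components",
    "roundness",
    "elliptical_fit",
    "length_width",
    "band_stats",
    "mvee",
    "inscribed_ellipse",
]

#: roundness assigned to degenerate (collinear / tiny) objects
ROUNDNESS_CAP = 5.0
#: length/width assigned when the minor eigenvalue vanishes
LENGTH_WIDTH_CAP = 100.0


@dataclass
class ImageObject:
    """A connected pixel region.

    ``rows``/``cols`` are parallel integer arrays of pixel coordinates
    (0-based, row-major grid).  ``pixel_size`` is the ground edge length in
    metres.  ``features`` is a free-form dict populated by the pipeline
    (band means/sds, ndvi stats, geometry).
    """

    rows: np.ndarray
    cols: np.ndarray
    pixel_size: float = 0.5
    label: int = 0
    features: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        if self.rows.size == 0:
            raise ValueError("ImageObject must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)

    @property
    def area_m2(self) -> float:
        """a = n x p: pixel count times pixel area."""
        return self.n_pixels * self.pixel_size**2

    def local_mask(self, pad: int = 1):
        """Boolean mask cropped to the object's bounding box.

        Returns ``(mask, (row_offset, col_offset))`` with ``pad`` background
        pixels around the object.
        """
        r0, c0 = self.rows.min() - pad, self.cols.min() - pad
        h = self.rows.max() - r0 + 1 + pad
        w = self.cols.max() - c0 + 1 + pad
        m = np.zeros((h, w), dtype=bool)
        m[self.rows - r0, self.cols - c0] = True
        return m, (r0, c0)

    def values_from(self, grid: np.ndarray) -> np.ndarray:
        return np.asarray(grid)[self.rows, self.cols]


def connected_components(mask: np.ndarray, connectivity: int = 8,
                         pixel_size: float = 0.5) -> list:
    """Split a boolean mask into connected ImageObjects.

    Objects are returned in deterministic order: sorted by the row-major
    position of each object's first pixel.  ``connectivity`` is 4 or 8.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab, n = ndi.label(mask, structure=ndi.generate_binary_structure(2, 2)
                       if connectivity == 8 else None)
    objs = []
    slices = ndi.find_objects(lab)
    for i, sl in enumerate(slices, start=1):
        rr, cc = np.nonzero(lab[sl] == i)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        # np.nonzero already yields row-major order; first element is the
        # object's first pixel in scan order.
        objs.append(ImageObject(rows, cols, pixel_size=pixel_size, label=i))
    objs.sort(key=lambda o: (int(o.rows[0]), int(o.cols[0])))
    for new_label, o in enumerate(objs, start=1):
        o.label = new_label
    return objs


# ---------------------------------------------------------------------------
# Enclosing / enclosed ellipses and roundness
# ---------------------------------------------------------------------------

def mvee(points: np.ndarray, tol: float = 1e-3, max_iter: int = 500):
    """Minimum-volume enclosing ellipse (Khachiyan iteration).

    Returns ``(center, A)`` such that ``(x-c)^T A (x-c) <= 1`` for all
    points.  ``tol`` is the relative convergence tolerance.
    """
    P = np.asarray(points, dtype=np.float64)
    n, d = P.shape
    if n <= d:
        raise ValueError("need more points than dimensions")
    Q = np.column_stack([P, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T @ np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1) * (M[j] - 1.0))
        new_u = (1 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol / n:
            u = new_u
            break
        u = new_u
    c = P.T @ u
    S = (P.T @ np.diag(u) @ P) - np.outer(c, c)
    A = np.linalg.inv(S) / d
    return c, A


def _ellipse_semiaxes(A: np.ndarray):
    evals = np.linalg.eigvalsh(A)
    evals = np.clip(evals, 1e-12, None)
    return 1.0 / np.sqrt(evals)  # ascending eigvals -> descending axes


def _ellipse_fits(mask, cx, cy, a, b, theta):
    """Grid-native ellipse containment: every pixel centre covered by the
    ellipse must be a mask pixel (and at least one must be covered).

    The covered set grows monotonically with the ellipse size, so a binary
    search over the semi-major axis is well defined.
    """
    ct, st = np.cos(theta), np.sin(theta)
    half_w = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
    half_h = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
    x0 = int(np.floor(cx - half_w))
    x1 = int(np.ceil(cx + half_w))
    y0 = int(np.floor(cy - half_h))
    y1 = int(np.ceil(cy + half_h))
    if x0 < 0 or y0 < 0 or x1 >= mask.shape[1] or y1 >= mask.shape[0]:
        return False  # the mask is padded, so a true inscribed ellipse fits
    gy, gx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    u = (gx - cx) * ct + (gy - cy) * st
    v = -(gx - cx) * st + (gy - cy) * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not inside.any():
        return False
    return bool(mask[gy[inside], gx[inside]].all())


def inscribed_ellipse(obj_mask: np.ndarray, n_angles: int = 6,
                      aspect_grid=(1.0, 0.75, 0.5, 0.3, 0.2)):
    """Largest-area ellipse contained in the mask (approximate).

    Distance-transform-guided search: candidate centres are the strongest
    interior points of the Euclidean distance transform; for each centre,
    orientation and aspect ratio the semi-major axis is grown by binary
    search.  Returns ``(area, (cx, cy, a, b, theta))`` in pixel units.
    """
    dist = ndi.distance_transform_edt(obj_mask)
    dmax = dist.max()
    if dmax <= 0:
        return 0.0, None
    # candidate centres: global max + a few strong, mutually distant maxima
    rr, cc = np.nonzero(dist >= 0.7 * dmax)
    order = np.argsort(dist[rr, cc])[::-1]
    centres = []
    for k in order:
        p = (cc[k], rr[k])
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 > dmax**2 for q in centres):
            centres.append(p)
        if len(centres) >= 3:
            break
    angles = np.linspace(0, np.pi, n_angles, endpoint=False)
    diag = float(np.hypot(*obj_mask.shape))
    best = (0.0, None)
    for cx, cy in centres:
        for theta in angles:
            for q in aspect_grid:
                lo, hi = dist[cy, cx] * 0.5, diag
                if not _ellipse_fits(obj_mask, cx, cy, lo, lo * q, theta):
                    continue
                for _ in range(16):
                    mid = 0.5 * (lo + hi)
                    if _ellipse_fits(obj_mask, cx, cy, mid, mid * q, theta):
                        lo = mid
                    else:
                        hi = mid
                area = np.pi * lo * (lo * q)
                if area > best[0]:
                    best = (area, (cx, cy, lo, lo * q, theta))
    return best


def roundness(obj: ImageObject) -> float:
    """r = (enclosing-ellipse radius - enclosed-ellipse radius), normalised.

    Both ellipse radii are geometric means of the semi-axes, divided by the
    object's equal-area-circle radius, making the feature scale invariant:
    0 for a perfect ellipse, increasingly positive for irregular shapes.
    Degenerate objects return ``ROUNDNESS_CAP``.
    """
    if obj.n_pixels < 3:
        return ROUNDNESS_CAP
    pts = np.column_stack([obj.cols, obj.rows]).astype(float)
    try:
        hull = ConvexHull(pts)
        hull_pts = pts[hull.vertices]
    except Exception:  # collinear
        return ROUNDNESS_CAP
    try:
        _, A = mvee(hull_pts)
    except (np.linalg.LinAlgError, ValueError):
        return ROUNDNESS_CAP
    a_enc, b_enc = _ellipse_semiaxes(A)[::-1][:2]
    r_enclosing = float(np.sqrt(a_enc * b_enc))
    mask, _ = obj.local_mask(pad=1)
    area_in, _ = inscribed_ellipse(mask)
    r_enclosed = float(np.sqrt(area_in / np.pi))
    r_eq = np.sqrt(obj.n_pixels / np.pi)
    return max(0.0, (r_enclosing - r_enclosed) / r_eq)


# ---------------------------------------------------------------------------
# Moment ellipse features
# ---------------------------------------------------------------------------

def _covariance_eigs(obj: ImageObject):
    """Eigen decomposition of the pixel-coordinate covariance (+ the 1/12
    single-pixel variance so 1-pixel-wide shapes stay non-degenerate)."""
    xy = np.column_stack([obj.cols, obj.rows]).astype(float)
    cov = np.cov(xy.T, bias=True) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    return evals, evecs, xy.mean(axis=0)


def elliptical_fit(obj: ImageObject) -> float:
    """Overlap of the object with its moment-fitted equal-area ellipse.

    fit = max(0, 2 * inside / n - 1): 1 when every pixel lies inside the
    ellipse (perfect ellipse), 0 when half or fewer do.  Degenerate objects
    return 0.
    """
    if obj.n_pixels < 3:
        return 0.0
    evals, evecs, centre = _covariance_eigs(obj)
    if evals[0] <= 0:
        return 0.0
    # scale moment axes so the ellipse area equals the object pixel area
    ratio = np.sqrt(evals[1] / evals[0])
    b = np.sqrt(obj.n_pixels / (np.pi * ratio))
    a = b * ratio
    xy = np.column_stack([obj.cols, obj.rows]).astype(float) - centre
    proj = xy @ evecs  # columns: minor then major axis direction
    inside = (proj[:, 1] / a) ** 2 + (proj[:, 0] / b) ** 2 <= 1.0
    return max(0.0, 2.0 * inside.sum() / obj.n_pixels - 1.0)


def length_width(obj: ImageObject) -> float:
    """Elongation: sqrt of the major/minor covariance eigenvalue ratio."""
    if obj.n_pixels < 2:
        return 1.0
    evals, _, _ = _covariance_eigs(obj)
    if evals[0] <= 1e-12:
        return LENGTH_WIDTH_CAP
    return float(np.sqrt(evals[1] / evals[0]))


def band_stats(obj: ImageObject, grid: np.ndarray):
    """Mean and population standard deviation (divisor n) over the object."""
    v = obj.values_from(grid)
    return float(v.mean()), float(v.std(ddof=0))


def compute_features(obj: ImageObject, scene=None, ndvi=None) -> dict:
    """Populate the full object feature set on ``obj.features``."""
    f = obj.features
    f["area_m2"] = obj.area_m2
    f["n_pixels"] = obj.n_pixels
    f["roundness"] = roundness(obj)
    f["elliptical_fit"] = elliptical_fit(obj)
    f["length_width"] = length_width(obj)
    if scene is not None:
        for role in scene.band_roles:
            m, s = band_stats(obj, scene.band(role))
            f[f"{role}_mean"] = m
            f[f"{role}_sd"] = s
    if ndvi is not None:
        grid = ndvi.values if hasattr(ndvi, "values") else ndvi
        m, s = band_stats(obj, grid)
        f["ndvi_mean"] = m
        f["ndvi_sd"] = s
    return f
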