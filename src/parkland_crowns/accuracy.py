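"""Accuracy assessment: detection and delineation statistics.

Detection accuracy compares delineated crown objects against a field
inventory of reference trees.  A reference tree matched one-to-one with a
crown object is an individual tree detection (ITD); several trees matched to
the same object are crown cluster detections (CCD); an unmatched tree is an
omission (O) and a treeless crown object a commission (C).  The overall
score is the Accuracy Index

    AI (%) = (n - (O + C)) / n * 100

with n the number of reference trees.  Delineation accuracy compares
field-measured crown area CA = pi * (D1/2) * (D2/2) (elliptical crown
assumption; D1, D2 the two crown diameters) with delineated object area via
Spearman's rank correlation, the mean absolute error (MAE), the mean
relative error (MRE, mean of |error|/field CA in percent) and the mean bias
error (MBE, mean delineated minus mean field CA).  Plot-level canopy cover
aggregates crown area as a percentage of the 50 m x 50 m plot area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ReferenceTree",
    "DetectionResult",
    "DelineationStats",
    "crown_area",
    "accuracy_index",
    "match_detections",
    "delineation_stats",
    "cluster_reference_area",
    "canopy_cover",
    "read_trees_csv",
    "write_trees_csv",
]

#: minimum stem diameter for inclusion in the survey (cm)
DBH_MIN_CM = 5.0
#: side length of a field inventory plot (m)
PLOT_SIDE_M = 50.0

TREE_CSV_COLUMNS = ["tree_id", "x", "y", "species", "dbh_cm", "height_m",
                    "d1_m", "d2_m", "land_use", "plot_id"]


def crown_area(d1_m: float, d2_m: float) -> float:
    """Elliptical crown area CA = pi * (D1/2) * (D2/2)."""
    if d1_m < 0 or d2_m < 0:
        raise ValueError("crown diameters must be non-negative")
    return math.pi * (d1_m / 2.0) * (d2_m / 2.0)


@dataclass
class ReferenceTree:
    """One field-inventory record (stem position, size, crown diameters)."""

    tree_id: int
    x: float
    y: float
    species: str = ""
    dbh_cm: float = float("nan")
    height_m: float = float("nan")
    d1_m: float = 0.0
    d2_m: float = 0.0
    land_use: str = "active_field"   # active_field | fallow
    plot_id: int = 0

    def __post_init__(self):
        if self.d2_m > self.d1_m:    # D1 is the largest axis by definition
            self.d1_m, self.d2_m = self.d2_m, self.d1_m

    @property
    def ca_m2(self) -> float:
        return crown_area(self.d1_m, self.d2_m)


def accuracy_index(n: int, o: int, c: int) -> float:
    """AI (%) = (n - (O + C)) / n * 100.

    May be negative when O + C > n (heavily over-segmented output); that is
    a legal value of the index, not an error.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if o < 0 or c < 0:
        raise ValueError("O and C must be non-negative")
    return (n - (o + c)) / n * 100.0


@dataclass
class DetectionResult:
    """Outcome of matching reference trees against a crown map."""

    tree_status: dict            # tree_id -> "ITD" | "CCD" | "omission"
    tree_crown: dict             # tree_id -> crown_id or None
    crown_trees: dict            # crown_id -> list of tree_ids
    n: int = 0
    itd: int = 0
    ccd: int = 0
    omissions: int = 0
    commissions: int = 0

    @property
    def itd_rate(self) -> float:
        return self.itd / self.n * 100.0 if self.n else 0.0

    @property
    def ccd_rate(self) -> float:
        return self.ccd / self.n * 100.0 if self.n else 0.0

    @property
    def detection_rate(self) -> float:
        """ITC and crown clusters both count as detections (100 - OE)."""
        return (self.itd + self.ccd) / self.n * 100.0 if self.n else 0.0

    @property
    def oe_rate(self) -> float:
        return self.omissions / self.n * 100.0 if self.n else 0.0

    @property
    def ce_rate(self) -> float:
        return self.commissions / self.n * 100.0 if self.n else 0.0

    @property
    def accuracy_index(self) -> float:
        return accuracy_index(self.n, self.omissions, self.commissions)

    def summary(self) -> dict:
        return {
            "n": self.n, "ITD": self.itd, "CCD": self.ccd,
            "O": self.omissions, "C": self.commissions,
            "ITD_pct": self.itd_rate, "CCD_pct": self.ccd_rate,
            "DR_pct": self.detection_rate, "OE_pct": self.oe_rate,
            "CE_pct": self.ce_rate, "AI_pct": self.accuracy_index,
        }


def _ellipse_pixels(tree: ReferenceTree, scene) -> tuple:
    """Fine pixels covered by the tree's elliptical crown footprint
    (axis-aligned; orientation is not surveyed)."""
    r1, r2 = tree.d1_m / 2.0, tree.d2_m / 2.0
    if r1 <= 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    corners_r, corners_c = scene.map_to_pixel(
        np.array([tree.x - r1, tree.x + r1]),
        np.array([tree.y - r2, tree.y + r2]))
    r_lo = max(0, int(np.floor(min(corners_r))))
    r_hi = min(scene.shape[0] - 1, int(np.ceil(max(corners_r))))
    c_lo = max(0, int(np.floor(min(corners_c))))
    c_hi = min(scene.shape[1] - 1, int(np.ceil(max(corners_c))))
    if r_hi < r_lo or c_hi < c_lo:
        return np.array([], dtype=int), np.array([], dtype=int)
    rr, cc = np.mgrid[r_lo:r_hi + 1, c_lo:c_hi + 1]
    x, y = scene.pixel_to_map(rr, cc)
    inside = ((x - tree.x) / r1) ** 2 + ((y - tree.y) / max(r2, 1e-9)) ** 2 <= 1.0
    return rr[inside], cc[inside]


def match_detections(labels: np.ndarray, trees, scene) -> DetectionResult:
    """Associate reference trees with crown objects.

    A tree matches the crown containing its stem point; if the stem falls on
    background (GPS offset), the fallback is the crown with the largest
    overlap with the tree's elliptical footprint.  Crowns with exactly one
    tree are ITD, with several trees CCD (for every member tree); unmatched
    trees are omissions and treeless crowns commissions.
    """
    ids = [t.tree_id for t in trees]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate tree ids in reference data")
    labels = np.asarray(labels)
    tree_crown: dict = {}
    for t in trees:
        row, col = scene.map_to_pixel(t.x, t.y)
        r, c = int(round(row)), int(round(col))
        crown = None
        if 0 <= r < labels.shape[0] and 0 <= c < labels.shape[1] \
                and labels[r, c] > 0:
            crown = int(labels[r, c])
        else:
            rr, cc = _ellipse_pixels(t, scene)
            if rr.size:
                hit = labels[rr, cc]
                hit = hit[hit > 0]
                if hit.size:
                    vals, counts = np.unique(hit, return_counts=True)
                    crown = int(vals[np.argmax(counts)])
        tree_crown[t.tree_id] = crown
    crown_trees: dict = {}
    for tid, cid in tree_crown.items():
        if cid is not None:
            crown_trees.setdefault(cid, []).append(tid)
    tree_status = {}
    itd = ccd = 0
    for tid, cid in tree_crown.items():
        if cid is None:
            tree_status[tid] = "omission"
        elif len(crown_trees[cid]) == 1:
            tree_status[tid] = "ITD"
            itd += 1
        else:
            tree_status[tid] = "CCD"
            ccd += 1
    all_crowns = set(np.unique(labels)) - {0}
    commissions = len(all_crowns - set(crown_trees))
    return DetectionResult(
        tree_status=tree_status, tree_crown=tree_crown,
        crown_trees=crown_trees, n=len(trees), itd=itd, ccd=ccd,
        omissions=sum(1 for s in tree_status.values() if s == "omission"),
        commissions=commissions)


@dataclass
class DelineationStats:
    """Crown-area agreement between field and delineated measurements."""

    r_s: float
    mae_m2: float
    mre_pct: float
    mbe_m2: float
    n_pairs: int
    excluded_pairs: int = 0


def delineation_stats(pairs) -> DelineationStats:
    """MAE/MRE/MBE and Spearman's rho over (field CA, delineated CA) pairs.

    MRE excludes (and counts) pairs with zero field CA.  Requires at least
    two pairs for the rank correlation.
    """
    pairs = [(float(f), float(d)) for f, d in pairs]
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    f = np.array([p[0] for p in pairs])
    d = np.array([p[1] for p in pairs])
    err = d - f
    mae = float(np.abs(err).mean())
    mbe = float(d.mean() - f.mean())
    ok = f > 0
    mre = float((np.abs(err[ok]) / f[ok]).mean() * 100.0) if ok.any() else float("nan")
    if np.all(f == f[0]) or np.all(d == d[0]):
        r_s = 1.0 if np.allclose(f, d) else 0.0
    else:
        r_s = float(sps.spearmanr(f, d).statistic)
    return DelineationStats(r_s=r_s, mae_m2=mae, mre_pct=mre, mbe_m2=mbe,
                            n_pairs=len(pairs),
                            excluded_pairs=int((~ok).sum()))


def cluster_reference_area(trees) -> float:
    """Aggregate field CA of the trees in one crown-cluster detection
    (plain sum, no overlap correction)."""
    return float(sum(t.ca_m2 for t in trees))


def delineation_pairs(result: DetectionResult, trees, labels, scene,
                      level: str = "all"):
    """Build (field CA, delineated CA) pairs from a matching.

    ``level``: "itc" (one-to-one matches only), "cluster" (aggregated CCD
    crowns) or "all" (both).  Delineated CA is the pixel area of the crown.
    """
    by_id = {t.tree_id: t for t in trees}
    labels = np.asarray(labels)
    counts = np.bincount(labels.ravel())
    px_area = scene.pixel_area_m2
    pairs = []
    for cid, tids in result.crown_trees.items():
        delin = counts[cid] * px_area if cid < len(counts) else 0.0
        if len(tids) == 1 and level in ("itc", "all"):
            pairs.append((by_id[tids[0]].ca_m2, delin))
        elif len(tids) > 1 and level in ("cluster", "all"):
            pairs.append((cluster_reference_area([by_id[i] for i in tids]),
                          delin))
    return pairs


def canopy_cover(crowns_or_trees, plot_bounds, scene=None,
                 labels=None) -> float:
    """Plot-level canopy cover in percent of the plot area.

    For delineated output pass ``labels`` + ``scene``: crown pixels are
    clipped to the plot (all crown objects count, commissions included).
    For reference trees pass the tree list: the unclipped elliptical CA of
    every tree whose stem falls inside the plot is summed.
    ``plot_bounds`` is (xmin, ymin, xmax, ymax) in map coordinates.
    """
    x0, y0, x1, y1 = plot_bounds
    plot_area = (x1 - x0) * (y1 - y0)
    if plot_area <= 0:
        raise ValueError("plot area must be positive")
    if labels is not None:
        if scene is None:
            raise ValueError("scene required with labels")
        labels = np.asarray(labels)
        rr, cc = np.nonzero(labels > 0)
        x, y = scene.pixel_to_map(rr, cc)
        inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        return float(inside.sum() * scene.pixel_area_m2 / plot_area * 100.0)
    total = 0.0
    for t in crowns_or_trees:
        if x0 <= t.x < x1 and y0 <= t.y < y1:
            total += t.ca_m2
    return float(total / plot_area * 100.0)


# ---------------------------------------------------------------------------
# Reference-tree CSV I/O (field-inventory schema)
# ---------------------------------------------------------------------------

def read_trees_csv(path, dbh_min_cm: float | None = DBH_MIN_CM):
    """Read reference trees; rows below the DBH survey floor are dropped
    when ``dbh_min_cm`` is given."""
    df = pd.read_csv(path)
    missing = [c for c in TREE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trees CSV missing columns: {missing}")
    trees = []
    for _, r in df.iterrows():
        if dbh_min_cm is not None and not np.isnan(r["dbh_cm"]) \
                and r["dbh_cm"] < dbh_min_cm:
            continue
        trees.append(ReferenceTree(
            tree_id=int(r["tree_id"]), x=float(r["x"]), y=float(r["y"]),
            species=str(r["species"]), dbh_cm=float(r["dbh_cm"]),
            height_m=float(r["height_m"]), d1_m=float(r["d1_m"]),
            d2_m=float(r["d2_m"]), land_use=str(r["land_use"]),
            plot_id=int(r["plot_id"])))
    return trees


def write_trees_csv(path, trees) -> None:
    df = pd.DataFrame([{
        "tree_id": t.tree_id, "x": t.x, "y": t.y, "species": t.species,
        "dbh_cm": t.dbh_cm, "height_m": t.height_m, "d1_m": t.d1_m,
        "d2_m": t.d2_m, "land_use": t.land_use, "plot_id": t.plot_id,
    } for t in trees], columns=TREE_CSV_COLUMNS)
    df.to_csv(path, index=False)
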