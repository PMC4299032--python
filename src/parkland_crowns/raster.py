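"""Raster substrate: multispectral scene container, radiometric calibration,
NDVI, and fine/coarse grid handling.

The pipeline operates on an 8-band high-resolution image (0.5 m grid) whose
band roles follow the WorldView-2 layout: coastal, blue, green, yellow, red,
red_edge, nir1, nir2.  Pixel values are on a top-of-atmosphere radiance scale
obtained from sensor digital numbers via per-band absolute calibration factor
and effective bandwidth.  Seeds for region growing are located on a coarser
grid (2 m, i.e. 4x4 fine-pixel blocks), which this module produces by block
averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = [
    "BAND_ROLES",
    "SceneRaster",
    "CalibrationTable",
    "NdviGrid",
    "ConfigurationError",
    "dn_to_toa_radiance",
    "compute_ndvi",
    "aggregate_to_coarse",
    "read_scene",
    "write_scene",
    "write_label_raster",
    "read_label_raster",
]

#: Canonical ordering of the eight WorldView-2-style band roles.
BAND_ROLES = (
    "coastal",
    "blue",
    "green",
    "yellow",
    "red",
    "red_edge",
    "nir1",
    "nir2",
)

#: Affine geotransform (a, b, c, d, e, f): x = c + a*col + b*row,
#: y = f + d*col + e*row.  Default: 0.5 m pixels, origin top-left, north up.
DEFAULT_GEOTRANSFORM = (0.5, 0.0, 0.0, 0.0, -0.5, 0.0)


class ConfigurationError(ValueError):
    """Raised for invalid band roles, calibration tables or grid factors."""


@dataclass
class SceneRaster:
    """Georeferenced multi-band image.

    Parameters
    ----------
    values : ndarray, shape (n_bands, rows, cols)
        Per-band pixel values on a TOA-radiance scale.
    band_roles : tuple of str
        Role name of each band, e.g. ``("coastal", ..., "nir2")``.  Every
        role must appear exactly once.
    pixel_size : float
        Ground edge length of a pixel in metres (default 0.5).
    geotransform : tuple of 6 floats
        Affine grid -> map coordinate mapping (see DEFAULT_GEOTRANSFORM).
    """

    values: np.ndarray
    band_roles: tuple = BAND_ROLES
    pixel_size: float = 0.5
    geotransform: tuple = DEFAULT_GEOTRANSFORM

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.band_roles = tuple(self.band_roles)
        if self.values.ndim != 3:
            raise ConfigurationError("values must be (bands, rows, cols)")
        if len(self.band_roles) != self.values.shape[0]:
            raise ConfigurationError(
                f"{len(self.band_roles)} roles for {self.values.shape[0]} bands"
            )
        if len(set(self.band_roles)) != len(self.band_roles):
            raise ConfigurationError("duplicate band role")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")

    @property
    def shape(self):
        """(rows, cols) of the pixel grid."""
        return self.values.shape[1:]

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size**2

    def band(self, role: str) -> np.ndarray:
        """Return the 2-D grid of the band with the given role."""
        try:
            i = self.band_roles.index(role)
        except ValueError:
            raise ConfigurationError(f"unknown band role {role!r}") from None
        return self.values[i]

    def pixel_to_map(self, row, col):
        """Map pixel centre (row, col) to map coordinates (x, y)."""
        a, b, c, d, e, f = self.geotransform
        col = np.asarray(col, dtype=float) + 0.5
        row = np.asarray(row, dtype=float) + 0.5
        return c + a * col + b * row, f + d * col + e * row

    def map_to_pixel(self, x, y):
        """Inverse of :meth:`pixel_to_map`; returns float (row, col)."""
        a, b, c, d, e, f = self.geotransform
        det = a * e - b * d
        dx = np.asarray(x, dtype=float) - c
        dy = np.asarray(y, dtype=float) - f
        col = (e * dx - b * dy) / det - 0.5
        row = (-d * dx + a * dy) / det - 0.5
        return row, col


@dataclass
class CalibrationTable:
    """Per-band absolute radiometric calibration.

    ``factors[role]`` is the absolute calibration factor (gain) and
    ``bandwidths[role]`` the effective bandwidth in micrometres; TOA radiance
    is ``DN * factor / bandwidth``.
    """

    factors: dict
    bandwidths: dict

    def __post_init__(self):
        for role, bw in self.bandwidths.items():
            if bw <= 0:
                raise ConfigurationError(
                    f"effective bandwidth for {role!r} must be > 0, got {bw}"
                )

    def gain(self, role: str) -> float:
        if role not in self.factors or role not in self.bandwidths:
            raise ConfigurationError(f"no calibration for band {role!r}")
        return self.factors[role] / self.bandwidths[role]


@dataclass
class NdviGrid:
    """NDVI values on the fine (0.5 m) or coarse (2 m) grid."""

    values: np.ndarray
    resolution: str = "fine"  # "fine" | "coarse"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.resolution not in ("fine", "coarse"):
            raise ConfigurationError("resolution must be 'fine' or 'coarse'")

    @property
    def shape(self):
        return self.values.shape


def dn_to_toa_radiance(
    dn: np.ndarray,
    cal: CalibrationTable,
    band_roles=BAND_ROLES,
    pixel_size: float = 0.5,
    geotransform=DEFAULT_GEOTRANSFORM,
) -> SceneRaster:
    """Convert digital numbers to top-of-atmosphere radiance.

    Each band is scaled by its absolute calibration factor divided by its
    effective bandwidth: ``L = DN * K / Δλ``.

    Parameters
    ----------
    dn : ndarray, shape (n_bands, rows, cols)
        Raw digital numbers.
    cal : CalibrationTable
        Must cover every role in ``band_roles``.
    """
    dn = np.asarray(dn, dtype=np.float64)
    if dn.ndim != 3 or dn.shape[0] != len(band_roles):
        raise ConfigurationError("dn must be (n_bands, rows, cols) matching roles")
    out = np.empty_like(dn)
    for i, role in enumerate(band_roles):
        out[i] = dn[i] * cal.gain(role)
    return SceneRaster(out, band_roles, pixel_size, geotransform)


def compute_ndvi(
    scene: SceneRaster, nir_role: str = "nir1", red_role: str = "red"
) -> NdviGrid:
    """NDVI = (NIR - Red) / (NIR + Red), defined as 0 where NIR + Red == 0.

    Zero-denominator pixels are radiometrically empty background; mapping
    them to 0 keeps them below every vegetation-mask threshold.
    """
    nir = scene.band(nir_role)
    red = scene.band(red_role)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom != 0, (nir - red) / np.where(denom == 0, 1, denom), 0.0)
    return NdviGrid(ndvi, "fine")


def aggregate_to_coarse(grid: np.ndarray, factor: int = 4) -> np.ndarray:
    """Block-average a fine grid into factor x factor coarse cells.

    Grids whose dimensions are not divisible by ``factor`` are edge-padded by
    replication first, so every fine pixel is owned by exactly one coarse
    cell.
    """
    if factor < 1 or int(factor) != factor:
        raise ConfigurationError(f"aggregation factor must be a positive int, got {factor}")
    factor = int(factor)
    g = np.asarray(grid, dtype=np.float64)
    pr = (-g.shape[0]) % factor
    pc = (-g.shape[1]) % factor
    if pr or pc:
        g = np.pad(g, ((0, pr), (0, pc)), mode="edge")
    h, w = g.shape[0] // factor, g.shape[1] // factor
    return g.reshape(h, factor, w, factor).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# TIFF I/O.  Band roles, pixel size and geotransform travel in the TIFF
# ImageDescription tag as JSON so a scene is one self-describing file.
# ---------------------------------------------------------------------------

def write_scene(path, scene: SceneRaster) -> None:
    """Write a SceneRaster as a multi-band float32 TIFF."""
    meta = {
        "band_roles": list(scene.band_roles),
        "pixel_size": scene.pixel_size,
        "geotransform": list(scene.geotransform),
    }
    tifffile.imwrite(
        str(path),
        scene.values.astype(np.float32),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_scene(path) -> SceneRaster:
    """Read a scene written by :func:`write_scene` (or any multi-band TIFF
    with a JSON ImageDescription carrying band_roles/pixel_size/geotransform;
    missing metadata falls back to the package defaults)."""
    with tifffile.TiffFile(str(path)) as tif:
        values = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if values.ndim == 2:
        values = values[None]
    roles = tuple(meta.get("band_roles", BAND_ROLES[: values.shape[0]]))
    return SceneRaster(
        values.astype(np.float64),
        roles,
        float(meta.get("pixel_size", 0.5)),
        tuple(meta.get("geotransform", DEFAULT_GEOTRANSFORM)),
    )


def write_label_raster(path, labels: np.ndarray, pixel_size: float = 0.5,
                       geotransform=DEFAULT_GEOTRANSFORM) -> None:
    """Write an integer label map (e.g. crown ids, 0 = background)."""
    meta = {"pixel_size": pixel_size, "geotransform": list(geotransform)}
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.int32),
                     description=json.dumps(meta), photometric="minisblack")


def read_label_raster(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.int64)
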