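"""Shared fixtures: small rasters, shapes and synthetic scenes."""

import numpy as np
import pytest

from parkland_crowns.raster import BAND_ROLES, SceneRaster
from parkland_crowns.synthetic import SceneSpec, generate_scene


def scene_from_fields(ndvi, nir, pixel_size=0.5):
    """Build an 8-band SceneRaster whose NDVI/NIR equal the given fields.

    The red band is solved from red = nir * (1 - ndvi) / (1 + ndvi); the
    remaining bands are simple affine mixes so all 8 roles exist.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    nir = np.asarray(nir, dtype=float)
    nd = np.clip(ndvi, -0.99, 0.99)
    red = nir * (1 - nd) / (1 + nd)
    bands = {
        "coastal": 0.85 * red + 8, "blue": 0.9 * red + 5,
        "green": 0.95 * red + 10, "yellow": red + 5, "red": red,
        "red_edge": 0.4 * red + 0.6 * nir, "nir1": nir, "nir2": 0.95 * nir,
    }
    values = np.stack([bands[b] for b in BAND_ROLES])
    return SceneRaster(values, BAND_ROLES, pixel_size,
                       (pixel_size, 0, 0, 0, -pixel_size,
                        ndvi.shape[0] * pixel_size))


@pytest.fixture(scope="session")
def easy_scene():
    """Isolated large crowns on bare soil, no GPS jitter: the regime where
    the pipeline should recover essentially every tree."""
    spec = SceneSpec(rng_seed=7, cluster_fraction=0.0, gps_jitter_sd=0.0,
                     d1_min_m=4.0)
    scene, truth = generate_scene(spec)
    return spec, scene, truth


@pytest.fixture(scope="session")
def easy_crown_map(easy_scene):
    from parkland_crowns.delineation import delineate_scene
    _, scene, _ = easy_scene
    return delineate_scene(scene)
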