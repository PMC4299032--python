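"""Vectorisation of crown label maps to GeoJSON polygons."""

from __future__ import annotations

import json

import numpy as np
from shapely.geometry import Polygon, mapping
from skimage import measure

__all__ = ["crown_polygons", "crowns_to_geojson"]


def crown_polygons(crown_map):
    """Boundary polygon of each crown in map coordinates.

    Marching-squares contours of the padded binary mask of every crown,
    converted through the scene geotransform.  Returns
    ``{crown_id: shapely geometry}``.
    """
    scene = crown_map.scene
    out = {}
    for obj in crown_map.crowns:
        m = np.zeros(scene.shape, dtype=np.uint8)
        m[obj.rows, obj.cols] = 1
        padded = np.pad(m, 1)
        rings = measure.find_contours(padded.astype(float), 0.5)
        polys = []
        for ring in rings:
            rr = ring[:, 0] - 1.0
            cc = ring[:, 1] - 1.0
            x, y = scene.pixel_to_map(rr, cc)
            if len(x) >= 4:
                p = Polygon(np.column_stack([x, y]))
                if p.is_valid and p.area > 0:
                    polys.append(p)
        if not polys:
            continue
        polys.sort(key=lambda p: p.area, reverse=True)
        geom = polys[0]
        for hole_or_part in polys[1:]:
            if geom.contains(hole_or_part):
                geom = geom.difference(hole_or_part)
            else:
                geom = geom.union(hole_or_part)
        out[obj.crown_id] = geom
    return out


def crowns_to_geojson(crown_map, path=None) -> dict:
    """GeoJSON FeatureCollection of the crown polygons with the per-object
    feature set as properties; optionally written to ``path``."""
    polys = crown_polygons(crown_map)
    features = []
    for obj in crown_map.crowns:
        if obj.crown_id not in polys:
            continue
        props = {
            "id": obj.crown_id,
            "label": obj.label,
            "generation": obj.generation,
            "species_type": obj.species_type,
            "area_m2": obj.area_m2(crown_map.scene.pixel_size),
        }
        props.update({k: float(v) for k, v in obj.features.items()
                      if isinstance(v, (int, float))})
        features.append({
            "type": "Feature",
            "geometry": mapping(polys[obj.crown_id]),
            "properties": props,
        })
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
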