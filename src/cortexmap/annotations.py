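"""Reading and writing annotation polygons.

GeoJSON is the canonical interchange format: each Feature carries a Polygon
geometry and a ``label`` property ("cortex", "tumor" or "slide-outline").
A minimal reader for scanner-style annotation XML (NDPA renamed to .xml) is
also provided; it parses only point lists and title labels, which is all a
mask-generation pipeline needs.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .registration import AnnotationSet

__all__ = ["read_geojson", "write_geojson", "read_annotation_xml"]


def read_geojson(path, scale_to_map: float = 1.0) -> AnnotationSet:
    """Load a FeatureCollection of labeled polygons."""
    doc = json.loads(Path(path).read_text())
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    polys = []
    for feat in feats:
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"unsupported geometry type {geom.get('type')!r}")
        label = feat.get("properties", {}).get("label", "cortex")
        exterior = np.asarray(geom["coordinates"][0], dtype=float)
        if len(exterior) >= 2 and np.allclose(exterior[0], exterior[-1]):
            exterior = exterior[:-1]  # GeoJSON rings repeat the first vertex
        polys.append((label, exterior))
    return AnnotationSet(polygons=polys, scale_to_map=scale_to_map)


def write_geojson(ann: AnnotationSet, path) -> None:
    feats = []
    for label, verts in ann.polygons:
        ring = [[float(x), float(y)] for x, y in verts]
        ring.append(ring[0])
        feats.append(
            {
                "type": "Feature",
                "properties": {"label": label},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}, indent=1)
    )


def read_annotation_xml(path, scale_to_map: float = 1.0) -> AnnotationSet:
    """Minimal scanner-annotation XML reader.

    Expected layout::

        <annotations>
          <ndpviewstate><title>cortex</title>
            <annotation><pointlist>
              <point><x>…</x><y>…</y></point> …
            </pointlist></annotation>
          </ndpviewstate> …
        </annotations>
    """
    root = ET.parse(str(path)).getroot()
    polys = []
    for state in root.iter("ndpviewstate"):
        title = state.findtext("title", default="cortex").strip()
        for plist in state.iter("pointlist"):
            pts = [
                (float(p.findtext("x")), float(p.findtext("y")))
                for p in plist.iter("point")
            ]
            polys.append((title, np.asarray(pts, dtype=float)))
    if not polys:
        raise ValueError(f"no annotation point lists found in {path}")
    return AnnotationSet(polygons=polys, scale_to_map=scale_to_map)
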