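"""Minimal GeoJSON reading/writing for the planar-meter vectors the tool uses.

GeoJSON here always carries projected metric coordinates (the pipeline
rejects anything that looks like lon/lat degrees); the CRS is whatever
metric projection the caller's data are in and is passed through untouched.
Writing is deterministic: fixed key order, fixed float formatting, so equal
inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from typing import Iterable


def read_features(path) -> list[dict]:
    """Return the feature list of a GeoJSON FeatureCollection (or wrap a
    bare Feature / geometry as a one-feature list)."""
    with open(path) as fh:
        obj = json.load(fh)
    t = obj.get("type")
    if t == "FeatureCollection":
        return obj["features"]
    if t == "Feature":
        return [obj]
    if t in ("Point", "LineString", "MultiLineString", "Polygon", "MultiPoint"):
        return [{"type": "Feature", "geometry": obj, "properties": {}}]
    raise ValueError(f"unsupported GeoJSON object type: {t!r}")


def _round_coords(coords, ndigits: int):
    if isinstance(coords, (int, float)):
        return round(float(coords), ndigits)
    return [_round_coords(c, ndigits) for c in coords]


def feature_collection(features: Iterable[dict], ndigits: int = 3) -> dict:
    feats = []
    for f in features:
        g = dict(f["geometry"])
        g["coordinates"] = _round_coords(g["coordinates"], ndigits)
        feats.append({
            "type": "Feature",
            "geometry": {"type": g["type"], "coordinates": g["coordinates"]},
            "properties": f.get("properties", {}),
        })
    return {"type": "FeatureCollection", "features": feats}


def write_features(features: Iterable[dict], path, ndigits: int = 3) -> None:
    """Write a FeatureCollection with millimetre-rounded coordinates;
    byte-identical for identical inputs."""
    obj = feature_collection(features, ndigits=ndigits)
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def point_feature(x: float, y: float, **properties) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [x, y]},
        "properties": properties,
    }


def line_feature(coords, **properties) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": [list(c) for c in coords]},
        "properties": properties,
    }
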