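"""GeoJSON reading/writing for city layers.

All layers live in a projected planar coordinate system in metres.
Layers whose coordinates all fit inside longitude/latitude ranges are
rejected as (probably) geographic with a hint to reproject.  Floats are
serialized with full round-trip precision, so a write -> read cycle is
lossless for geometry and exact for attributes, and identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Optional, Sequence, Tuple

from shapely.geometry import Polygon, mapping, shape

from .e2sfca import Facility, PopulationPoint
from .modes import TransitStop
from .network import GeoSegment

__all__ = [
    "SchemaError",
    "write_geojson",
    "read_geojson",
    "segments_to_features",
    "features_to_segments",
    "write_bundle",
    "read_bundle",
]

#: layer name -> filename used by write_bundle/read_bundle
BUNDLE_FILES = {
    "roads": "roads.geojson",
    "sidewalks": "sidewalks.geojson",
    "trails": "trails.geojson",
    "intersections": "intersections.geojson",
    "bus_routes": "bus_routes.geojson",
    "bus_stops": "bus_stops.geojson",
    "train_lines": "train_lines.geojson",
    "stations": "stations.geojson",
    "das": "das.geojson",
    "clinics": "clinics.geojson",
}


class SchemaError(ValueError):
    """Raised when a feature is missing required properties or uses
    geographic coordinates."""


def _check_planar(coords: Sequence[Tuple[float, float]], context: str) -> None:
    """Layer-level heuristic: a projected metre layer of any extent will
    not fit entirely inside longitude/latitude ranges."""
    if coords and all(abs(x) <= 180.0 and abs(y) <= 90.0 for x, y in coords):
        raise SchemaError(
            f"{context}: coordinates look geographic (degrees); reproject "
            "the layer to a planar metre CRS before loading"
        )


def write_geojson(path: str, features: List[dict]) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, separators=(",", ":"))
        fh.write("\n")


def read_geojson(path: str) -> List[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    return doc["features"]


def segments_to_features(segments: Sequence[GeoSegment]) -> List[dict]:
    feats = []
    for s in segments:
        props = {"id": s.id, "mode": s.mode}
        if s.class_label is not None:
            props["class_label"] = s.class_label
        if s.speed_kmh is not None:
            props["speed_kmh"] = s.speed_kmh
        feats.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in s.coords]},
            "properties": props,
        })
    return feats


def features_to_segments(features: Sequence[dict], default_mode: str,
                         require_class: bool = False) -> List[GeoSegment]:
    out: List[GeoSegment] = []
    all_coords: List[Tuple[float, float]] = []
    for feat in features:
        props = feat.get("properties") or {}
        fid = props.get("id", f"feature_{len(out)}")
        geom = feat.get("geometry") or {}
        if geom.get("type") == "LineString":
            parts = [geom["coordinates"]]
        elif geom.get("type") == "MultiLineString":
            parts = geom["coordinates"]
        else:
            raise SchemaError(f"feature {fid!r}: expected LineString geometry")
        if require_class and "class_label" not in props:
            raise SchemaError(f"feature {fid!r}: missing required property "
                              "'class_label'")
        for k, coords in enumerate(parts):
            coords = [(float(x), float(y)) for x, y in coords]
            all_coords.extend(coords)
            out.append(GeoSegment(
                id=fid if len(parts) == 1 else f"{fid}/{k}",
                mode=props.get("mode", default_mode),
                coords=coords,
                class_label=props.get("class_label"),
                speed_kmh=props.get("speed_kmh"),
            ))
    _check_planar(all_coords, "layer")
    return out


def _point_feature(fid: str, xy: Tuple[float, float], props: dict) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [float(xy[0]), float(xy[1])]},
        "properties": {"id": fid, **props},
    }


def _point_of(feat: dict, context: str) -> Tuple[float, float]:
    geom = feat.get("geometry") or {}
    if geom.get("type") != "Point":
        raise SchemaError(f"{context}: expected Point geometry")
    x, y = geom["coordinates"]
    return float(x), float(y)


def write_bundle(bundle, out_dir: str) -> Dict[str, str]:
    """Write every layer of a city bundle as GeoJSON; returns the mapping
    layer name -> path."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def path_of(layer: str) -> str:
        p = os.path.join(out_dir, BUNDLE_FILES[layer])
        paths[layer] = p
        return p

    for layer in ("roads", "sidewalks", "trails", "bus_routes", "train_lines"):
        write_geojson(path_of(layer), segments_to_features(getattr(bundle, layer)))
    write_geojson(path_of("intersections"),
                  [_point_feature(i, xy, {}) for i, xy in bundle.intersections])
    for layer in ("bus_stops", "stations"):
        write_geojson(path_of(layer), [
            _point_feature(s.id, s.location, {"route_id": s.route_id})
            for s in getattr(bundle, layer)
        ])
    write_geojson(path_of("clinics"), [
        _point_feature(c.id, c.location, {"providers": c.providers})
        for c in bundle.clinics
    ])
    da_feats = []
    for p in bundle.das:
        poly = bundle.da_polygons[p.id]
        da_feats.append({
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {
                "id": p.id,
                "centroid_x": float(p.location[0]),
                "centroid_y": float(p.location[1]),
                "population": p.population,
                "area_km2": p.area_km2,
                "covariates": p.covariates,
            },
        })
    write_geojson(path_of("das"), da_feats)
    return paths


def read_bundle(layer_dir: str):
    """Read a city bundle previously written by :func:`write_bundle`."""
    from .synth import CityBundle

    def feats(layer: str) -> List[dict]:
        p = os.path.join(layer_dir, BUNDLE_FILES[layer])
        if not os.path.exists(p):
            return []
        return read_geojson(p)

    def stops(layer: str) -> List[TransitStop]:
        out = []
        for f in feats(layer):
            props = f.get("properties") or {}
            fid = props.get("id")
            if fid is None or "route_id" not in props:
                raise SchemaError(f"{layer} feature: missing 'id'/'route_id'")
            out.append(TransitStop(id=fid, location=_point_of(f, fid),
                                   route_id=props["route_id"]))
        if out:
            _check_planar([s.location for s in out], layer)
        return out

    das: List[PopulationPoint] = []
    da_polygons: Dict[str, Polygon] = {}
    da_coords: List[Tuple[float, float]] = []
    for f in feats("das"):
        props = f.get("properties") or {}
        fid = props.get("id")
        for req in ("centroid_x", "centroid_y", "population", "area_km2"):
            if req not in props:
                raise SchemaError(f"DA feature {fid!r}: missing property {req!r}")
        poly = shape(f["geometry"])
        da_coords.extend(poly.exterior.coords)
        das.append(PopulationPoint(
            id=fid, location=(props["centroid_x"], props["centroid_y"]),
            population=props["population"], area_km2=props["area_km2"],
            covariates=dict(props.get("covariates") or {})))
        da_polygons[fid] = poly
    if da_coords:
        _check_planar(da_coords, "das")

    clinics = []
    for f in feats("clinics"):
        props = f.get("properties") or {}
        fid = props.get("id")
        if "providers" not in props:
            raise SchemaError(f"clinic {fid!r}: missing property 'providers'")
        clinics.append(Facility(id=fid, location=_point_of(f, fid),
                                providers=props["providers"]))

    return CityBundle(
        config=None,
        roads=features_to_segments(feats("roads"), "road", require_class=True),
        sidewalks=features_to_segments(feats("sidewalks"), "sidewalk"),
        trails=features_to_segments(feats("trails"), "trail"),
        intersections=[
            ((f.get("properties") or {}).get("id", f"int_{k}"),
             _point_of(f, f"intersection {k}"))
            for k, f in enumerate(feats("intersections"))
        ],
        bus_routes=features_to_segments(feats("bus_routes"), "bus"),
        bus_stops=stops("bus_stops"),
        train_lines=features_to_segments(feats("train_lines"), "train"),
        stations=stops("stations"),
        das=das,
        da_polygons=da_polygons,
        clinics=clinics,
    )
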