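"""Mode-specific network builders: driving, walking, and multimodal transit.

Driving uses the road layer with class-specific speed limits.  Walking
merges per-block sidewalks, trails and pathways with generated crosswalks
at a constant pedestrian speed.  The multimodal network overlays bus
routes and train lines on the walking network, entered only at stops and
stations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from shapely.geometry import LineString, Point
from shapely.ops import substring
from shapely.strtree import STRtree

from .network import (
    ConfigurationError,
    GeoSegment,
    TravelNetwork,
    build_graph,
    distance_to_time,
    snap_point,
)

__all__ = [
    "SpeedMap",
    "TransitStop",
    "TransitLayer",
    "DataError",
    "build_road_network",
    "generate_crosswalks",
    "build_walk_network",
    "build_multimodal_network",
]

#: road-class speed limits, km/h
DEFAULT_ROAD_SPEEDS = {"Collector": 50.0, "Major": 65.0, "Expressway": 80.0, "Alley": 15.0}

#: descriptive road-class vocabulary mapped onto the speed-table classes
DEFAULT_CLASS_ALIASES = {
    "primary highway": "Expressway",
    "secondary highway": "Major",
    "major road": "Major",
    "local road": "Collector",
}


class DataError(ValueError):
    """Raised for inconsistent input layers (e.g. a stop off its route)."""


@dataclass
class SpeedMap:
    """Travel-speed configuration for all modes.

    Road classes default to the municipal speed-limit table (Collector 50,
    Major 65, Expressway 80, Alley 15 km/h); walking is a constant
    4.8 km/h; bus routes without a road class fall back to
    ``bus_default_kmh``; train speed is a single configurable value.
    """

    road_speeds: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROAD_SPEEDS))
    aliases: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_ALIASES))
    walking_speed_kmh: float = 4.8
    bus_default_kmh: float = 40.0
    train_kmh: float = 45.0

    def __post_init__(self) -> None:
        for name, v in [("walking_speed_kmh", self.walking_speed_kmh),
                        ("bus_default_kmh", self.bus_default_kmh),
                        ("train_kmh", self.train_kmh)]:
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        for cls, v in self.road_speeds.items():
            if v <= 0:
                raise ConfigurationError(f"road class {cls!r}: speed must be positive")

    def resolve_road(self, class_label: Optional[str]) -> float:
        if class_label is None:
            raise ConfigurationError("road segment without class_label")
        label = self.aliases.get(class_label, class_label)
        try:
            return self.road_speeds[label]
        except KeyError:
            raise ConfigurationError(f"unknown road class {class_label!r}") from None

    def resolve_transit(self, seg: GeoSegment) -> float:
        if seg.mode == "train":
            return self.train_kmh
        if seg.class_label is not None:
            return self.resolve_road(seg.class_label)
        return self.bus_default_kmh


@dataclass
class TransitStop:
    id: str
    location: Tuple[float, float]
    route_id: str


@dataclass
class TransitLayer:
    """Bus/train routes with their boarding points."""

    routes: Sequence[GeoSegment]
    stops: Sequence[TransitStop]

    def stops_for(self, route_id: str) -> List[TransitStop]:
        return [s for s in self.stops if s.route_id == route_id]


def build_road_network(roads: Iterable[GeoSegment], speeds: SpeedMap,
                       snap_tol_m: float = 0.5) -> TravelNetwork:
    """Driving network: one edge per road segment at its class speed."""
    resolved = []
    for seg in roads:
        speed = seg.speed_kmh if seg.speed_kmh is not None else speeds.resolve_road(seg.class_label)
        resolved.append(GeoSegment(id=seg.id, mode="road", coords=seg.coords,
                                   class_label=seg.class_label, speed_kmh=speed))
    return build_graph(resolved, snap_tol_m)


# ---------------------------------------------------------------------------
# crosswalk generation
# ---------------------------------------------------------------------------

def _circle_crossings(circle_center: Tuple[float, float], r: float,
                      coords: Sequence[Tuple[float, float]]) -> List[float]:
    """Angles (radians) where a polyline crosses the circle |p - c| = r."""
    cx, cy = circle_center
    out: List[float] = []
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        dx, dy = x1 - x0, y1 - y0
        fx, fy = x0 - cx, y0 - cy
        a = dx * dx + dy * dy
        if a == 0:
            continue
        b = 2.0 * (fx * dx + fy * dy)
        c = fx * fx + fy * fy - r * r
        disc = b * b - 4 * a * c
        if disc < 0:
            continue
        sq = math.sqrt(disc)
        for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
            if -1e-12 <= t <= 1 + 1e-12:
                px, py = x0 + t * dx, y0 + t * dy
                out.append(math.atan2(py - cy, px - cx))
    return out


def _arc_coords(center: Tuple[float, float], r: float, a0: float, a1: float,
                max_step_rad: float = math.radians(5.0)) -> List[Tuple[float, float]]:
    """Polyline along the circle from angle a0 to a1 (counter-clockwise),
    every vertex exactly on the circle."""
    cx, cy = center
    span = (a1 - a0) % (2 * math.pi)
    if span == 0:
        span = 2 * math.pi
    n = max(1, int(math.ceil(span / max_step_rad)))
    return [
        (cx + r * math.cos(a0 + span * k / n), cy + r * math.sin(a0 + span * k / n))
        for k in range(n + 1)
    ]


def generate_crosswalks(sidewalks: Sequence[GeoSegment],
                        intersections: Sequence[Tuple[str, Tuple[float, float]]],
                        roads: Sequence[GeoSegment],
                        radius_m: float = 18.0) -> List[GeoSegment]:
    """Derive street-crossing links from circles around road intersections.

    For each intersection point: (1) take the circle of ``radius_m``
    around it (the boundary of the buffer); (2) split the circle at its
    crossing points with sidewalk segments; (3) keep only the resulting
    arcs that cross a road segment.  Retained arcs become ``crosswalk``
    segments whose endpoints lie on sidewalks, bridging adjacent sidewalk
    blocks across the street.

    ``intersections`` is a sequence of ``(id, (x, y))`` pairs.  An empty
    intersection layer yields an empty result.
    """
    if not intersections:
        return []
    sw_geoms = [LineString(s.coords) for s in sidewalks]
    sw_tree = STRtree(sw_geoms) if sw_geoms else None
    road_geoms = [LineString(s.coords) for s in roads]
    road_tree = STRtree(road_geoms) if road_geoms else None

    out: List[GeoSegment] = []
    for pt_id, (cx, cy) in intersections:
        if sw_tree is None:
            continue
        probe = Point(cx, cy).buffer(radius_m * 1.001, quad_segs=8)
        angles: List[float] = []
        for idx in sw_tree.query(probe):
            angles.extend(_circle_crossings((cx, cy), radius_m, list(sw_geoms[idx].coords)))
        if not angles:
            continue
        angles = sorted(set(angles))
        # drop near-duplicate angles from shared polyline vertices
        dedup: List[float] = []
        for a in angles:
            if not dedup or (a - dedup[-1]) > 1e-9:
                dedup.append(a)
        if len(dedup) > 1 and (dedup[0] + 2 * math.pi - dedup[-1]) <= 1e-9:
            dedup.pop(0)
        arcs = (
            [(dedup[i], dedup[(i + 1) % len(dedup)]) for i in range(len(dedup))]
            if len(dedup) > 1
            else []
        )
        for k, (a0, a1) in enumerate(arcs):
            coords = _arc_coords((cx, cy), radius_m, a0, a1)
            arc_line = LineString(coords)
            if road_tree is None:
                continue
            hit = any(
                arc_line.intersects(road_geoms[idx])
                for idx in road_tree.query(arc_line)
            )
            if hit:
                out.append(GeoSegment(id=f"cw_{pt_id}_{k}", mode="crosswalk",
                                      coords=coords))
    return out


# ---------------------------------------------------------------------------
# walking network
# ---------------------------------------------------------------------------

def _split_at_points(segments: Sequence[GeoSegment],
                     points: Sequence[Tuple[float, float]],
                     tol_m: float = 1e-6) -> List[GeoSegment]:
    """Split segments wherever one of ``points`` lies on them (within
    ``tol_m``), so those points become graph nodes."""
    if not segments or not points:
        return list(segments)
    pts = [Point(p) for p in points]
    tree = STRtree(pts)
    out: List[GeoSegment] = []
    for seg in segments:
        line = LineString(seg.coords)
        cut_params: List[float] = []
        for idx in tree.query(line.buffer(tol_m, quad_segs=2)):
            p = pts[idx]
            if line.distance(p) <= tol_m:
                d = line.project(p)
                if tol_m < d < line.length - tol_m:
                    cut_params.append(d)
        if not cut_params:
            out.append(seg)
            continue
        cut_params = sorted(set(cut_params))
        bounds = [0.0] + cut_params + [line.length]
        for i, (d0, d1) in enumerate(zip(bounds[:-1], bounds[1:])):
            piece = substring(line, d0, d1)
            out.append(GeoSegment(id=f"{seg.id}~{i}", mode=seg.mode,
                                  coords=list(piece.coords),
                                  class_label=seg.class_label,
                                  speed_kmh=seg.speed_kmh))
    return out


def build_walk_network(sidewalks: Sequence[GeoSegment],
                       trails: Sequence[GeoSegment] = (),
                       pathways: Sequence[GeoSegment] = (),
                       crosswalks: Sequence[GeoSegment] = (),
                       speeds: Optional[SpeedMap] = None,
                       snap_tol_m: float = 0.5) -> TravelNetwork:
    """Pedestrian network: sidewalks + trails + pathways + crosswalks at a
    constant walking speed.

    Crosswalk endpoints generally fall mid-segment on a sidewalk side, so
    sidewalk-type segments are split at those points before graph
    construction; otherwise crosswalks would dangle under endpoint-only
    connectivity.
    """
    speeds = speeds or SpeedMap()
    walkable = list(sidewalks) + list(trails) + list(pathways)
    endpoints = [s.start for s in crosswalks] + [s.end for s in crosswalks]
    walkable = _split_at_points(walkable, endpoints)
    merged = walkable + list(crosswalks)
    resolved = [
        GeoSegment(id=s.id, mode=s.mode, coords=s.coords, class_label=s.class_label,
                   speed_kmh=speeds.walking_speed_kmh)
        for s in merged
    ]
    return build_graph(resolved, snap_tol_m)


# ---------------------------------------------------------------------------
# multimodal network
# ---------------------------------------------------------------------------

def build_multimodal_network(walk: TravelNetwork, transit: TransitLayer,
                             speeds: Optional[SpeedMap] = None,
                             boarding_penalty_min: float = 0.0,
                             link_max_dist_m: float = 100.0) -> TravelNetwork:
    """Walking network plus transit overlays.

    Each route polyline is split at its stops into ride edges timed at the
    route's speed; every stop becomes a node joined to the nearest walking
    node by a ``link`` edge (walking speed over the straight-line gap,
    plus an optional boarding penalty).  Transit is therefore enterable
    only at stops.  The walking network is contained unchanged.
    """
    speeds = speeds or SpeedMap()
    net = walk.copy()
    for route in transit.routes:
        stops = transit.stops_for(route.id)
        if not stops:
            continue
        line = LineString(route.coords)
        speed = speeds.resolve_transit(route)
        placed = []
        for stop in stops:
            p = Point(stop.location)
            if line.distance(p) > 1.0:
                raise DataError(
                    f"stop {stop.id!r} lies {line.distance(p):.1f} m from "
                    f"route {route.id!r} (max 1 m)"
                )
            placed.append((line.project(p), stop))
        placed.sort(key=lambda it: (it[0], it[1].id))
        # ride edges between consecutive stops along the route
        node_ids = []
        for d, stop in placed:
            nid = f"transit:{stop.id}"
            net.add_node(nid, (stop.location[0], stop.location[1]))
            node_ids.append((d, nid, stop))
        for (d0, u, _), (d1, v, _) in zip(node_ids[:-1], node_ids[1:]):
            seg_len = d1 - d0
            if seg_len <= 0:
                continue
            net.add_edge(u, v, distance_to_time(seg_len, speed), route.mode)
        # link edges stop <-> walking network
        for _, nid, stop in node_ids:
            wn = snap_point(walk, stop.location, link_max_dist_m)
            if wn is None:
                raise DataError(
                    f"stop {stop.id!r} has no walking node within "
                    f"{link_max_dist_m} m"
                )
            wx, wy = walk.position(wn)
            gap = math.hypot(wx - stop.location[0], wy - stop.location[1])
            t = distance_to_time(gap, speeds.walking_speed_kmh) + boarding_penalty_min
            net.add_edge(nid, wn, t, "link")
    return net
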