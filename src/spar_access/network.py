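"""Travel-time network core.

A travel network is an undirected graph whose nodes are planar points
(metres) and whose edges carry a positive travel time in minutes.  All
three mode networks (driving, walking, multimodal) share this
representation; mode-specific construction lives in
:mod:`spar_access.modes`.

Edges come from polyline segments: one edge per segment, joining its two
endpoints (endpoint connectivity only — segments never interact along
their interiors unless they have been split beforehand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import networkx as nx

__all__ = [
    "GeoSegment",
    "TravelNetwork",
    "ConfigurationError",
    "NetworkError",
    "distance_to_time",
    "build_graph",
    "snap_point",
    "one_to_many_times",
    "polyline_length",
]

#: segment modes understood by the builders
SEGMENT_MODES = {"road", "sidewalk", "trail", "pathway", "crosswalk", "bus", "train", "link"}


class ConfigurationError(ValueError):
    """Raised when a segment or parameter cannot be resolved from config."""


class NetworkError(ValueError):
    """Raised for structurally invalid network operations."""


def polyline_length(coords: Sequence[Tuple[float, float]]) -> float:
    """Arc length of a planar polyline in metres."""
    return sum(
        math.hypot(x1 - x0, y1 - y0)
        for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:])
    )


@dataclass
class GeoSegment:
    """A polyline feature in a projected (metre) coordinate system.

    ``length_m`` defaults to the polyline arc length; ``speed_kmh`` may be
    left unset and resolved later from ``class_label`` via a speed map.
    """

    id: str
    mode: str
    coords: Sequence[Tuple[float, float]]
    class_label: Optional[str] = None
    speed_kmh: Optional[float] = None
    length_m: Optional[float] = None
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in SEGMENT_MODES:
            raise ConfigurationError(f"segment {self.id!r}: unknown mode {self.mode!r}")
        if len(self.coords) < 2:
            raise ValueError(f"segment {self.id!r}: polyline needs >= 2 points")
        arc = polyline_length(self.coords)
        if self.length_m is None:
            self.length_m = arc
        elif arc > 0 and abs(self.length_m - arc) > 1e-6 * max(arc, 1.0):
            raise ValueError(
                f"segment {self.id!r}: declared length {self.length_m} differs "
                f"from polyline arc length {arc}"
            )
        if self.length_m <= 0:
            raise ValueError(f"segment {self.id!r}: length must be positive")
        if self.speed_kmh is not None and self.speed_kmh <= 0:
            raise ConfigurationError(f"segment {self.id!r}: speed must be positive")

    @property
    def start(self) -> Tuple[float, float]:
        return tuple(self.coords[0])

    @property
    def end(self) -> Tuple[float, float]:
        return tuple(self.coords[-1])


def distance_to_time(length_m: float, speed_kmh: float) -> float:
    """Convert a distance in metres to a travel time in minutes.

    ``time = length_m / (speed_kmh * 1000 / 60)``.
    """
    if speed_kmh <= 0:
        raise ConfigurationError(f"speed must be positive, got {speed_kmh}")
    if length_m < 0:
        raise ValueError(f"length must be non-negative, got {length_m}")
    return length_m / (speed_kmh * 1000.0 / 60.0)


class TravelNetwork:
    """Undirected graph with node coordinates and minute edge weights.

    Thin wrapper around :class:`networkx.Graph`; node attribute ``pos``
    holds (x, y) in metres, edge attributes ``time_min`` and ``mode``.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction ---------------------------------------------------
    def add_node(self, node_id: str, xy: Tuple[float, float]) -> None:
        self.graph.add_node(node_id, pos=(float(xy[0]), float(xy[1])))

    def add_edge(self, u: str, v: str, time_min: float, mode: str,
                 segment_id: Optional[str] = None) -> None:
        if u == v:
            # degenerate (zero-extent) segment: carries no travel, drop
            return
        if time_min < 0:
            raise NetworkError(f"edge {u}-{v}: negative time {time_min}")
        if time_min == 0 and mode != "link":
            raise NetworkError(f"edge {u}-{v}: zero travel time for mode {mode!r}")
        prev = self.graph.get_edge_data(u, v)
        if prev is None or time_min < prev["time_min"]:
            self.graph.add_edge(u, v, time_min=float(time_min), mode=mode,
                                segment_id=segment_id)

    # -- accessors ------------------------------------------------------
    @property
    def nodes(self) -> Mapping[str, Tuple[float, float]]:
        return {n: d["pos"] for n, d in self.graph.nodes(data=True)}

    def position(self, node_id: str) -> Tuple[float, float]:
        return self.graph.nodes[node_id]["pos"]

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def total_km(self) -> float:
        """Total network length in km, inferred from edge times x speeds is
        not stored; this sums Euclidean node-to-node extents and is for
        reporting only."""
        total = 0.0
        for u, v in self.graph.edges():
            (x0, y0), (x1, y1) = self.position(u), self.position(v)
            total += math.hypot(x1 - x0, y1 - y0)
        return total / 1000.0

    def copy(self) -> "TravelNetwork":
        out = TravelNetwork()
        out.graph = self.graph.copy()
        return out

    # -- serialization --------------------------------------------------
    def to_csv(self, node_path: str, edge_path: str) -> None:
        import csv

        with open(node_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node_id", "x", "y"])
            for n in sorted(self.graph.nodes):
                x, y = self.position(n)
                w.writerow([n, repr(x), repr(y)])
        with open(edge_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["u", "v", "time_min", "mode"])
            for u, v, d in sorted(self.graph.edges(data=True)):
                w.writerow([u, v, repr(d["time_min"]), d["mode"]])


def build_graph(segments: Iterable[GeoSegment], snap_tol_m: float = 0.5) -> TravelNetwork:
    """Build a travel network from polyline segments.

    One node per distinct segment endpoint (endpoints closer than
    ``snap_tol_m`` are merged), one edge per segment timed at its resolved
    speed.  Node ids are zero-padded sequence numbers in order of first
    appearance, so they are deterministic for a given segment order.
    """
    if snap_tol_m < 0:
        raise ConfigurationError("snap_tol_m must be >= 0")
    net = TravelNetwork()
    cell = max(snap_tol_m, 1e-9)
    grid: dict = {}  # (ix, iy) -> list of (node_id, xy)

    def node_for(xy: Tuple[float, float]) -> str:
        ix, iy = int(math.floor(xy[0] / cell)), int(math.floor(xy[1] / cell))
        best = None
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for nid, pt in grid.get((ix + dx, iy + dy), ()):
                    d = math.hypot(pt[0] - xy[0], pt[1] - xy[1])
                    if d <= snap_tol_m and (best is None or d < best[0]):
                        best = (d, nid)
        if best is not None:
            return best[1]
        nid = f"n{len(net.graph):06d}"
        net.add_node(nid, xy)
        grid.setdefault((ix, iy), []).append((nid, (float(xy[0]), float(xy[1]))))
        return nid

    for seg in segments:
        if seg.speed_kmh is None:
            raise ConfigurationError(
                f"segment {seg.id!r}: unresolved speed for class {seg.class_label!r}"
            )
        u = node_for(seg.start)
        v = node_for(seg.end)
        t = distance_to_time(seg.length_m, seg.speed_kmh)
        net.add_edge(u, v, t, seg.mode, segment_id=seg.id)
    return net


def snap_point(network: TravelNetwork, point: Tuple[float, float],
               max_dist_m: float) -> Optional[str]:
    """Nearest network node within ``max_dist_m`` (Euclidean).

    Ties are broken by smallest node id; returns ``None`` when no node is
    within range.
    """
    if network.n_nodes() == 0:
        raise NetworkError("cannot snap to an empty network")
    px, py = point
    best: Optional[Tuple[float, str]] = None
    for nid, (x, y) in network.nodes.items():
        d = math.hypot(x - px, y - py)
        if d <= max_dist_m and (best is None or (d, nid) < best):
            best = (d, nid)
    return None if best is None else best[1]


def one_to_many_times(network: TravelNetwork, source: str,
                      cutoff_min: float) -> dict:
    """Shortest travel times (minutes) from ``source`` to all nodes within
    ``cutoff_min`` (inclusive, with 1e-9 slack for float round-off)."""
    if cutoff_min <= 0:
        raise NetworkError("cutoff_min must be positive")
    if source not in network.graph:
        raise NetworkError(f"unknown source node {source!r}")
    raw = nx.single_source_dijkstra_path_length(
        network.graph, source, cutoff=cutoff_min + 1e-9, weight="time_min"
    )
    return {n: t for n, t in raw.items() if t <= cutoff_min + 1e-9}
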