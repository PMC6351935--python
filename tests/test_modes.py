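"""Mode-specific builders: road speeds, crosswalk geometry, walking and
multimodal assembly."""

import math

import pytest

from spar_access.modes import (DataError, SpeedMap, TransitLayer, TransitStop,
                               build_multimodal_network, build_road_network,
                               build_walk_network, generate_crosswalks)
from spar_access.network import (ConfigurationError, GeoSegment,
                                 one_to_many_times, snap_point)


def road(sid, a, b, cls="Collector"):
    return GeoSegment(id=sid, mode="road", coords=[a, b], class_label=cls)


def sidewalk(sid, coords):
    return GeoSegment(id=sid, mode="sidewalk", coords=coords)


class TestRoadNetwork:
    def test_single_major_segment_time(self):
        net = build_road_network([road("r", (0, 0), (1000, 0), "Major")], SpeedMap())
        (_, _, d), = net.graph.edges(data=True)
        assert d["time_min"] == pytest.approx(1000 / (65 * 1000 / 60))

    def test_block_grid_counts(self):
        segs = []
        for r in range(3):
            for c in range(2):
                segs.append(road(f"h{r}{c}", (c * 100, r * 100), ((c + 1) * 100, r * 100)))
        for c in range(3):
            for r in range(2):
                segs.append(road(f"v{c}{r}", (c * 100, r * 100), (c * 100, (r + 1) * 100)))
        net = build_road_network(segs, SpeedMap())
        assert net.n_nodes() == 9
        assert net.n_edges() == 12

    def test_per_class_speeds(self):
        table = {"Collector": 50.0, "Major": 65.0, "Expressway": 80.0, "Alley": 15.0}
        segs = [road(c, (i * 10, 0), (i * 10, 500), c)
                for i, c in enumerate(table)]
        net = build_road_network(segs, SpeedMap())
        times = sorted(d["time_min"] for _, _, d in net.graph.edges(data=True))
        expected = sorted(500 / (v * 1000 / 60) for v in table.values())
        assert times == pytest.approx(expected)

    def test_alias_vocabulary(self):
        net = build_road_network(
            [road("r", (0, 0), (1000, 0), "primary highway")], SpeedMap())
        (_, _, d), = net.graph.edges(data=True)
        assert d["time_min"] == pytest.approx(1000 / (80 * 1000 / 60))

    def test_unknown_class_errors(self):
        with pytest.raises(ConfigurationError, match="Cowpath"):
            build_road_network([road("r", (0, 0), (1, 0), "Cowpath")], SpeedMap())


def four_way_fixture():
    """One 4-way road intersection at the origin with four sidewalk
    corners, one per quadrant (corner point 6 m inside each block)."""
    roads = [road("e", (0, 0), (100, 0)), road("w", (0, 0), (-100, 0)),
             road("n", (0, 0), (0, 100)), road("s", (0, 0), (0, -100))]
    sidewalks = []
    for sx in (1, -1):
        for sy in (1, -1):
            cx, cy = 6 * sx, 6 * sy
            sidewalks.append(sidewalk(f"swx_{sx}_{sy}",
                                      [(cx + 100 * sx, cy), (cx, cy),
                                       (cx, cy + 100 * sy)]))
    return roads, sidewalks


class TestCrosswalks:
    def test_four_way_intersection_yields_four_crossings(self):
        roads, sidewalks = four_way_fixture()
        cws = generate_crosswalks(sidewalks, [("i0", (0.0, 0.0))], roads)
        assert len(cws) == 4
        # each retained arc crosses exactly one road arm
        from shapely.geometry import LineString
        arms = [LineString(r.coords) for r in roads]
        for cw in cws:
            arc = LineString(cw.coords)
            assert sum(arc.intersects(a) for a in arms) == 1

    def test_arcs_lie_on_18m_circle(self):
        roads, sidewalks = four_way_fixture()
        for cw in generate_crosswalks(sidewalks, [("i0", (0.0, 0.0))], roads):
            for x, y in cw.coords:
                assert math.hypot(x, y) == pytest.approx(18.0, abs=1e-6)

    def test_no_sidewalk_in_radius_gives_no_crosswalks(self):
        roads, _ = four_way_fixture()
        far = [sidewalk("far", [(50, 50), (150, 50)])]
        assert generate_crosswalks(far, [("i0", (0.0, 0.0))], roads) == []

    def test_empty_intersections_is_empty_not_error(self):
        roads, sidewalks = four_way_fixture()
        assert generate_crosswalks(sidewalks, [], roads) == []

    def test_arc_without_road_crossing_dropped(self):
        # only the east road arm: arcs over the other three arms vanish
        roads, sidewalks = four_way_fixture()
        cws = generate_crosswalks(sidewalks, [("i0", (0.0, 0.0))], roads[:1])
        assert len(cws) == 1


class TestWalkNetwork:
    def test_crosswalk_bridges_blocks(self):
        roads, sidewalks = four_way_fixture()
        cws = generate_crosswalks(sidewalks, [("i0", (0.0, 0.0))], roads)
        net = build_walk_network(sidewalks, crosswalks=cws)
        assert net.n_components() == 1

    def test_without_crosswalks_components_equal_blocks(self):
        _, sidewalks = four_way_fixture()
        net = build_walk_network(sidewalks)
        assert net.n_components() == 4

    def test_walking_edge_time(self):
        net = build_walk_network([sidewalk("s", [(0, 0), (240, 0)])])
        (_, _, d), = net.graph.edges(data=True)
        assert d["time_min"] == pytest.approx(3.0)

    def test_removing_crosswalks_never_speeds_walking(self):
        roads, sidewalks = four_way_fixture()
        cws = generate_crosswalks(sidewalks, [("i0", (0.0, 0.0))], roads)
        full = build_walk_network(sidewalks, crosswalks=cws)
        bare = build_walk_network(sidewalks)
        src_full = snap_point(full, (106, 6), 50)
        src_bare = snap_point(bare, (106, 6), 50)
        t_full = one_to_many_times(full, src_full, 1e9)
        t_bare = one_to_many_times(bare, src_bare, 1e9)
        pos_full = full.nodes
        pos_bare = bare.nodes
        for nb, tb in t_bare.items():
            matches = [n for n, p in pos_full.items()
                       if p == pos_bare[nb] and n in t_full]
            for nf in matches:
                assert t_full[nf] <= tb + 1e-9


def corridor_fixture():
    """A straight 2000-m bus route with 3 stops over a sidewalk chain."""
    sidewalks = [sidewalk(f"sw{k}", [(k * 250, 5), ((k + 1) * 250, 5)])
                 for k in range(8)]
    walk = build_walk_network(sidewalks)
    route = GeoSegment(id="bus1", mode="bus", coords=[(0, 0), (2000, 0)])
    stops = [TransitStop(f"stop{k}", (x, 0.0), "bus1")
             for k, x in enumerate([0.0, 1000.0, 2000.0])]
    return walk, TransitLayer(routes=[route], stops=stops)


class TestMultimodal:
    def test_split_and_link_counts(self):
        walk, transit = corridor_fixture()
        net = build_multimodal_network(walk, transit)
        modes = [d["mode"] for _, _, d in net.graph.edges(data=True)]
        assert modes.count("bus") == 2
        assert modes.count("link") == 3
        assert net.n_edges() == walk.n_edges() + 5

    def test_bus_corridor_beats_walking(self):
        walk, transit = corridor_fixture()
        net = build_multimodal_network(walk, transit)
        a = snap_point(walk, (0, 5), 10)
        b = snap_point(walk, (2000, 5), 10)
        t_walk = one_to_many_times(walk, a, 1e9)[b]
        t_multi = one_to_many_times(net, a, 1e9)[b]
        assert t_multi < t_walk
        # 2 km at 40 km/h = 3 min plus two 5-m links
        assert t_multi == pytest.approx(3.0 + 2 * (5 / 80), abs=1e-9)

    def test_multimodal_dominates_walking_everywhere(self):
        walk, transit = corridor_fixture()
        net = build_multimodal_network(walk, transit)
        for src in walk.graph.nodes:
            tw = one_to_many_times(walk, src, 1e9)
            tm = one_to_many_times(net, src, 1e9)
            for n, t in tw.items():
                assert tm[n] <= t + 1e-9

    def test_transit_entered_only_at_stops(self):
        walk, transit = corridor_fixture()
        net = build_multimodal_network(walk, transit)
        for u, v, d in net.graph.edges(data=True):
            if d["mode"] in ("bus", "train"):
                assert u.startswith("transit:") and v.startswith("transit:")

    def test_walk_network_contained_unchanged(self):
        walk, transit = corridor_fixture()
        net = build_multimodal_network(walk, transit)
        for u, v, d in walk.graph.edges(data=True):
            assert net.graph[u][v]["time_min"] == d["time_min"]

    def test_off_route_stop_raises(self):
        walk, transit = corridor_fixture()
        bad = TransitLayer(routes=transit.routes,
                           stops=[TransitStop("lost", (500.0, 30.0), "bus1")])
        with pytest.raises(DataError, match="lost"):
            build_multimodal_network(walk, bad)

    def test_coincident_stop_zero_link_allowed(self):
        walk, transit = corridor_fixture()
        stops = [TransitStop("s0", (0.0, 5.0), "bus1"),
                 TransitStop("s1", (2000.0, 5.0), "bus1")]
        routes = [GeoSegment(id="bus1", mode="bus", coords=[(0, 5), (2000, 5)])]
        net = build_multimodal_network(walk, TransitLayer(routes, stops))
        link_times = [d["time_min"] for _, _, d in net.graph.edges(data=True)
                      if d["mode"] == "link"]
        assert link_times == [0.0, 0.0]
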