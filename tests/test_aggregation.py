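import numpy as np
import pytest

from streetscape.aggregation import (
    aggregate_zone,
    assign_images,
    build_zone,
    label_segments,
    network_graph,
    sidewalk_length_per_zone,
    sidewalk_segment_label,
)
from streetscape.geo_io import RoadSegment, StreetNetwork
from streetscape.sampler import SamplePoint
from streetscape.segmentation import CLASS_NAMES, ClassPixelSummary


def _summary(point_id="p", heading=0, **given):
    fracs = {c: given.get(c, 0.0) for c in CLASS_NAMES}
    rest = 1.0 - sum(fracs.values())
    return ClassPixelSummary(
        point_id=point_id, heading_deg=heading, fractions=fracs, void_fraction=rest
    )


class TestBuildZone:
    def test_l1_diamond_vertices(self):
        z = build_zone((0.0, 0.0), 500.0, "l1_diamond")
        verts = set(map(tuple, np.round(np.array(z.polygon.exterior.coords)[:-1], 6)))
        assert verts == {(500.0, 0.0), (0.0, 500.0), (-500.0, 0.0), (0.0, -500.0)}
        for vx, vy in verts:
            assert abs(vx) + abs(vy) == pytest.approx(500.0, abs=1e-6)

    def test_l1_membership_arithmetic(self):
        z = build_zone((0.0, 0.0), 500.0, "l1_diamond")
        assert not z.contains(300.0, 300.0)  # |dx|+|dy| = 600 > 500
        assert z.contains(250.0, 250.0)
        assert z.contains(500.0, 0.0)  # boundary closed

    def test_diamond_membership_matches_l1_predicate(self):
        rng = np.random.default_rng(0)
        anchor = (37.0, -12.0)
        z = build_zone(anchor, 350.0, "l1_diamond")
        pts = rng.uniform(-600, 600, size=(10_000, 2)) + np.array(anchor)
        mine = z.contains_many(pts)
        oracle = (
            np.abs(pts[:, 0] - anchor[0]) + np.abs(pts[:, 1] - anchor[1])
        ) <= 350.0
        assert np.array_equal(mine, oracle)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            build_zone((0, 0), 0.0, "l1_diamond")

    def test_network_metric_requires_network(self):
        with pytest.raises(ValueError, match="network"):
            build_zone((0, 0), 100.0, "network")


def _chain_network(n_segments=8, seg_len=150.0):
    segs = [
        RoadSegment(
            segment_id=f"c{i:02d}",
            polyline=np.array([[i * seg_len, 0.0], [(i + 1) * seg_len, 0.0]]),
        )
        for i in range(n_segments)
    ]
    return StreetNetwork(segments=segs, crs_id="local-meters")


class TestNetworkBuffer:
    def test_straight_street_reaches_exactly_the_radius(self):
        net = _chain_network(n_segments=10, seg_len=150.0)  # x in [0, 1500]
        anchor = (750.0, 0.0)
        z = build_zone(anchor, 500.0, "network", network=net)
        pad = 25.0
        # reachable street is x in [250, 1250]; the polygon is that corridor
        # padded by the buffer constant
        assert z.polygon.covers(_point(251.0, 0.0))
        assert z.polygon.covers(_point(1249.0, 0.0))
        assert not z.polygon.covers(_point(250.0 - pad - 1.0, 0.0))
        assert not z.polygon.covers(_point(1250.0 + pad + 1.0, 0.0))

    def test_anchor_beyond_radius_rejected(self):
        net = _chain_network()
        with pytest.raises(ValueError, match="radius"):
            build_zone((0.0, 5000.0), 100.0, "network", network=net)

    def test_reachable_locations_within_radius_by_dijkstra_oracle(self, small_city):
        net = small_city.network
        anchor = (small_city.config.extent_m / 2, small_city.config.extent_m / 2)
        radius = 400.0
        z = build_zone(anchor, radius, "network", network=net)
        # independent oracle: scipy sparse-graph shortest paths over a
        # vertex-subdivided copy of the network
        import scipy.sparse as sp
        from scipy.sparse.csgraph import dijkstra as sp_dijkstra

        nodes, edges = _subdivide(net, step=25.0)
        xy = np.array(nodes)
        # snap anchor to nearest subdivided vertex
        start = int(np.argmin(np.hypot(xy[:, 0] - anchor[0], xy[:, 1] - anchor[1])))
        n = len(nodes)
        rows = [e[0] for e in edges] + [e[1] for e in edges]
        cols = [e[1] for e in edges] + [e[0] for e in edges]
        vals = [e[2] for e in edges] * 2
        dist = sp_dijkstra(
            sp.csr_matrix((vals, (rows, cols)), shape=(n, n)), indices=start
        )
        import shapely

        pad = 25.0
        inside = shapely.covers(z.polygon.buffer(1e-6), shapely.points(xy))
        for i, is_in in enumerate(inside):
            if dist[i] <= radius - 30.0:  # clear of snap discretization
                assert is_in, f"vertex {i} at path distance {dist[i]:.0f} excluded"
            if dist[i] > radius + pad + 30.0:
                assert not is_in, f"vertex {i} at {dist[i]:.0f} wrongly included"


def _subdivide(net, step):
    nodes, edges = [], []
    index = {}

    def node_id(x, y):
        key = (round(x, 6), round(y, 6))
        if key not in index:
            index[key] = len(nodes)
            nodes.append((x, y))
        return index[key]

    for seg in net.segments:
        n_sub = max(1, int(seg.length_m // step))
        prev = None
        for j in range(n_sub + 1):
            p = seg.line.interpolate(seg.length_m * j / n_sub)
            cur = node_id(p.x, p.y)
            if prev is not None and prev != cur:
                a, b = nodes[prev], nodes[cur]
                edges.append((prev, cur, float(np.hypot(a[0] - b[0], a[1] - b[1]))))
            prev = cur
    return nodes, edges


def _point(x, y):
    from shapely.geometry import Point

    return Point(x, y)


class TestAssignAndAggregate:
    def test_boundary_point_included(self):
        z = build_zone((0.0, 0.0), 100.0, "l1_diamond")
        pts = [SamplePoint("onedge", "s", 0.0, (100.0, 0.0))]
        assert [p.point_id for p in assign_images(pts, z)] == ["onedge"]

    def test_excluded_points_do_not_contribute(self):
        z = build_zone((0.0, 0.0), 100.0, "l1_diamond")
        pts = [SamplePoint("px", "s", 0.0, (0.0, 0.0), excluded=True)]
        assert assign_images(pts, z) == []

    def test_empty_zone_flagged_missing(self):
        z = build_zone((0.0, 0.0), 10.0, "l1_diamond", zone_id="empty")
        assert aggregate_zone([], z) is None

    def test_mean_of_two_images(self):
        z = build_zone((0.0, 0.0), 100.0, "l1_diamond")
        s = [
            _summary("p1", 0, vegetation=0.2),
            _summary("p1", 90, vegetation=0.4),
        ]
        vec = aggregate_zone(s, z)
        assert vec.features["vegetation"] == pytest.approx(0.3)
        assert vec.n_images == 2 and vec.n_points == 1

    def test_single_image_is_identity(self):
        z = build_zone((0.0, 0.0), 100.0, "l1_diamond")
        s = _summary("p1", 0, vegetation=0.25, road=0.3)
        vec = aggregate_zone([s], z)
        for c in CLASS_NAMES:
            assert vec.features[c] == pytest.approx(s.fractions[c], abs=1e-15)

    def test_matches_independent_mean_oracle(self):
        rng = np.random.default_rng(9)
        z = build_zone((0.0, 0.0), 100.0, "l1_diamond")
        summaries = []
        for i in range(12):
            raw = rng.dirichlet(np.ones(len(CLASS_NAMES) + 1))
            fr = {c: float(raw[j]) for j, c in enumerate(CLASS_NAMES)}
            summaries.append(
                ClassPixelSummary(f"p{i}", 0, fractions=fr, void_fraction=float(raw[-1]))
            )
        vec = aggregate_zone(summaries, z)
        for c in CLASS_NAMES:
            oracle = np.mean([s.fractions[c] for s in summaries])
            assert vec.features[c] == pytest.approx(oracle, abs=1e-12)

    def test_duplicate_images_do_not_shift_the_mean(self):
        z = build_zone((0.0, 0.0), 100.0, "l1_diamond")
        a = _summary("p1", 0, vegetation=0.2)
        b = _summary("p2", 0, vegetation=0.4)
        v1 = aggregate_zone([a, b], z)
        v2 = aggregate_zone([a, a, b, a], z)
        assert v1.features == v2.features
        assert v2.n_images == 2


class TestSidewalk:
    @pytest.mark.parametrize(
        "fractions,tau,expected",
        [
            ([0.0], 0.005, False),
            ([0.001, 0.03], 0.01, True),  # any image over threshold suffices
            ([0.0001], 0.0, True),  # tau=0: any sidewalk pixel at all
            ([0.0], 0.0, False),
            ([0.004, 0.004], 0.005, False),
        ],
    )
    def test_detection_rule(self, fractions, tau, expected):
        summaries = [
            _summary(f"p{i}", 0, sidewalk=f) for i, f in enumerate(fractions)
        ]
        assert sidewalk_segment_label("s", summaries, tau=tau) is expected

    def test_no_imagery_gives_missing_label(self):
        assert sidewalk_segment_label("s", []) is None

    def test_length_clipping(self):
        seg = RoadSegment("s1", np.array([[-100.0, 0.0], [100.0, 0.0]]))
        net = StreetNetwork(segments=[seg], crs_id="local-meters")
        inside = build_zone((0.0, 0.0), 400.0, "l1_diamond")
        assert sidewalk_length_per_zone(net, {"s1": True}, inside) == pytest.approx(
            200.0
        )
        half = build_zone((100.0, 0.0), 100.0, "l1_diamond")
        assert sidewalk_length_per_zone(net, {"s1": True}, half) == pytest.approx(
            100.0
        )
        assert sidewalk_length_per_zone(net, {"s1": False}, inside) == 0.0

    def test_length_monotone_in_radius(self, small_city):
        net = small_city.network
        labels = {s.segment_id: True for s in net.segments}
        anchor = (small_city.config.extent_m / 2,) * 2
        lengths = [
            sidewalk_length_per_zone(
                net, labels, build_zone(anchor, r, "l1_diamond")
            )
            for r in (100, 200, 400, 800)
        ]
        assert lengths == sorted(lengths)
        assert lengths[-1] > 0

    def test_label_segments_groups_by_segment(self):
        pts = [
            SamplePoint("p1", "sa", 0.0, (0, 0)),
            SamplePoint("p2", "sb", 0.0, (10, 0)),
        ]
        summaries = [
            _summary("p1", 0, sidewalk=0.05),
            _summary("p2", 0, sidewalk=0.0),
        ]
        labels = label_segments(pts, summaries)
        assert labels == {"sa": True, "sb": False}


def test_network_graph_edge_count(small_city):
    g = network_graph(small_city.network)
    assert g.number_of_edges() == len(small_city.network.segments)
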