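"""Zones and zone-level feature aggregation.

A zone is the analysis neighbourhood around an anchor point: a Manhattan
(L1 / taxicab) diamond around a postal-code centroid — the default reading of
a "Manhattan-style buffer" — a Euclidean disc (the default for intersection
buffer sweeps), or a street-network service area (all network locations
within a path distance, buffered into a polygon). Image-level class
fractions of the sample points falling in a zone are averaged, unweighted
over images, into one feature vector per zone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring, unary_union

from .geo_io import StreetNetwork
from .sampler import SamplePoint
from .segmentation import (
    CLASS_NAMES,
    ClassPixelSummary,
    collapse_classes,
)

logger = logging.getLogger(__name__)

#: Width of the corridor drawn around reachable network locations when a
#: network-distance buffer is turned into a polygon.
NETWORK_BUFFER_PAD_M = 25.0

ZONE_METRICS = ("l1_diamond", "euclidean_disc", "network")


@dataclass
class Zone:
    zone_id: str
    kind: str  # postal_code | intersection
    anchor: tuple[float, float]
    radius_m: float
    metric: str
    polygon: Polygon

    def contains(self, x: float, y: float) -> bool:
        """Closed-region membership (boundary points belong to the zone).

        For the analytic metrics the exact distance predicate is used, so
        membership never depends on polygon discretization.
        """
        dx, dy = x - self.anchor[0], y - self.anchor[1]
        if self.metric == "l1_diamond":
            return abs(dx) + abs(dy) <= self.radius_m
        if self.metric == "euclidean_disc":
            return math.hypot(dx, dy) <= self.radius_m
        return self.polygon.covers(Point(x, y))

    def contains_many(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized closed-region membership for an (n, 2) coordinate array."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        dx = xy[:, 0] - self.anchor[0]
        dy = xy[:, 1] - self.anchor[1]
        if self.metric == "l1_diamond":
            return np.abs(dx) + np.abs(dy) <= self.radius_m
        if self.metric == "euclidean_disc":
            return np.hypot(dx, dy) <= self.radius_m
        import shapely

        return shapely.covers(self.polygon, shapely.points(xy))


@dataclass
class ZoneFeatureVector:
    zone_id: str
    features: dict[str, float]  # raw classes + cyclist + vehicle
    n_images: int
    n_points: int


def build_zone(
    anchor: tuple[float, float],
    radius_m: float,
    metric: str = "l1_diamond",
    network: Optional[StreetNetwork] = None,
    zone_id: str = "",
    kind: str = "postal_code",
) -> Zone:
    """Construct a buffer zone around an anchor point."""
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if metric not in ZONE_METRICS:
        raise ValueError(f"unknown zone metric {metric!r}")
    x, y = anchor
    if metric == "l1_diamond":
        poly = Polygon(
            [(x + radius_m, y), (x, y + radius_m), (x - radius_m, y), (x, y - radius_m)]
        )
    elif metric == "euclidean_disc":
        poly = Point(x, y).buffer(radius_m, quad_segs=64)
    else:
        if network is None:
            raise ValueError("network metric requires a StreetNetwork")
        poly = _network_service_area(network, anchor, radius_m)
    return Zone(
        zone_id=zone_id or f"zone_{x:.0f}_{y:.0f}",
        kind=kind,
        anchor=(float(x), float(y)),
        radius_m=float(radius_m),
        metric=metric,
        polygon=poly,
    )


def _node_key(xy: Sequence[float]) -> tuple[float, float]:
    return (round(float(xy[0]), 6), round(float(xy[1]), 6))


def network_graph(network: StreetNetwork) -> nx.MultiGraph:
    """Undirected multigraph: nodes are segment endpoints, one edge/segment."""
    g = nx.MultiGraph()
    for seg in network.segments:
        u = _node_key(seg.polyline[0])
        v = _node_key(seg.polyline[-1])
        g.add_edge(u, v, key=seg.segment_id, weight=seg.length_m, segment=seg)
    return g


def _network_service_area(
    network: StreetNetwork, anchor: tuple[float, float], radius_m: float
) -> Polygon:
    """Locations within ``radius_m`` path distance of the network point
    nearest the anchor, buffered into a corridor polygon."""
    pt = Point(anchor)
    best = min(network.segments, key=lambda s: s.line.distance(pt))
    snap_gap = best.line.distance(pt)
    if snap_gap > radius_m:
        raise ValueError(
            f"anchor is {snap_gap:.1f} m from the network, beyond the "
            f"{radius_m:.1f} m radius"
        )
    t0 = best.line.project(pt)

    g = network_graph(network)
    u = _node_key(best.polyline[0])
    v = _node_key(best.polyline[-1])
    # Split the snapped segment at the anchor: any route through it can pass
    # through the anchor node at identical cost.
    g.remove_edge(u, v, key=best.segment_id)
    anchor_node = ("__anchor__",)
    g.add_edge(anchor_node, u, key="__a0__", weight=t0,
               segment=None, geom=substring(best.line, t0, 0))
    g.add_edge(anchor_node, v, key="__a1__", weight=best.length_m - t0,
               segment=None, geom=substring(best.line, t0, best.length_m))

    dist = nx.single_source_dijkstra_path_length(g, anchor_node, weight="weight")

    pieces: list[LineString] = []
    for a, b, key, data in g.edges(keys=True, data=True):
        line = data.get("geom")
        if line is None:
            line = data["segment"].line
            if _node_key(line.coords[0]) != a:
                line = line.reverse()
        elif a != anchor_node:
            # geom is stored starting at the anchor node; relabel so the
            # substring parameter origin coincides with node `a`
            a, b = b, a
        length = data["weight"]
        da = dist.get(a, math.inf)
        db = dist.get(b, math.inf)
        # reachable parameter set along the edge from both ends
        lo_end = min(length, radius_m - da) if da <= radius_m else -1.0
        hi_start = length - (radius_m - db) if db <= radius_m else length + 1.0
        if lo_end >= hi_start:  # whole edge reachable
            pieces.append(line)
            continue
        if lo_end > 0:
            pieces.append(substring(line, 0, lo_end))
        if hi_start < length:
            pieces.append(substring(line, hi_start, length))

    if not pieces:
        return Point(anchor).buffer(NETWORK_BUFFER_PAD_M, quad_segs=32)
    reach = unary_union(pieces)
    return reach.buffer(NETWORK_BUFFER_PAD_M, quad_segs=32)


def assign_images(
    points: Sequence[SamplePoint],
    zone: Zone,
    summaries: Optional[Sequence[ClassPixelSummary]] = None,
) -> list:
    """Images of non-excluded points inside (or on the boundary of) a zone.

    Without summaries, returns the member points; with summaries, returns the
    summaries of member points (only fetched images have summaries, so a
    partially-imaged point contributes just its available images).
    """
    candidates = [p for p in points if not p.excluded]
    if not candidates:
        member_ids: set[str] = set()
    else:
        inside = zone.contains_many(np.array([p.coord for p in candidates]))
        member_ids = {p.point_id for p, ok in zip(candidates, inside) if ok}
    if summaries is None:
        return [p for p in points if p.point_id in member_ids]
    return [s for s in summaries if s.point_id in member_ids]


def aggregate_zone(
    summaries: Sequence[ClassPixelSummary], zone: Zone
) -> Optional[ZoneFeatureVector]:
    """Unweighted per-class mean over a zone's contributing images.

    Duplicate (point_id, heading) entries are collapsed to one before
    averaging, so re-presenting an image never shifts the mean. A zone with
    no imagery is flagged missing (returns None with a warning) and excluded
    from modeling.
    """
    unique: dict[tuple[str, int], ClassPixelSummary] = {}
    for s in summaries:
        unique.setdefault((s.point_id, s.heading_deg), s)
    if not unique:
        logger.warning("zone %s has no contributing images", zone.zone_id)
        return None
    imgs = list(unique.values())
    feats: dict[str, float] = {}
    for c in CLASS_NAMES:
        feats[c] = float(np.mean([s.fractions[c] for s in imgs]))
    collapsed = [collapse_classes(s) for s in imgs]
    feats["cyclist"] = float(np.mean([s.cyclist for s in collapsed]))
    feats["vehicle"] = float(np.mean([s.vehicle for s in collapsed]))
    return ZoneFeatureVector(
        zone_id=zone.zone_id,
        features=feats,
        n_images=len(imgs),
        n_points=len({pid for pid, _ in unique}),
    )


#: An image "detects" a sidewalk when at least this fraction of its pixels
#: are labelled sidewalk. Binary presence needs a threshold on the
#: fraction-valued summary; half a percent of image area rejects stray pixels
#: while catching any visible sidewalk.
DEFAULT_SIDEWALK_TAU = 0.005


def sidewalk_segment_label(
    segment_id: str,
    summaries: Sequence[ClassPixelSummary],
    tau: float = DEFAULT_SIDEWALK_TAU,
) -> Optional[bool]:
    """True if any of the segment's images detects a sidewalk.

    ``summaries`` are the images of the segment's sample points; a segment
    with no imagery gets a missing label (None).
    """
    if not summaries:
        return None
    # tau = 0 degenerates to "any sidewalk pixel at all"
    return any(
        s.fractions["sidewalk"] > 0 and s.fractions["sidewalk"] >= tau
        for s in summaries
    )


def label_segments(
    points: Sequence[SamplePoint],
    summaries: Sequence[ClassPixelSummary],
    tau: float = DEFAULT_SIDEWALK_TAU,
) -> dict[str, Optional[bool]]:
    """Per-segment sidewalk labels from all of each segment's images."""
    seg_of_point = {p.point_id: p.segment_id for p in points if not p.excluded}
    by_segment: dict[str, list[ClassPixelSummary]] = {}
    for s in summaries:
        seg = seg_of_point.get(s.point_id)
        if seg is not None:
            by_segment.setdefault(seg, []).append(s)
    return {
        seg: sidewalk_segment_label(seg, ss, tau) for seg, ss in by_segment.items()
    }


def sidewalk_length_per_zone(
    network: StreetNetwork,
    labels: Mapping[str, Optional[bool]],
    zone: Zone,
) -> float:
    """Meters of sidewalk-bearing road inside a zone.

    Positively-labelled segments are clipped to the zone polygon; the summed
    clipped length is the zone's sidewalk-length measure.
    """
    total = 0.0
    for seg in network.segments:
        if not labels.get(seg.segment_id):
            continue
        clipped = seg.line.intersection(zone.polygon)
        total += clipped.length
    return float(total)
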