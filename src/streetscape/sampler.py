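"""Image-sampling points along a street network.

Points are placed every ``spacing_m`` (150 m by default) along every segment,
with centered placement: a segment of length L gets n = max(1, floor(L /
spacing)) points at offsets (i - 0.5) * L / n. Street-level imagery resolves
objects out to roughly 75-100 m, so a 150 m interval gives near-complete
visual coverage with little duplication; segments shorter than the interval
get a single midpoint query, which the centered rule reproduces as the n = 1
case. Each point yields four image requests facing the cardinal directions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from .geo_io import StreetNetwork, write_feature_collection
from .projection import LocalEquirectangular, is_local_crs

CARDINAL_HEADINGS = (0, 90, 180, 270)


@dataclass
class SamplePoint:
    point_id: str
    segment_id: str
    offset_m: float
    coord: tuple[float, float]
    excluded: bool = False


@dataclass
class ImageRequest:
    point_id: str
    heading_deg: int
    lat: float
    lon: float
    status: str = "pending"  # pending | fetched | missing


def sample_points(
    network: StreetNetwork, spacing_m: float = 150.0
) -> list[SamplePoint]:
    """Place sampling points with half-interval margins on every segment.

    Deterministic ordering by (segment_id, offset).
    """
    if spacing_m <= 0:
        raise ValueError("spacing_m must be positive")
    if not network.segments:
        warnings.warn("empty network: no sample points", stacklevel=2)
        return []
    points: list[SamplePoint] = []
    for seg in sorted(network.segments, key=lambda s: s.segment_id):
        n = max(1, math.floor(seg.length_m / spacing_m))
        line = seg.line
        for i in range(1, n + 1):
            off = (i - 0.5) * seg.length_m / n
            p = line.interpolate(off)
            points.append(
                SamplePoint(
                    point_id=f"{seg.segment_id}:{i:03d}",
                    segment_id=seg.segment_id,
                    offset_m=off,
                    coord=(p.x, p.y),
                )
            )
    return points


def make_requests(
    points: Sequence[SamplePoint], crs_id: str
) -> list[ImageRequest]:
    """Four cardinal-heading requests per non-excluded point.

    Latitude/longitude come from the inverse of the local projection named by
    ``crs_id``; a network in an unknown projected CRS cannot be inverted here.
    """
    if not is_local_crs(crs_id):
        raise ValueError(
            f"cannot invert CRS {crs_id!r} to latitude/longitude; image "
            "requests need a local:equirect CRS"
        )
    proj = LocalEquirectangular.from_crs_id(crs_id)
    requests: list[ImageRequest] = []
    for pt in points:
        if pt.excluded:
            continue
        lon, lat = proj.inverse(pt.coord[0], pt.coord[1])
        for h in CARDINAL_HEADINGS:
            requests.append(
                ImageRequest(
                    point_id=pt.point_id,
                    heading_deg=h,
                    lat=float(lat),
                    lon=float(lon),
                )
            )
    return requests


def mark_missing(
    points: Sequence[SamplePoint], fetch_results: Iterable[ImageRequest]
) -> list[SamplePoint]:
    """Exclude points with no available imagery.

    A point whose four requests all came back missing is excluded from the
    analysis. Points with partial imagery (1-3 images) stay included; only
    their fetched images contribute downstream.
    """
    fetched_by_point: dict[str, int] = {}
    for req in fetch_results:
        if req.status == "fetched":
            fetched_by_point[req.point_id] = fetched_by_point.get(req.point_id, 0) + 1
    out = []
    for pt in points:
        out.append(
            SamplePoint(
                point_id=pt.point_id,
                segment_id=pt.segment_id,
                offset_m=pt.offset_m,
                coord=pt.coord,
                excluded=fetched_by_point.get(pt.point_id, 0) == 0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Hexagonal-grid thinning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HexGrid:
    """Flat-top hexagonal grid; ``cell_width_m`` is the across-flats width."""

    cell_width_m: float
    x0: float
    y0: float

    @property
    def size(self) -> float:
        # circumradius of a flat-top hexagon with the given across-flats width
        return self.cell_width_m / math.sqrt(3.0)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        s = self.size
        px, py = x - self.x0, y - self.y0
        qf = (2.0 / 3.0) * px / s
        rf = (-1.0 / 3.0 * px + math.sqrt(3.0) / 3.0 * py) / s
        return _cube_round(qf, rf)

    def center_of(self, q: int, r: int) -> tuple[float, float]:
        s = self.size
        return (
            self.x0 + s * 1.5 * q,
            self.y0 + s * math.sqrt(3.0) * (r + q / 2.0),
        )


def _cube_round(qf: float, rf: float) -> tuple[int, int]:
    sf = -qf - rf
    q, r, s = round(qf), round(rf), round(sf)
    dq, dr, ds = abs(q - qf), abs(r - rf), abs(s - sf)
    if dq > dr and dq > ds:
        q = -r - s
    elif dr > ds:
        r = -q - s
    return int(q), int(r)


def hex_downsample(
    points: Sequence[SamplePoint], cell_width_m: float
) -> list[SamplePoint]:
    """Thin points to at most one per hexagonal cell.

    The grid covers the points' bounding box (origin at its lower-left
    corner); within each occupied cell the point nearest the cell centroid is
    kept, ties broken by lexicographically smallest point_id.
    """
    if not points:
        raise ValueError("hex_downsample needs a non-empty point set")
    if cell_width_m <= 0:
        raise ValueError("cell_width_m must be positive")
    xs = np.array([p.coord[0] for p in points])
    ys = np.array([p.coord[1] for p in points])
    grid = HexGrid(cell_width_m, float(xs.min()), float(ys.min()))

    best: dict[tuple[int, int], tuple[float, str, SamplePoint]] = {}
    for pt in points:
        cell = grid.cell_of(*pt.coord)
        cx, cy = grid.center_of(*cell)
        d = math.hypot(pt.coord[0] - cx, pt.coord[1] - cy)
        key = (d, pt.point_id)
        if cell not in best or key < (best[cell][0], best[cell][1]):
            best[cell] = (d, pt.point_id, pt)
    kept = [v[2] for v in best.values()]
    kept.sort(key=lambda p: p.point_id)
    return kept


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_points(points: Sequence[SamplePoint], path, crs_id: str) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(p.coord)},
            "properties": {
                "point_id": p.point_id,
                "segment_id": p.segment_id,
                "offset_m": p.offset_m,
                "excluded": p.excluded,
            },
        }
        for p in points
    ]
    write_feature_collection(feats, path, crs_id)


def read_points(path) -> list[SamplePoint]:
    from .geo_io import read_feature_collection

    feats, _ = read_feature_collection(path)
    out = []
    for f in feats:
        props = f["properties"]
        out.append(
            SamplePoint(
                point_id=props["point_id"],
                segment_id=props["segment_id"],
                offset_m=float(props["offset_m"]),
                coord=tuple(f["geometry"]["coordinates"]),
                excluded=bool(props.get("excluded", False)),
            )
        )
    out.sort(key=lambda p: p.point_id)
    return out
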