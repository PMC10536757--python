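"""Reading and writing of street networks, zones, ground truth, and masks.

All internal geometry is planar in meters. GeoJSON (RFC 7946) is the exchange
format for networks, points and zone polygons; ground truth travels as CSV
with columns ``id,target_name,value[,year]``; segmentation masks are
single-channel PNGs with pixel value = class index 0-18 and 255 for void.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import LineString, mapping, shape

from .projection import LocalEquirectangular, is_local_crs, looks_geographic

logger = logging.getLogger(__name__)

#: Measurement targets validated against municipal ground truth.
TARGET_NAMES = frozenset(
    {
        "trees",
        "sidewalk_length",
        "pedestrians",
        "bicycles",
        "vehicles",
        "traffic_lights",
        "traffic_signs",
    }
)


class ConfigurationError(ValueError):
    """Raised for unusable coordinate-reference or input configuration."""


@dataclass
class RoadSegment:
    """A street polyline in projected meters.

    ``sidewalk_truth`` carries the municipal per-segment sidewalk label when
    one exists; ``road_class`` is a coarse functional class (residential /
    arterial / rural) used by the sidewalk error analysis.
    """

    segment_id: str
    polyline: np.ndarray  # (n, 2) float, meters
    sidewalk_truth: Optional[bool] = None
    road_class: Optional[str] = None
    length_m: float = field(init=False)

    def __post_init__(self) -> None:
        poly = np.asarray(self.polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
            raise ValueError(
                f"segment {self.segment_id!r}: polyline must be (n>=2, 2)"
            )
        if not np.isfinite(poly).all():
            raise ValueError(f"segment {self.segment_id!r}: non-finite coordinates")
        self.polyline = poly
        self.length_m = float(np.hypot(*np.diff(poly, axis=0).T).sum())

    @property
    def line(self) -> LineString:
        return LineString(self.polyline)


@dataclass
class StreetNetwork:
    segments: list[RoadSegment]
    crs_id: str
    units: str = "m"

    def __post_init__(self) -> None:
        for seg in self.segments:
            if seg.length_m <= 0:
                raise ValueError(f"segment {seg.segment_id!r} has zero length")

    def total_length_m(self) -> float:
        return float(sum(s.length_m for s in self.segments))

    def bounds(self) -> tuple[float, float, float, float]:
        coords = np.vstack([s.polyline for s in self.segments])
        return (
            float(coords[:, 0].min()),
            float(coords[:, 1].min()),
            float(coords[:, 0].max()),
            float(coords[:, 1].max()),
        )


def _segment_parts(geom) -> list[np.ndarray]:
    if geom.geom_type == "LineString":
        return [np.asarray(geom.coords, dtype=float)[:, :2]]
    if geom.geom_type == "MultiLineString":
        out = []
        for part in geom.geoms:
            out.append(np.asarray(part.coords, dtype=float)[:, :2])
        return out
    raise ValueError(f"unsupported geometry type {geom.geom_type!r}")


def load_network(path, target_crs: Optional[str] = None) -> StreetNetwork:
    """Load a street network from GeoJSON, reprojecting degrees to meters.

    MultiLineString features are split into one segment per part (the
    per-segment sidewalk label is the unit of classification, so parts are
    independent segments). Zero-length parts are dropped with a warning.

    Geographic inputs require ``target_crs``: either ``"local"`` (fit a local
    equirectangular projection to the data) or an explicit
    ``local:equirect:lon0=...:lat0=...`` identifier. Projected inputs pass
    through unchanged; their CRS identifier is taken from the file's ``crs``
    member or from ``target_crs``.
    """
    path = Path(path)
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")

    raw: list[tuple[str, np.ndarray, dict]] = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        base_id = str(props.get("segment_id", props.get("id", f"seg{i:05d}")))
        parts = _segment_parts(geom)
        for j, coords in enumerate(parts):
            sid = base_id if len(parts) == 1 else f"{base_id}.{j}"
            raw.append((sid, coords, props))

    if not raw:
        raise ValueError(f"{path}: no LineString features")

    all_coords = np.vstack([c for _, c, _ in raw])
    file_crs = _file_crs_id(gj)
    geographic = looks_geographic(all_coords)

    proj: Optional[LocalEquirectangular] = None
    if geographic:
        if target_crs is None:
            raise ConfigurationError(
                f"{path}: coordinates are geographic degrees; supply "
                "target_crs='local' (or a local:equirect:... identifier) to "
                "project into a metric plane"
            )
        if target_crs == "local":
            proj = LocalEquirectangular.fit(all_coords[:, 0], all_coords[:, 1])
        elif is_local_crs(target_crs):
            proj = LocalEquirectangular.from_crs_id(target_crs)
        else:
            raise ConfigurationError(
                f"unsupported target_crs {target_crs!r}: only local "
                "equirectangular projections are available"
            )
        crs_id = proj.crs_id
    else:
        crs_id = target_crs or file_crs
        if crs_id is None:
            raise ConfigurationError(
                f"{path}: no CRS declared in the file and none supplied; "
                "pass target_crs with the projected CRS identifier"
            )

    segments: list[RoadSegment] = []
    n_dropped = 0
    for sid, coords, props in raw:
        if proj is not None:
            x, y = proj.forward(coords[:, 0], coords[:, 1])
            coords = np.column_stack([x, y])
        length = float(np.hypot(*np.diff(coords, axis=0).T).sum())
        if length <= 0:
            n_dropped += 1
            continue
        truth = props.get("sidewalk_truth")
        segments.append(
            RoadSegment(
                segment_id=sid,
                polyline=coords,
                sidewalk_truth=None if truth is None else bool(truth),
                road_class=props.get("road_class"),
            )
        )
    if n_dropped:
        warnings.warn(
            f"{path}: dropped {n_dropped} zero-length segment(s)", stacklevel=2
        )
    return StreetNetwork(segments=segments, crs_id=crs_id)


def _file_crs_id(gj: dict) -> Optional[str]:
    crs = gj.get("crs")
    if isinstance(crs, dict):
        name = (crs.get("properties") or {}).get("name")
        if name:
            return str(name)
    if isinstance(crs, str):
        return crs
    return None


def save_network(network: StreetNetwork, path) -> None:
    feats = []
    for seg in network.segments:
        props = {"segment_id": seg.segment_id}
        if seg.sidewalk_truth is not None:
            props["sidewalk_truth"] = seg.sidewalk_truth
        if seg.road_class is not None:
            props["road_class"] = seg.road_class
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(seg.line),
                "properties": props,
            }
        )
    gj = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": network.crs_id}},
        "features": feats,
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


# ---------------------------------------------------------------------------
# Ground truth tables
# ---------------------------------------------------------------------------

def validate_ground_truth(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a ground-truth table.

    Required columns: ``id``, ``target_name``, ``value``; ``year`` optional.
    Values are kept in native units (the two cities define e.g. traffic counts
    differently); standardization happens at modeling time.
    """
    required = {"id", "target_name", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ground truth missing columns: {sorted(missing)}")
    df = df.copy()
    df["id"] = df["id"].astype(str)
    df["value"] = df["value"].astype(float)
    bad = set(df["target_name"]) - TARGET_NAMES
    if bad:
        raise ValueError(f"unknown target_name values: {sorted(bad)}")
    if (df["value"] < 0).any():
        raise ValueError("ground-truth values must be >= 0")
    dups = df.duplicated(["id", "target_name"], keep=False)
    if dups.any() and "year" not in df.columns:
        ids = sorted(df.loc[dups, "id"].unique()[:5])
        raise ValueError(
            f"duplicate (id, target_name) rows without a year column: {ids}"
        )
    return df


def load_ground_truth(path) -> pd.DataFrame:
    return validate_ground_truth(pd.read_csv(path, dtype={"id": str}))


def resolve_most_recent(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, per (id, target_name), only the most recent year's row.

    Raises if two rows share the same maximal year for an id, naming the id.
    """
    df = validate_ground_truth(df)
    if "year" not in df.columns:
        return df.reset_index(drop=True)
    keyed = df.groupby(["id", "target_name"], sort=True)
    rows = []
    for (gid, tname), grp in keyed:
        if len(grp) == 1:
            rows.append(grp)
            continue
        if grp["year"].isna().any():
            raise ValueError(
                f"id {gid!r} target {tname!r}: duplicate rows need a year"
            )
        top = grp[grp["year"] == grp["year"].max()]
        if len(top) > 1:
            raise ValueError(
                f"id {gid!r} target {tname!r}: {len(top)} rows share the "
                f"most recent year {int(grp['year'].max())}"
            )
        rows.append(top)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Images and masks
# ---------------------------------------------------------------------------

def load_mask(path) -> np.ndarray:
    """Read a single-channel PNG label mask (values 0-18, 255 = void)."""
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel")
    return arr.astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_image(img: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path)


# ---------------------------------------------------------------------------
# Generic GeoJSON point/polygon helpers (zones, sample points)
# ---------------------------------------------------------------------------

def write_feature_collection(features: Iterable[dict], path, crs_id: str) -> None:
    gj = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs_id}},
        "features": list(features),
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def read_feature_collection(path) -> tuple[list[dict], Optional[str]]:
    with open(path) as fh:
        gj = json.load(fh)
    return list(gj.get("features", [])), _file_crs_id(gj)
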