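"""Per-pixel street-scene labelling: backend contract, summaries, collapsing.

The pixel taxonomy is the 19-class cityscapes trainId palette (road,
sidewalk, building, ..., bicycle) plus a void value (255) for unlabeled
pixels. The segmentation network itself is a pluggable backend: any callable
that maps an RGB image to a label grid of the same shape satisfies the
contract (a deployment would wrap a DeepLab-style model; the test path uses
the deterministic synthetic segmenter).

Class pixel counts are reduced to fractions of image area, which makes the
features invariant to image resolution. Bicycle + rider collapse to
"cyclist" and road + car + truck + motorcycle to "vehicle"; bus is carried
but excluded from modeling (too rare to validate), and terrain / sky are
carried but unused.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

#: cityscapes trainId order, indices 0-18.
CLASS_NAMES: tuple[str, ...] = (
    "road",
    "sidewalk",
    "building",
    "wall",
    "fence",
    "pole",
    "traffic_light",
    "traffic_sign",
    "vegetation",
    "terrain",
    "sky",
    "person",
    "rider",
    "car",
    "truck",
    "bus",
    "train",
    "motorcycle",
    "bicycle",
)
VOID_LABEL = 255
N_CLASSES = len(CLASS_NAMES)

#: Collapsed feature definitions.
CYCLIST_PARTS = ("bicycle", "rider")
VEHICLE_PARTS = ("road", "car", "truck", "motorcycle")

#: Classes carried through summaries but never fed to models.
EXCLUDED_FROM_MODELING = frozenset({"bus"})
UNUSED_CLASSES = frozenset({"terrain", "sky"})

#: Which pixel-fraction features feed which measurement target. The three
#: traffic-density targets share the road/car/truck/person block (driving
#: vehicles occlude road, so visible road is itself a traffic signal);
#: pedestrians and bicycles additionally use their direct class.
FEATURES_BY_TARGET: dict[str, tuple[str, ...]] = {
    "trees": ("vegetation",),
    "sidewalk_length": ("sidewalk",),
    "pedestrians": ("person", "road", "car", "truck"),
    "bicycles": ("cyclist", "road", "car", "truck", "person"),
    "vehicles": ("road", "car", "truck", "person"),
    "traffic_lights": ("pole", "traffic_light", "traffic_sign"),
    "traffic_signs": ("pole", "traffic_light", "traffic_sign"),
}

#: RGB rendering of each trainId (the standard cityscapes colour map), used
#: by the synthetic image/mask round trip.
CLASS_PALETTE: dict[int, tuple[int, int, int]] = {
    0: (128, 64, 128),
    1: (244, 35, 232),
    2: (70, 70, 70),
    3: (102, 102, 156),
    4: (190, 153, 153),
    5: (153, 153, 153),
    6: (250, 170, 30),
    7: (220, 220, 0),
    8: (107, 142, 35),
    9: (152, 251, 152),
    10: (70, 130, 180),
    11: (220, 20, 60),
    12: (255, 0, 0),
    13: (0, 0, 142),
    14: (0, 0, 70),
    15: (0, 60, 100),
    16: (0, 80, 100),
    17: (0, 0, 230),
    18: (119, 11, 32),
    VOID_LABEL: (0, 0, 0),
}


class BackendContractError(RuntimeError):
    """The segmentation backend violated its output contract."""


@dataclass
class SegmentationMask:
    labels: np.ndarray  # (h, w) uint8, values 0-18 or 255

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("mask must be a 2-D label grid")
        valid = (arr < N_CLASSES) | (arr == VOID_LABEL)
        if not valid.all():
            bad = np.unique(arr[~valid])
            raise ValueError(f"invalid label values in mask: {bad.tolist()}")
        self.labels = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]


@dataclass
class ClassPixelSummary:
    """Per-image class pixel fractions; together with void they sum to 1."""

    point_id: str
    heading_deg: int
    fractions: dict[str, float]
    void_fraction: float = 0.0

    def __post_init__(self) -> None:
        missing = set(CLASS_NAMES) - set(self.fractions)
        if missing:
            self.fractions = {c: self.fractions.get(c, 0.0) for c in CLASS_NAMES}
        total = sum(self.fractions.values()) + self.void_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"fractions + void must sum to 1 (got {total!r}) for "
                f"{self.point_id}/{self.heading_deg}"
            )

    def __getitem__(self, cls: str) -> float:
        return self.fractions[cls]


@dataclass
class CollapsedSummary(ClassPixelSummary):
    cyclist: float = 0.0
    vehicle: float = 0.0


def segment_image(
    image: np.ndarray,
    backend: Callable[[np.ndarray], np.ndarray],
) -> SegmentationMask:
    """Run a backend on an RGB image and validate the contract."""
    image = np.asarray(image)
    labels = np.asarray(backend(image))
    if labels.shape != image.shape[:2]:
        raise BackendContractError(
            f"backend returned shape {labels.shape}, expected {image.shape[:2]}"
        )
    try:
        return SegmentationMask(labels)
    except ValueError as exc:
        raise BackendContractError(str(exc)) from exc


def summarize_mask(
    mask: SegmentationMask, point_id: str = "", heading_deg: int = 0
) -> ClassPixelSummary:
    """Reduce a label mask to per-class pixel fractions."""
    area = mask.height * mask.width
    if area == 0:
        raise ValueError("zero-area mask")
    flat = mask.labels.ravel()
    counts = np.bincount(flat[flat != VOID_LABEL], minlength=N_CLASSES)
    void = int((flat == VOID_LABEL).sum())
    fractions = {c: counts[i] / area for i, c in enumerate(CLASS_NAMES)}
    return ClassPixelSummary(
        point_id=point_id,
        heading_deg=heading_deg,
        fractions=fractions,
        void_fraction=void / area,
    )


def collapse_classes(summary: ClassPixelSummary) -> CollapsedSummary:
    """Add the cyclist and vehicle composites to a raw summary."""
    f = summary.fractions
    return CollapsedSummary(
        point_id=summary.point_id,
        heading_deg=summary.heading_deg,
        fractions=dict(f),
        void_fraction=summary.void_fraction,
        cyclist=sum(f[c] for c in CYCLIST_PARTS),
        vehicle=sum(f[c] for c in VEHICLE_PARTS),
    )


def render_palette_image(mask: SegmentationMask) -> np.ndarray:
    """Render a mask as an RGB image with the standard class colours."""
    lut = np.zeros((256, 3), dtype=np.uint8)
    for idx, rgb in CLASS_PALETTE.items():
        lut[idx] = rgb
    return lut[mask.labels]


def palette_backend(image: np.ndarray) -> np.ndarray:
    """Deterministic backend: invert the class colour palette.

    Pixels whose colour is not an exact palette entry map to void. Paired
    with :func:`render_palette_image` this gives a lossless image->mask round
    trip for synthetic imagery.
    """
    image = np.asarray(image)
    out = np.full(image.shape[:2], VOID_LABEL, dtype=np.uint8)
    for idx, rgb in CLASS_PALETTE.items():
        hit = (image == np.array(rgb, dtype=image.dtype)).all(axis=-1)
        out[hit] = idx
    return out


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ["point_id", "heading_deg", *CLASS_NAMES, "void_fraction"]


def summaries_to_frame(summaries: Sequence[ClassPixelSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"point_id": s.point_id, "heading_deg": s.heading_deg}
        row.update({c: s.fractions[c] for c in CLASS_NAMES})
        row["void_fraction"] = s.void_fraction
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def frame_to_summaries(df: pd.DataFrame) -> list[ClassPixelSummary]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            ClassPixelSummary(
                point_id=str(d["point_id"]),
                heading_deg=int(d["heading_deg"]),
                fractions={c: float(d[c]) for c in CLASS_NAMES},
                void_fraction=float(d.get("void_fraction", 0.0)),
            )
        )
    return out
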