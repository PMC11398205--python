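"""Automated annotation of layered renders into COCO bounding boxes.

The instance-index layer is ground truth: every pixel carrying id k belongs
to fish k, so instances are extracted by id without connected-component
analysis (occlusion may split a fish into disjoint pixel groups that still
share one box). Instances are then filtered — too few pixels (tiny slivers
at the frame edge or heavily occluded fish) or too far from the camera
(blurry, low-contrast fish) are excluded — and the survivors become tight
axis-aligned boxes in COCO convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InvalidArgumentError
from .render import LayeredFrame

logger = logging.getLogger(__name__)


@dataclass
class InstanceMask:
    """All pixels of one fish instance plus its median camera distance."""

    instance_id: int
    pixel_coords: np.ndarray  # (n, 2) int array of (row, col)
    pixel_count: int
    representative_depth: float


@dataclass(frozen=True)
class AnnotationFilter:
    """Inclusion rules: at least ``min_pixels`` pixels and at most ``max_depth`` metres.

    Both are mandatory, deliberately: sensible values depend on the camera
    and turbidity preset, so there is no silent default in configs.
    """

    min_pixels: int = 100
    max_depth: float = 3.0

    def __post_init__(self):
        if self.min_pixels < 1:
            raise InvalidArgumentError("min_pixels must be >= 1")
        if self.max_depth <= 0:
            raise InvalidArgumentError("max_depth must be > 0")


@dataclass
class AnnotationRecord:
    """One fish's COCO-style box: (x_min, y_min, width, height) in pixels."""

    instance_id: int
    bbox: tuple[float, float, float, float]
    area_px: int
    center: tuple[float, float]  # (u, v) = (col, row) centroid of the mask
    depth: float
    category: str = "fish"


def extract_instances(index: np.ndarray, depth: np.ndarray) -> list[InstanceMask]:
    """One InstanceMask per distinct id > 0, sorted by id.

    ``representative_depth`` is the median depth over the instance's pixels,
    which resists boundary-pixel outliers.
    """
    index = np.asarray(index)
    depth = np.asarray(depth)
    if index.shape != depth.shape:
        raise InvalidArgumentError(
            f"index shape {index.shape} != depth shape {depth.shape}"
        )
    out = []
    for fish_id in np.unique(index):
        if fish_id <= 0:
            continue
        rows, cols = np.nonzero(index == fish_id)
        coords = np.stack([rows, cols], axis=1)
        out.append(
            InstanceMask(
                instance_id=int(fish_id),
                pixel_coords=coords,
                pixel_count=len(coords),
                representative_depth=float(np.median(depth[rows, cols])),
            )
        )
    return out


def exclusion_reason(mask: InstanceMask, filt: AnnotationFilter) -> str | None:
    """Why `mask` would be excluded, or None. Pixel count is checked before depth."""
    if mask.pixel_count < filt.min_pixels:
        return "pixel_count"
    if mask.representative_depth > filt.max_depth:
        return "depth"
    return None


def filter_instances(instances: list[InstanceMask], filt: AnnotationFilter) -> list[InstanceMask]:
    """Keep instances passing both checks, preserving order; log exclusions."""
    kept = []
    for mask in instances:
        reason = exclusion_reason(mask, filt)
        if reason is None:
            kept.append(mask)
        else:
            logger.debug(
                "excluding instance %d: %s (pixels=%d, depth=%.2f m)",
                mask.instance_id, reason, mask.pixel_count, mask.representative_depth,
            )
    logger.info("kept %d/%d instances", len(kept), len(instances))
    return kept


def to_record(mask: InstanceMask) -> AnnotationRecord:
    """Tight axis-aligned COCO box over the mask; area is the true pixel count."""
    rows = mask.pixel_coords[:, 0]
    cols = mask.pixel_coords[:, 1]
    x_min, y_min = int(cols.min()), int(rows.min())
    width = int(cols.max()) - x_min + 1
    height = int(rows.max()) - y_min + 1
    return AnnotationRecord(
        instance_id=mask.instance_id,
        bbox=(float(x_min), float(y_min), float(width), float(height)),
        area_px=mask.pixel_count,
        center=(float(cols.mean()), float(rows.mean())),
        depth=mask.representative_depth,
    )


def annotate_frame(frame: LayeredFrame, filt: AnnotationFilter) -> list[AnnotationRecord]:
    """Full flow: extract instances, filter, convert to records. Deterministic."""
    return [to_record(m) for m in filter_instances(extract_instances(frame.index, frame.depth), filt)]


# ---------------------------------------------------------------------------
# COCO JSON
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageMeta:
    id: int
    file_name: str
    width: int
    height: int


def write_coco(
    images: list[ImageMeta],
    records: dict[int, list[AnnotationRecord]],
    path,
    description: str = "rastank virtual fish dataset",
) -> None:
    """Write single-category ("fish") COCO detection JSON.

    ``records`` maps image id -> that image's AnnotationRecords. Annotation
    ids are assigned sequentially from 1 in image order.
    """
    ids = [im.id for im in images]
    if len(set(ids)) != len(ids):
        raise InvalidArgumentError("duplicate image ids in COCO export")
    unknown = set(records) - set(ids)
    if unknown:
        raise InvalidArgumentError(f"records reference unknown image ids: {sorted(unknown)}")

    annotations = []
    ann_id = 1
    for im in images:
        for rec in records.get(im.id, []):
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": im.id,
                    "category_id": 1,
                    "bbox": [float(v) for v in rec.bbox],
                    "area": float(rec.area_px),
                    "iscrowd": 0,
                    "center": [float(v) for v in rec.center],
                    "depth": float(rec.depth),
                }
            )
            ann_id += 1

    doc = {
        "info": {"description": description, "version": "1.0"},
        "licenses": [{"id": 1, "name": "unspecified", "url": ""}],
        "categories": [{"id": 1, "name": "fish", "supercategory": "animal"}],
        "images": [
            {"id": im.id, "file_name": im.file_name, "width": im.width, "height": im.height}
            for im in images
        ],
        "annotations": annotations,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_coco(path) -> dict:
    """Load and structurally validate a COCO detection JSON file."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("info", "licenses", "categories", "images", "annotations"):
        if key not in doc:
            raise FormatError(f"{path}: missing top-level key '{key}'")
    for i, im in enumerate(doc["images"]):
        for key in ("id", "file_name", "width", "height"):
            if key not in im:
                raise FormatError(f"{path}: images[{i}] missing '{key}'")
    image_ids = {im["id"] for im in doc["images"]}
    for i, ann in enumerate(doc["annotations"]):
        for key in ("id", "image_id", "category_id", "bbox", "area", "iscrowd"):
            if key not in ann:
                raise FormatError(f"{path}: annotations[{i}] missing '{key}'")
        if len(ann["bbox"]) != 4:
            raise FormatError(f"{path}: annotations[{i}].bbox must have 4 entries")
        if ann["image_id"] not in image_ids:
            raise FormatError(f"{path}: annotations[{i}].image_id not in images")
    return doc
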