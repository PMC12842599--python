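"""COCO-dialect I/O for ground-truth annotations and detection results.

Boxes are kept exactly as COCO stores them: ``[x, y, width, height]`` in
pixel units, origin at the image's top-left corner, x rightward and y
downward, zero-based. No coordinate transformation is applied on read or
write, so read -> write -> read is an identity on the in-memory structures.

Only plain boxes are supported. Annotations carrying ``iscrowd = 1`` are
rejected outright rather than half-implementing COCO crowd semantics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "Box",
    "GroundTruthSet",
    "DetectionSet",
    "ParseError",
    "read_ground_truth",
    "read_detections",
    "write_ground_truth",
    "write_detections",
    "read_manifest",
]


class ParseError(ValueError):
    """A file violated the expected COCO dialect; the message names the record."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in COCO convention: top-left corner plus size."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"box coordinate {name} is not finite")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box width/height must be positive, got w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    def as_xywh(self) -> list[float]:
        return [self.x, self.y, self.w, self.h]


@dataclass
class GroundTruthSet:
    """Per-image annotated boxes plus the category catalogue.

    ``boxes`` maps image_id to a list of ``(Box, category_id)``; images with
    zero annotations are retained with an empty list.
    """

    boxes: dict[int, list[tuple[Box, int]]]
    categories: dict[int, str]

    @property
    def image_ids(self) -> list[int]:
        return sorted(self.boxes)

    def categories_in_image(self, image_id) -> list[int]:
        return sorted({cat for _, cat in self.boxes[image_id]})

    def n_boxes(self) -> int:
        return sum(len(v) for v in self.boxes.values())


@dataclass
class DetectionSet:
    """Scored predicted boxes for one variant, grouped per image.

    ``detections`` maps image_id to a list of ``(Box, category_id, score)``
    in file order (the stable tie-break order for equal confidences).
    """

    variant_id: int
    detections: dict[int, list[tuple[Box, int, float]]]
    variant_name: str = ""

    def for_image(self, image_id) -> list[tuple[Box, int, float]]:
        return self.detections.get(image_id, [])

    def n_detections(self) -> int:
        return sum(len(v) for v in self.detections.values())


def _load_json(path) -> object:
    path = Path(path)
    try:
        with open(path) as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON ({exc})") from exc


def _parse_bbox(raw, context: str) -> Box:
    if not isinstance(raw, (list, tuple)) or len(raw) != 4:
        raise ParseError(f"{context}: bbox must be [x, y, w, h], got {raw!r}")
    try:
        return Box(*(float(v) for v in raw))
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{context}: invalid bbox {raw!r} ({exc})") from exc


def read_ground_truth(path) -> GroundTruthSet:
    """Read a COCO annotation file (images / annotations / categories arrays)."""
    data = _load_json(path)
    for key in ("images", "annotations", "categories"):
        if key not in data:
            raise ParseError(f"{path}: missing top-level {key!r} array")
    categories = {}
    for cat in data["categories"]:
        categories[int(cat["id"])] = str(cat.get("name", cat["id"]))
    boxes: dict[int, list[tuple[Box, int]]] = {}
    seen: set[int] = set()
    for img in data["images"]:
        image_id = int(img["id"])
        if image_id in seen:
            raise ParseError(f"{path}: duplicate image id {image_id}")
        seen.add(image_id)
        boxes[image_id] = []
    for ann in data["annotations"]:
        context = f"{path}: annotation id {ann.get('id', '?')}"
        if int(ann.get("iscrowd", 0)) == 1:
            raise ParseError(f"{context}: crowd annotations are not supported")
        if "bbox" not in ann:
            raise ParseError(f"{context}: missing bbox")
        image_id = int(ann["image_id"])
        if image_id not in boxes:
            raise ParseError(f"{context}: references unknown image id {image_id}")
        category_id = int(ann["category_id"])
        if category_id not in categories:
            raise ParseError(f"{context}: unknown category id {category_id}")
        boxes[image_id].append((_parse_bbox(ann["bbox"], context), category_id))
    return GroundTruthSet(boxes=boxes, categories=categories)


def read_detections(path, variant_id: int, ground_truth: GroundTruthSet | None = None,
                    unknown_image: str = "error", variant_name: str = "") -> DetectionSet:
    """Read a COCO results file (list of {image_id, category_id, bbox, score}).

    When ``ground_truth`` is given, detections for image ids absent from it
    are an error by default (``unknown_image="error"``); pass ``"warn"`` to
    keep them and get a flag list in ``result.detections``-external handling,
    or ``"drop"`` to discard them silently.
    """
    data = _load_json(path)
    if not isinstance(data, list):
        raise ParseError(f"{path}: COCO results file must be a JSON array")
    detections: dict[int, list[tuple[Box, int, float]]] = {}
    if ground_truth is not None:
        known = set(ground_truth.boxes)
    for i, det in enumerate(data):
        context = f"{path}: result #{i}"
        image_id = int(det["image_id"])
        score = float(det["score"])
        if not 0.0 <= score <= 1.0:
            raise ParseError(f"{context}: score {score} outside [0, 1]")
        if ground_truth is not None and image_id not in known:
            if unknown_image == "error":
                raise ParseError(f"{context}: image id {image_id} not in ground truth")
            if unknown_image == "drop":
                continue
        box = _parse_bbox(det["bbox"], context)
        detections.setdefault(image_id, []).append((box, int(det["category_id"]), score))
    return DetectionSet(variant_id=int(variant_id), detections=detections, variant_name=variant_name)


def write_ground_truth(gt: GroundTruthSet, path) -> None:
    """Write a GroundTruthSet back to the COCO annotation dialect."""
    images = [{"id": image_id} for image_id in gt.image_ids]
    annotations = []
    ann_id = 1
    for image_id in gt.image_ids:
        for box, category_id in gt.boxes[image_id]:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": image_id,
                    "category_id": category_id,
                    "bbox": box.as_xywh(),
                    "area": box.area,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    categories = [{"id": cid, "name": name} for cid, name in sorted(gt.categories.items())]
    with open(path, "w") as fh:
        json.dump({"images": images, "annotations": annotations, "categories": categories}, fh)


def write_detections(dets: DetectionSet, path) -> None:
    """Write a DetectionSet back to the COCO results dialect."""
    out = []
    for image_id in sorted(dets.detections):
        for box, category_id, score in dets.detections[image_id]:
            out.append(
                {
                    "image_id": image_id,
                    "category_id": category_id,
                    "bbox": box.as_xywh(),
                    "score": score,
                }
            )
    with open(path, "w") as fh:
        json.dump(out, fh)


def read_manifest(path) -> dict:
    """Read a YAML manifest mapping variant names to files.

    Expected shape::

        ground_truth: annotations.json
        variants:
          - {name: original, variant_id: 0, detections: dets_original.json}
          - {name: enhancerA, variant_id: 1, detections: dets_a.json}
    """
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "variants" not in manifest:
        raise ParseError(f"{path}: manifest must contain a 'variants' list")
    names = [v["name"] for v in manifest["variants"]]
    if len(names) != len(set(names)):
        raise ParseError(f"{path}: variant names must be unique")
    return manifest
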