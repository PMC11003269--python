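"""Lesion annotation model, COCO-style JSON I/O and dataset summaries.

Four lesion classes (comedone, papule, pustule, nodule) are annotated with
axis-aligned rectangles; the two irregular classes (cyst, scar) carry
polygon outlines.  Coordinates are 0-based continuous pixel coordinates,
boxes are half-open ``[x, x+w) × [y, y+h)`` and a pixel belongs to a polygon
iff its center ``(col+0.5, row+0.5)`` lies inside under the even–odd rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

BOX_CLASSES = ("comedone", "papule", "pustule", "nodule")
POLYGON_CLASSES = ("cyst", "scar")
LESION_CLASSES = BOX_CLASSES + POLYGON_CLASSES


class SchemaError(ValueError):
    """Annotation violates the documented dialect."""


def geometry_kind(cls: str) -> str:
    if cls in BOX_CLASSES:
        return "box"
    if cls in POLYGON_CLASSES:
        return "polygon"
    raise SchemaError(f"unknown lesion class {cls!r}")


@dataclass
class LesionInstance:
    cls: str
    box: Optional[Tuple[float, float, float, float]] = None
    polygon: Optional[List[Tuple[float, float]]] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        kind = geometry_kind(self.cls)
        if kind == "box":
            if self.box is None or self.polygon is not None:
                raise SchemaError(f"class {self.cls!r} requires a box geometry")
            x, y, w, h = self.box
            if w <= 0 or h <= 0:
                raise SchemaError("box width and height must be positive")
        else:
            if self.polygon is None or self.box is not None:
                raise SchemaError(f"class {self.cls!r} requires a polygon geometry")
            if len(self.polygon) < 3:
                raise SchemaError("polygon needs at least 3 vertices")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise SchemaError("score must lie in [0, 1]")

    def bounding_box(self) -> Tuple[float, float, float, float]:
        """Axis-aligned bounds of either geometry, as (x, y, w, h)."""
        if self.box is not None:
            return self.box
        xs = [p[0] for p in self.polygon]
        ys = [p[1] for p in self.polygon]
        return (min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))


@dataclass
class AnnotationSet:
    image_id: str
    image_size: Tuple[int, int]  # (H, W)
    instances: List[LesionInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, w = self.image_size
        for inst in self.instances:
            bx, by, bw, bh = inst.bounding_box()
            if bx < 0 or by < 0 or bx + bw > w or by + bh > h:
                raise SchemaError(
                    f"instance of {inst.cls!r} outside [0,{w}]×[0,{h}]")

    def counts(self) -> Dict[str, int]:
        c = {cls: 0 for cls in LESION_CLASSES}
        for inst in self.instances:
            c[inst.cls] += 1
        return c


@dataclass
class DatasetManifest:
    """Per-split image counts plus a declared grand total."""

    split_counts: Dict[str, int]
    total: int
    class_totals: Optional[Dict[str, Dict[str, int]]] = None


# ---------------------------------------------------------------------------
# JSON dialect

def _canonical_payload(sets: Sequence[AnnotationSet]) -> dict:
    images, annotations = [], []
    for s in sorted(sets, key=lambda s: s.image_id):
        h, w = s.image_size
        images.append({"id": s.image_id, "file_name": f"{s.image_id}.png",
                       "height": int(h), "width": int(w), "split": "none"})
        for inst in s.instances:
            rec: dict = {"image_id": s.image_id, "category": inst.cls}
            if inst.box is not None:
                rec["bbox"] = [float(v) for v in inst.box]
            else:
                flat = [float(v) for xy in inst.polygon for v in xy]
                rec["segmentation"] = [flat]
            if inst.score is not None:
                rec["score"] = float(inst.score)
            annotations.append(rec)
    return {"images": images, "annotations": annotations,
            "categories": list(LESION_CLASSES)}


def write_annotations(sets: Sequence[AnnotationSet], path,
                      splits: Optional[Dict[str, str]] = None) -> None:
    """Write the COCO-style dialect; ``splits`` maps image_id → split tag."""
    payload = _canonical_payload(sets)
    if splits:
        for img in payload["images"]:
            img["split"] = splits.get(img["id"], "none")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_annotations(path) -> List[AnnotationSet]:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed JSON: {exc}") from exc
    for key in ("images", "annotations", "categories"):
        if key not in payload:
            raise SchemaError(f"missing top-level key {key!r}")
    for name in payload["categories"]:
        if name not in LESION_CLASSES:
            raise SchemaError(f"unknown category {name!r}")
    by_id: Dict[str, AnnotationSet] = {}
    for img in payload["images"]:
        by_id[img["id"]] = AnnotationSet(
            image_id=img["id"], image_size=(img["height"], img["width"]))
    for rec in payload["annotations"]:
        if rec["image_id"] not in by_id:
            raise SchemaError(f"annotation references unknown image {rec['image_id']!r}")
        cls = rec["category"]
        kind = geometry_kind(cls)
        if kind == "box":
            if "bbox" not in rec or "segmentation" in rec:
                raise SchemaError(f"class {cls!r} must carry bbox geometry")
            inst = LesionInstance(cls, box=tuple(rec["bbox"]),
                                  score=rec.get("score"))
        else:
            if "segmentation" not in rec or "bbox" in rec:
                raise SchemaError(f"class {cls!r} must carry polygon geometry")
            flat = rec["segmentation"][0]
            if len(flat) % 2 or len(flat) < 6:
                raise SchemaError("segmentation must hold ≥3 (x, y) pairs")
            poly = [(flat[i], flat[i + 1]) for i in range(0, len(flat), 2)]
            inst = LesionInstance(cls, polygon=poly, score=rec.get("score"))
        s = by_id[rec["image_id"]]
        s.instances.append(inst)
    for s in by_id.values():
        AnnotationSet(s.image_id, s.image_size, s.instances)  # re-validate bounds
    return [by_id[k] for k in sorted(by_id)]


def read_splits(path) -> Dict[str, str]:
    """Split tags recorded alongside the annotations file."""
    with open(path) as fh:
        payload = json.load(fh)
    return {img["id"]: img.get("split", "none") for img in payload["images"]}


# ---------------------------------------------------------------------------
# Polygon rasterization (pixel-center even–odd rule)

def rasterize_polygon(polygon: Sequence[Tuple[float, float]], H: int, W: int) -> np.ndarray:
    """Fill a polygon onto an H×W grid.

    A pixel (row r, col c) is set iff its center (c+0.5, r+0.5) is inside the
    polygon under the even–odd (ray crossing) rule.  Self-intersecting rings
    are accepted; the rule keeps the result deterministic.
    """
    if len(polygon) < 3:
        raise ValueError("degenerate polygon: need at least 3 vertices")
    verts = np.asarray(polygon, dtype=np.float64)
    cx = np.arange(W) + 0.5
    cy = np.arange(H) + 0.5
    px = np.broadcast_to(cx, (H, W))
    py = np.broadcast_to(cy[:, None], (H, W))
    inside = np.zeros((H, W), dtype=bool)
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for ax, ay, bx, by in zip(x1, y1, x2, y2):
        if ay == by:
            continue  # horizontal edge never crosses a horizontal ray test band
        cond = (ay > py) != (by > py)
        with np.errstate(invalid="ignore"):
            xint = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= cond & (px < xint)
    return inside


# ---------------------------------------------------------------------------
# Dataset ledger / summary arithmetic

def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def class_shares(means: Sequence[float]) -> List[float]:
    """Percentage share of each class's per-image mean, half-up at 2 decimals."""
    total = float(np.sum(means))
    if total == 0:
        return [0.0 for _ in means]
    return [_round2(100.0 * m / total) for m in means]


def summarize_dataset(sets_by_split: Dict[str, Sequence[AnnotationSet]]) -> dict:
    """Per-split per-class mean instances per image and percentage shares."""
    summary: dict = {"splits": {}}
    split_counts, class_totals = {}, {}
    for split, sets in sets_by_split.items():
        if len(sets) == 0:
            raise ValueError(f"empty split {split!r}: cannot summarize")
        totals = {cls: 0 for cls in LESION_CLASSES}
        for s in sets:
            for cls, n in s.counts().items():
                totals[cls] += n
        n_img = len(sets)
        means = [totals[c] / n_img for c in LESION_CLASSES]
        shares = class_shares(means)
        summary["splits"][split] = {
            "n_images": n_img,
            "mean_per_image": dict(zip(LESION_CLASSES, means)),
            "share_percent": dict(zip(LESION_CLASSES, shares)),
        }
        split_counts[split] = n_img
        class_totals[split] = totals
    summary["manifest"] = DatasetManifest(
        split_counts=split_counts, total=sum(split_counts.values()),
        class_totals=class_totals)
    return summary


def validate_splits(manifest: DatasetManifest) -> Tuple[bool, dict]:
    """Check that the per-split image counts add up to the declared total."""
    counted = sum(manifest.split_counts.values())
    ok = counted == manifest.total
    report = {"declared_total": manifest.total, "counted_total": counted,
              "split_counts": dict(manifest.split_counts), "ok": ok}
    return ok, report
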