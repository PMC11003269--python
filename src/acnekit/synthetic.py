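"""Seeded generator of face-like images with annotated acne lesions.

Scenes emulate the structure of smartphone acne photographs at desk scale:
a skin-tone background with a brighter elliptical face region, on which the
six lesion classes are placed without heavy overlap — comedones as small
dark dots, papules as red discs, pustules as red discs with a bright core,
nodules as large dark-red discs, cysts as compact irregular polygon blobs
and scars as elongated blobs.  Box classes are annotated by the drawn
disc's bounding box, polygon classes by their vertex rings.  Everything is
a pure function of the spec and its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from .annotations import (LESION_CLASSES, AnnotationSet, DatasetManifest,
                          LesionInstance, rasterize_polygon, write_annotations)
from .records import ImageRecord

SKIN_BASE = np.array([209.0, 178.0, 152.0])
FACE_TONE = np.array([228.0, 198.0, 172.0])

LESION_COLOR = {
    "comedone": np.array([74.0, 52.0, 38.0]),
    "papule": np.array([204.0, 72.0, 70.0]),
    "pustule": np.array([206.0, 80.0, 72.0]),
    "pustule_core": np.array([240.0, 230.0, 178.0]),
    "nodule": np.array([132.0, 28.0, 38.0]),
    "cyst": np.array([186.0, 92.0, 144.0]),
    "scar": np.array([164.0, 118.0, 102.0]),
}

# lesion extent ranges in pixels (diameter for discs, major axis for blobs)
DEFAULT_SIZE_RANGES = {
    "comedone": (3, 5), "papule": (5, 9), "pustule": (6, 10),
    "nodule": (11, 16), "cyst": (8, 13), "scar": (9, 16),
}

# Per-image mean counts for dataset emulation: the clinical class mix
# (comedones-heavy, nodules rare) scaled down to what fits a desk-scale face.
CLINICAL_MEANS = {"comedone": 4.89, "papule": 2.74, "pustule": 0.35,
                  "nodule": 0.09, "cyst": 1.03, "scar": 4.09}
DATASET_SCALE = 0.30  # ≈4 lesions per 64×64 scene on average


class CapacityError(RuntimeError):
    """Could not place all requested lesions without heavy overlap."""


@dataclass
class SceneSpec:
    size: Tuple[int, int] = (64, 64)  # (H, W)
    # exact per-class instance counts; sampled upstream when ranges are used
    counts: Dict[str, int] = field(default_factory=lambda: {c: 0 for c in LESION_CLASSES})
    size_ranges: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_RANGES))
    max_overlap_iou: float = 0.3
    max_rejections: int = 1000
    noise_amplitude: float = 5.0
    seed: int = 0


def benchmark_spec_counts(rng: np.random.Generator) -> Dict[str, int]:
    """Per-class counts for the detection benchmark: every class has support."""
    return {
        "comedone": int(rng.integers(1, 4)),
        "papule": int(rng.integers(1, 3)),
        "pustule": int(rng.integers(0, 3)),
        "nodule": int(rng.integers(0, 2)),
        "cyst": int(rng.integers(0, 2)),
        "scar": int(rng.integers(0, 2)),
    }


def clinical_mix_counts(rng: np.random.Generator,
                        scale: float = DATASET_SCALE) -> Dict[str, int]:
    """Poisson counts whose means follow the clinical validation-split mix."""
    return {c: int(rng.poisson(CLINICAL_MEANS[c] * scale))
            for c in LESION_CLASSES}


def _box_iou(a, b) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union else 0.0


def _star_polygon(rng: np.random.Generator, cx: float, cy: float,
                  radius: float, elongation: float = 1.0,
                  n_vertices: int = 8) -> List[Tuple[float, float]]:
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = radius * rng.uniform(0.65, 1.0, n_vertices)
    theta = rng.uniform(0, np.pi)
    xs = radii * np.cos(angles) * elongation
    ys = radii * np.sin(angles)
    rot_x = xs * np.cos(theta) - ys * np.sin(theta) + cx
    rot_y = xs * np.sin(theta) + ys * np.cos(theta) + cy
    return [(float(x), float(y)) for x, y in zip(rot_x, rot_y)]


def render_scene(spec: SceneSpec) -> Tuple[ImageRecord, AnnotationSet]:
    """Render one annotated scene deterministically from the spec."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    img = np.empty((H, W, 3))
    img[:] = SKIN_BASE
    # face ellipse, recorded as the face region
    fcy, fcx = H / 2.0, W / 2.0
    ry, rx = 0.44 * H, 0.40 * W
    yy, xx = np.mgrid[0:H, 0:W]
    ellipse = ((yy + 0.5 - fcy) / ry) ** 2 + ((xx + 0.5 - fcx) / rx) ** 2 <= 1.0
    img[ellipse] = FACE_TONE
    img += rng.normal(0.0, spec.noise_amplitude, img.shape)
    face_region = (int(np.floor(fcx - rx)), int(np.floor(fcy - ry)),
                   int(np.ceil(2 * rx)), int(np.ceil(2 * ry)))

    instances: List[LesionInstance] = []
    placed_boxes: List[Tuple[float, float, float, float]] = []
    rejections = 0

    def place(extent: float) -> Tuple[float, float]:
        """Sample a lesion center inside the face ellipse with margin."""
        nonlocal rejections
        half = extent / 2.0
        while True:
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform())
            cx = fcx + rad * (rx - half - 1.0) * np.cos(ang)
            cy = fcy + rad * (ry - half - 1.0) * np.sin(ang)
            bbox = (cx - half, cy - half, extent, extent)
            if (0 <= bbox[0] and 0 <= bbox[1]
                    and bbox[0] + extent <= W and bbox[1] + extent <= H
                    and all(_box_iou(bbox, b) <= spec.max_overlap_iou
                            for b in placed_boxes)):
                return cx, cy
            rejections += 1
            if rejections >= spec.max_rejections:
                raise CapacityError(
                    f"could not place lesions after {rejections} rejections")

    def draw_disc(cx, cy, d, color, core=None):
        r = d / 2.0
        dist = np.sqrt((yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2)
        m = dist <= r
        shade = 1.0 - 0.25 * (dist[m] / max(r, 1e-9))  # darker rim-to-center ramp
        img[m] = color * shade[:, None] + rng.normal(0, 2.0, (int(m.sum()), 3))
        if core is not None:
            img[dist <= 0.4 * r] = core

    for cls in LESION_CLASSES:
        for _ in range(spec.counts.get(cls, 0)):
            lo, hi = spec.size_ranges[cls]
            extent = float(rng.uniform(lo, hi))
            cx, cy = place(extent)
            if cls in ("comedone", "papule", "pustule", "nodule"):
                core = LESION_COLOR["pustule_core"] if cls == "pustule" else None
                draw_disc(cx, cy, extent, LESION_COLOR[cls], core)
                box = (cx - extent / 2.0, cy - extent / 2.0, extent, extent)
                instances.append(LesionInstance(cls, box=box))
                placed_boxes.append(box)
            else:
                elong = rng.uniform(2.0, 3.0) if cls == "scar" else 1.0
                radius = extent / 2.0 / (elong if cls == "scar" else 1.0)
                poly = _star_polygon(rng, cx, cy, radius, elongation=elong)
                poly = [(float(np.clip(x, 0, W)), float(np.clip(y, 0, H)))
                        for x, y in poly]
                mask = rasterize_polygon(poly, H, W)
                img[mask] = LESION_COLOR[cls] + rng.normal(0, 2.0, (int(mask.sum()), 3))
                instances.append(LesionInstance(cls, polygon=poly))
                xs_ = [p[0] for p in poly]
                ys_ = [p[1] for p in poly]
                placed_boxes.append((min(xs_), min(ys_),
                                     max(xs_) - min(xs_), max(ys_) - min(ys_)))

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    rec = ImageRecord(id=f"scene-{spec.seed}", pixels=pixels,
                      face_region=face_region)
    ann = AnnotationSet(image_id=rec.id, image_size=(H, W), instances=instances)
    return rec, ann


def degrade(image: ImageRecord, kind: str, *, sigma: float = 3.0,
            factor: float = 0.5, fraction: float = 0.5,
            seed: int = 0) -> ImageRecord:
    """Return a degraded copy: 'blur', 'darken' or 'saturate'."""
    px = image.pixels.astype(np.float64)
    if kind == "blur":
        out = np.stack([ndimage.gaussian_filter(px[..., c], sigma)
                        for c in range(3)], axis=-1)
    elif kind == "darken":
        out = px * factor
    elif kind == "saturate":
        rng = np.random.default_rng(seed)
        flat = rng.uniform(size=image.shape) < fraction
        out = px.copy()
        out[flat] = 255.0
    else:
        raise ValueError(f"unknown degradation {kind!r}")
    return ImageRecord(id=f"{image.id}/{kind}",
                       pixels=np.clip(np.round(out), 0, 255).astype(np.uint8),
                       split=image.split, face_region=image.face_region)


@dataclass
class SyntheticDataset:
    records: List[ImageRecord]
    annotations: List[AnnotationSet]
    manifest: DatasetManifest

    def split(self, name: str) -> List[Tuple[ImageRecord, AnnotationSet]]:
        return [(r, a) for r, a in zip(self.records, self.annotations)
                if r.split == name]


def generate_dataset(n_images: int, template: Optional[SceneSpec] = None,
                     split_ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0, out_dir=None,
                     count_sampler=clinical_mix_counts) -> SyntheticDataset:
    """Generate a dataset of annotated scenes with train/val/test splits.

    ``count_sampler`` draws per-image class counts; the default follows the
    clinical validation-split class mix.  When ``out_dir`` is given, PNG
    images, the annotations JSON and a manifest JSON are written there.
    """
    if n_images <= 0:
        raise ValueError("n_images must be positive")
    if abs(sum(split_ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    template = template or SceneSpec()
    master = np.random.default_rng(seed)
    n_train = int(round(n_images * split_ratios[0]))
    n_val = int(round(n_images * split_ratios[1]))
    n_test = n_images - n_train - n_val
    split_of = (["train"] * n_train + ["val"] * n_val + ["test"] * n_test)

    records, annotations = [], []
    for i in range(n_images):
        scene_seed = int(master.integers(0, 2 ** 31 - 1))
        count_rng = np.random.default_rng(scene_seed + 1)
        spec = replace(template, counts=count_sampler(count_rng),
                       seed=scene_seed)
        rec, ann = render_scene(spec)
        rec.id = f"img-{i:05d}"
        ann.image_id = rec.id
        rec.split = split_of[i]
        records.append(rec)
        annotations.append(ann)

    manifest = DatasetManifest(
        split_counts={"train": n_train, "val": n_val, "test": n_test},
        total=n_images)
    ds = SyntheticDataset(records, annotations, manifest)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        for rec in records:
            Image.fromarray(rec.pixels).save(out / "images" / f"{rec.id}.png")
        write_annotations(annotations, out / "ann.json",
                          splits={r.id: r.split for r in records})
        with open(out / "manifest.json", "w") as fh:
            json.dump({"total": manifest.total,
                       "split_counts": manifest.split_counts}, fh, indent=1)
    return ds
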