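"""Encode annotations into center-point training targets and decode back.

Boxes become per-class Gaussian peaks on a stride-R heatmap plus sub-cell
offset and (w, h) size entries at the integer center cell; cyst/scar
polygons are rasterized into full-resolution binary masks.  Decoding finds
3×3 local maxima on a predicted heatmap, recovers continuous centers via
the offset channel and reads sizes at the peak cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union
from skimage.measure import label as cc_label

from .annotations import (BOX_CLASSES, POLYGON_CLASSES, AnnotationSet,
                          LesionInstance, rasterize_polygon)


@dataclass
class TargetTensors:
    heatmap: np.ndarray      # C × h × w in [0, 1], exact 1 at centers
    offset: np.ndarray       # 2 × h × w, entries in [0, 1) at centers
    size: np.ndarray         # 2 × h × w, (w, h) in input pixels at centers
    center_mask: np.ndarray  # h × w bool
    seg: np.ndarray          # M × H × W binary (cyst, scar)
    stride: int


@dataclass
class Detection:
    cls: str
    score: float
    box: Tuple[float, float, float, float]

    def to_instance(self) -> LesionInstance:
        return LesionInstance(self.cls, box=self.box, score=float(np.clip(self.score, 0, 1)))


def gaussian_radius(w_box: float, h_box: float, min_overlap: float = 0.7) -> float:
    """Largest center shift (in cells) keeping IoU ≥ ``min_overlap``.

    Solves the three standard quadratic cases (both corners shifted inward,
    one shrunk, one grown) and takes the smallest root, floored at 1.
    """
    if w_box <= 0 or h_box <= 0:
        raise ValueError("box dimensions must be positive")
    w, h = float(w_box), float(h_box)

    a1 = 1.0
    b1 = h + w
    c1 = w * h * (1.0 - min_overlap) / (1.0 + min_overlap)
    r1 = (b1 - np.sqrt(b1 ** 2 - 4 * a1 * c1)) / (2 * a1)

    a2 = 4.0
    b2 = 2.0 * (h + w)
    c2 = (1.0 - min_overlap) * w * h
    r2 = (b2 - np.sqrt(b2 ** 2 - 4 * a2 * c2)) / (2 * a2)

    a3 = 4.0 * min_overlap
    b3 = -2.0 * min_overlap * (h + w)
    c3 = (min_overlap - 1.0) * w * h
    r3 = (-b3 + np.sqrt(b3 ** 2 - 4 * a3 * c3)) / (2 * a3)

    return max(1.0, min(r1, r2, r3))


def _splat_gaussian(channel: np.ndarray, cx: int, cy: int, sigma: float) -> None:
    h, w = channel.shape
    radius = max(1, int(np.ceil(3.0 * sigma)))
    x0, x1 = max(0, cx - radius), min(w, cx + radius + 1)
    y0, y1 = max(0, cy - radius), min(h, cy + radius + 1)
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    g = np.exp(-(xs[None, :] ** 2 + ys[:, None] ** 2) / (2.0 * sigma ** 2))
    np.maximum(channel[y0:y1, x0:x1], g, out=channel[y0:y1, x0:x1])


def encode(ann: AnnotationSet, stride: int = 4,
           min_overlap: float = 0.7) -> TargetTensors:
    """Build training targets for one annotated image."""
    H, W = ann.image_size
    if H % stride or W % stride:
        raise ValueError(f"image size {H}×{W} not divisible by stride {stride}")
    h, w = H // stride, W // stride
    C = len(BOX_CLASSES)
    heat = np.zeros((C, h, w))
    off = np.zeros((2, h, w))
    size = np.zeros((2, h, w))
    mask = np.zeros((h, w), dtype=bool)
    seg = np.zeros((len(POLYGON_CLASSES), H, W), dtype=np.uint8)

    for inst in ann.instances:
        if inst.polygon is not None:
            m = POLYGON_CLASSES.index(inst.cls)
            seg[m] |= rasterize_polygon(inst.polygon, H, W).astype(np.uint8)
            continue
        bx, by, bw, bh = inst.box
        px, py = bx + bw / 2.0, by + bh / 2.0  # continuous center in pixels
        gx, gy = px / stride, py / stride
        ix, iy = int(np.floor(gx)), int(np.floor(gy))
        if not (0 <= ix < w and 0 <= iy < h):
            raise ValueError("box center outside image")
        ci = BOX_CLASSES.index(inst.cls)
        r = gaussian_radius(bw / stride, bh / stride, min_overlap)
        _splat_gaussian(heat[ci], ix, iy, sigma=r / 3.0)
        heat[ci, iy, ix] = 1.0
        off[:, iy, ix] = (gx - ix, gy - iy)
        size[:, iy, ix] = (bw, bh)
        mask[iy, ix] = True
    return TargetTensors(heat, off, size, mask, seg, stride)


def decode(heatmap: np.ndarray, offset: np.ndarray, size: np.ndarray,
           stride: int = 4, top_k: int = 100,
           score_min: float = 0.0) -> List[Detection]:
    """Extract detections from predicted grids.

    Peaks are cells equal to the maximum of their 3×3 neighborhood; plateau
    ties keep only the lowest row-major index per plateau neighborhood.
    Output is sorted by descending score (row-major order breaking ties),
    truncated to ``top_k``.
    """
    heatmap = np.asarray(heatmap, dtype=np.float64)
    if heatmap.shape[-2:] != offset.shape[-2:] or heatmap.shape[-2:] != size.shape[-2:]:
        raise ValueError("heatmap/offset/size grids must share spatial shape")
    C, h, w = heatmap.shape
    pad = np.pad(heatmap, ((0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
    is_max = np.ones_like(heatmap, dtype=bool)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            shifted = pad[:, 1 + dy:1 + dy + h, 1 + dx:1 + dx + w]
            if dy < 0 or (dy == 0 and dx < 0):
                # strict against earlier row-major neighbors: on a plateau
                # only the lowest-index representative survives
                is_max &= heatmap > shifted
            else:
                is_max &= heatmap >= shifted
    is_max &= heatmap >= score_min
    dets: List[Detection] = []
    cs, ys, xs = np.nonzero(is_max)
    scores = heatmap[cs, ys, xs]
    order = np.lexsort((xs, ys, cs, -scores))[:top_k]
    for i in order:
        c, y, x = int(cs[i]), int(ys[i]), int(xs[i])
        score = float(scores[i])
        cx = stride * (x + float(offset[0, y, x]))
        cy = stride * (y + float(offset[1, y, x]))
        bw, bh = float(size[0, y, x]), float(size[1, y, x])
        dets.append(Detection(BOX_CLASSES[c], score,
                              (cx - bw / 2.0, cy - bh / 2.0, bw, bh)))
    return dets


def masks_to_instances(seg_prob: np.ndarray, threshold: float = 0.5,
                       min_area: int = 16) -> List[LesionInstance]:
    """Turn per-class segmentation probabilities into polygon instances.

    Thresholds each channel, labels 8-connected components, drops those
    below ``min_area`` pixels and emits each survivor's exact outer pixel
    boundary as a polygon (so rasterizing it reproduces the component).
    """
    seg_prob = np.asarray(seg_prob, dtype=np.float64)
    if seg_prob.min() < 0 or seg_prob.max() > 1:
        raise ValueError("segmentation probabilities must lie in [0, 1]")
    out: List[LesionInstance] = []
    for m, cls in enumerate(POLYGON_CLASSES[:seg_prob.shape[0]]):
        binary = seg_prob[m] >= threshold
        labels, n = cc_label(binary, connectivity=2, return_num=True)
        for k in range(1, n + 1):
            ys, xs = np.nonzero(labels == k)
            if ys.size < min_area:
                continue
            cells = unary_union([shapely_box(x, y, x + 1, y + 1)
                                 for x, y in zip(xs.tolist(), ys.tolist())])
            poly = max(cells.geoms, key=lambda g: g.area) \
                if cells.geom_type == "MultiPolygon" else cells
            ring = [(float(x), float(y)) for x, y in poly.exterior.coords[:-1]]
            out.append(LesionInstance(cls, polygon=ring))
    return out
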