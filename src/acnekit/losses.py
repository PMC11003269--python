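"""Multi-task loss family for the center-point detector.

Components:

* ``center_loss`` (L_k) — a focal-style penalized binary cross-entropy
  between predicted and true center heatmaps, with exponents α (prediction)
  and β (proximity down-weighting of near-center negatives).
* ``offset_loss`` (L_off) — L1 error of the sub-cell center offset, averaged
  over annotated centers.
* ``size_loss`` (L_size) — L1 error of (w, h) regression at centers.
* ``seg_loss`` (L_seg) — mean squared error of the cyst/scar segmentation maps.

The detection loss is L_det = L_k + λ_size·L_size + λ_off·L_off with
λ_size = 0.1 and λ_off = 1, and the total is L_total = L_det + L_seg.

``*_grad`` variants return ``(value, d value / d prediction)`` and are what
the training loop consumes; they are checked against finite differences in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np


@dataclass
class LossConfig:
    alpha: float = 2.0
    beta: float = 4.0
    lambda_size: float = 0.1
    lambda_off: float = 1.0
    epsilon: float = 1e-4  # clamp for predicted probabilities before logs
    # "pixels": divide L_k by h·w of the down-sampled map; "objects": by the
    # number of annotated centers (max 1).  Pixel normalization is the default.
    center_loss_norm: str = "pixels"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.center_loss_norm not in ("pixels", "objects"):
            raise ValueError("center_loss_norm must be 'pixels' or 'objects'")


@dataclass
class LossBreakdown:
    center: float
    offset: float
    size: float
    seg: float
    det: float
    total: float

    def as_dict(self) -> Dict[str, float]:
        return {"L_k": self.center, "L_off": self.offset, "L_size": self.size,
                "L_seg": self.seg, "L_det": self.det, "L_total": self.total}


def _check_shapes(a: np.ndarray, b: np.ndarray, name: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{name}: shape mismatch {a.shape} vs {b.shape}")


def center_loss_grad(pred: np.ndarray, target: np.ndarray,
                     cfg: LossConfig = LossConfig()) -> Tuple[float, np.ndarray]:
    """Focal heatmap loss and its gradient w.r.t. the predicted probabilities.

    ``pred`` holds probabilities in (0, 1) of shape C×h×w (any leading dims);
    ``target`` the ground-truth heatmap in [0, 1] with exact 1s at centers.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_shapes(pred, target, "center_loss")
    if target.min() < 0 or target.max() > 1:
        raise ValueError("heatmap target must lie in [0, 1]")
    a, b, eps = cfg.alpha, cfg.beta, cfg.epsilon
    y = np.clip(pred, eps, 1.0 - eps)
    clamped = (pred < eps) | (pred > 1.0 - eps)
    pos = target == 1.0
    if cfg.center_loss_norm == "pixels":
        n = pred.shape[-2] * pred.shape[-1]
        if pred.ndim > 3:  # batched: pixels per map, summed over batch
            n *= int(np.prod(pred.shape[:-3]))
    else:
        n = max(int(pos.sum()), 1)
    pos_term = (1.0 - y) ** a * np.log(y)
    neg_term = (1.0 - target) ** b * y ** a * np.log1p(-y)
    value = -(np.where(pos, pos_term, neg_term).sum()) / n
    # d/dy of each branch
    dpos = -a * (1.0 - y) ** (a - 1.0) * np.log(y) + (1.0 - y) ** a / y
    dneg = (1.0 - target) ** b * (a * y ** (a - 1.0) * np.log1p(-y)
                                  - y ** a / (1.0 - y))
    grad = -np.where(pos, dpos, dneg) / n
    grad[clamped] = 0.0
    return float(value), grad


def center_loss(pred, target, cfg: LossConfig = LossConfig()) -> float:
    return center_loss_grad(pred, target, cfg)[0]


def offset_loss_grad(pred: np.ndarray, target: np.ndarray,
                     center_mask: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean L1 offset error over annotated centers; 0 with no objects."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_shapes(pred, target, "offset_loss")
    mask = np.asarray(center_mask, dtype=bool)
    if mask.shape != pred.shape[-2:]:
        raise ValueError("center_mask must match the spatial grid")
    n = int(mask.sum())
    if n == 0:
        return 0.0, np.zeros_like(pred)
    diff = (pred - target) * mask  # broadcast over the 2 offset channels
    value = float(np.abs(diff).sum() / n)
    grad = np.sign(diff) / n
    return value, grad


def offset_loss(pred, target, center_mask) -> float:
    return offset_loss_grad(pred, target, center_mask)[0]


def size_loss_grad(pred: np.ndarray, target: np.ndarray,
                   center_mask: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean L1 (w, h) regression error over annotated centers."""
    return offset_loss_grad(pred, target, center_mask)  # identical form


def size_loss(pred, target, center_mask) -> float:
    return size_loss_grad(pred, target, center_mask)[0]


def seg_loss_grad(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean squared segmentation error over all M·H·W elements."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_shapes(pred, target, "seg_loss")
    n = pred.size
    diff = pred - target
    value = float((diff ** 2).sum() / n)
    grad = 2.0 * diff / n
    return value, grad


def seg_loss(pred, target) -> float:
    return seg_loss_grad(pred, target)[0]


def total_loss(center: float, offset: float, size: float, seg: float,
               cfg: LossConfig = LossConfig()) -> LossBreakdown:
    """Combine component losses with the fixed λ weights."""
    det = center + cfg.lambda_size * size + cfg.lambda_off * offset
    return LossBreakdown(center=center, offset=offset, size=size, seg=seg,
                         det=det, total=det + seg)


def compute_all(heat_pred, heat_gt, off_pred, off_gt, size_pred, size_gt,
                center_mask, seg_pred, seg_gt,
                cfg: LossConfig = LossConfig()) -> LossBreakdown:
    """Evaluate the full breakdown for one sample or batch."""
    lk = center_loss(heat_pred, heat_gt, cfg)
    lo = offset_loss(off_pred, off_gt, center_mask)
    ls = size_loss(size_pred, size_gt, center_mask)
    lg = seg_loss(seg_pred, seg_gt)
    return total_loss(lk, lo, ls, lg, cfg)
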