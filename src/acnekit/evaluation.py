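"""Detection and grading metrics: IoU matching, PR/AP, kappa, agreement.

Detections are matched to ground truth greedily in descending score order
at an IoU threshold (default 0.5); AP uses all-point interpolation of the
precision–recall curve.  Grading agreement is summarized by per-image
accuracy, a confusion matrix over grades NONE..IV, one-vs-rest sensitivity
and specificity per grade, Cohen's unweighted kappa, and the
downgrade-misdiagnosis and cross-grade error fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .annotations import (BOX_CLASSES, POLYGON_CLASSES, AnnotationSet,
                          LesionInstance, rasterize_polygon)
from .codec import Detection
from .grading import Grade


def box_iou(a: Sequence[float], b: Sequence[float]) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class MatchResult:
    """Score-ordered match flags per class, plus TP/FP/FN tallies."""

    flags: Dict[str, List[Tuple[float, bool]]]  # class -> [(score, is_tp)]
    n_gt: Dict[str, int]

    def tallies(self, cls: str) -> Tuple[int, int, int]:
        tp = sum(1 for _, ok in self.flags.get(cls, []) if ok)
        fp = sum(1 for _, ok in self.flags.get(cls, []) if not ok)
        fn = self.n_gt.get(cls, 0) - tp
        return tp, fp, fn


def match_detections(preds: Sequence[Detection],
                     gts: Sequence[LesionInstance],
                     iou_min: float = 0.5,
                     classes: Sequence[str] = BOX_CLASSES) -> MatchResult:
    """Greedy per-class matching of one image's detections to ground truth."""
    flags: Dict[str, List[Tuple[float, bool]]] = {c: [] for c in classes}
    n_gt = {c: sum(1 for g in gts if g.cls == c) for c in classes}
    for cls in classes:
        cls_gts = [g for g in gts if g.cls == cls]
        used = [False] * len(cls_gts)
        cls_preds = sorted((p for p in preds if p.cls == cls),
                           key=lambda p: -p.score)
        for p in cls_preds:
            best, best_iou = -1, iou_min
            for j, g in enumerate(cls_gts):
                if used[j]:
                    continue
                iou = box_iou(p.box, g.bounding_box())
                if iou > best_iou or (iou == best_iou and best < 0 and iou >= iou_min):
                    best, best_iou = j, iou
            if best >= 0 and box_iou(p.box, cls_gts[best].bounding_box()) >= iou_min:
                used[best] = True
                flags[cls].append((p.score, True))
            else:
                flags[cls].append((p.score, False))
    return MatchResult(flags=flags, n_gt=n_gt)


def merge_matches(results: Iterable[MatchResult]) -> MatchResult:
    flags: Dict[str, List[Tuple[float, bool]]] = {}
    n_gt: Dict[str, int] = {}
    for r in results:
        for cls, fl in r.flags.items():
            flags.setdefault(cls, []).extend(fl)
        for cls, n in r.n_gt.items():
            n_gt[cls] = n_gt.get(cls, 0) + n
    return MatchResult(flags=flags, n_gt=n_gt)


def pr_curve_ap(flags: Sequence[Tuple[float, bool]], n_gt: int):
    """All-point-interpolated AP from score-ordered match flags.

    Returns ``(precision, recall, ap, max_recall)``.  With no ground truth
    but some predictions AP is undefined and returned as NaN.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be non-negative")
    ordered = sorted(flags, key=lambda t: -t[0])
    tp = np.cumsum([1.0 if ok else 0.0 for _, ok in ordered])
    fp = np.cumsum([0.0 if ok else 1.0 for _, ok in ordered])
    ranks = np.arange(1, len(ordered) + 1)
    precision = tp / ranks if len(ordered) else np.array([])
    if n_gt == 0:
        ap = np.nan if len(ordered) else 0.0
        return precision, np.zeros_like(precision), ap, 0.0
    recall = tp / n_gt
    # precision envelope: best precision at any recall ≥ r
    env = np.maximum.accumulate(precision[::-1])[::-1] if len(ordered) else precision
    ap = 0.0
    prev_r = 0.0
    for i, (_, ok) in enumerate(ordered):
        if ok:
            ap += (recall[i] - prev_r) * env[i]
            prev_r = recall[i]
    max_recall = float(recall[-1]) if len(ordered) else 0.0
    return precision, recall, float(ap), max_recall


def error_recall_curve(flags: Sequence[Tuple[float, bool]], n_gt: int):
    """Error (1 − precision) against recall at every rank."""
    precision, recall, _, _ = pr_curve_ap(flags, n_gt)
    return 1.0 - precision, recall


def f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def detection_report(matches: MatchResult, iou_min: float = 0.5) -> dict:
    """Per-class precision/recall/F1/AP plus instance-set Jaccard accuracy."""
    out = {}
    for cls in matches.flags:
        tp, fp, fn = matches.tallies(cls)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        _, _, ap, max_rec = pr_curve_ap(matches.flags[cls], matches.n_gt[cls])
        out[cls] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": p, "recall": r, "f1": f1(p, r),
            "ap": ap, "max_recall": max_rec,
            # detection accuracy (Jaccard of instance sets) at the IoU threshold
            "accuracy": tp / (tp + fp + fn) if tp + fp + fn else 0.0,
        }
    aps = [v["ap"] for v in out.values() if not np.isnan(v["ap"])]
    out["mean_ap"] = float(np.mean(aps)) if aps else float("nan")
    return out


# ---------------------------------------------------------------------------
# Agreement statistics

def cohen_kappa(labels_a: Sequence, labels_b: Sequence,
                categories: Optional[Sequence] = None) -> float:
    """Unweighted Cohen's kappa between two equal-length labelings."""
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must have equal length")
    if len(labels_a) == 0:
        raise ValueError("labelings must be non-empty")
    if categories is None:
        categories = sorted(set(labels_a) | set(labels_b), key=repr)
    idx = {c: i for i, c in enumerate(categories)}
    n = len(labels_a)
    cm = np.zeros((len(categories), len(categories)))
    for a, b in zip(labels_a, labels_b):
        cm[idx[a], idx[b]] += 1
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


GRADES = (Grade.NONE, Grade.I, Grade.II, Grade.III, Grade.IV)


def grade_agreement_report(pred: Sequence[Grade], ref: Sequence[Grade]) -> dict:
    """Per-image grading agreement against a reference labeling.

    The confusion matrix is indexed [reference, predicted] over
    NONE, I, II, III, IV.  The downgrade fraction is the share of errors
    where the prediction is milder than the reference; the cross-grade
    fraction counts |pred − ref| ≥ 2 errors over all predictions.
    """
    if len(pred) != len(ref):
        raise ValueError("prediction and reference lists must align")
    if len(pred) == 0:
        raise ValueError("empty input")
    cm = np.zeros((5, 5), dtype=int)
    for p, r in zip(pred, ref):
        cm[int(r), int(p)] += 1
    n = len(pred)
    errors = [(p, r) for p, r in zip(pred, ref) if p != r]
    per_grade = {}
    for g in GRADES:
        i = int(g)
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        per_grade[g.name] = {
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        }
    return {
        "confusion_matrix": cm,
        "accuracy": float(np.trace(cm) / n),
        "kappa": cohen_kappa(list(map(int, pred)), list(map(int, ref)),
                             categories=list(range(5))),
        "per_grade": per_grade,
        "downgrade_fraction": (sum(1 for p, r in errors if p < r) / len(errors)
                               if errors else 0.0),
        "cross_grade_fraction": sum(1 for p, r in zip(pred, ref)
                                    if abs(int(p) - int(r)) >= 2) / n,
    }
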