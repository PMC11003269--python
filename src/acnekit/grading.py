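"""Severity grading from per-image lesion counts.

The grade follows the Chinese Acne Treatment Guideline (2019 revision)
criteria — mild (I): only comedones; moderate (II): papules; moderate
(III): pustules; severe (IV): nodules or cysts — combined by the
maximum-severity rule: the highest grade whose defining lesion is present
wins.  Scars never influence the grade (no guideline grade mentions them)
but are always reported in the counts.  Lesion-free images map to the NONE
sentinel so the function is total.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .annotations import LESION_CLASSES, POLYGON_CLASSES, LesionInstance
from .codec import Detection


class Grade(IntEnum):
    NONE = 0
    I = 1
    II = 2
    III = 3
    IV = 4


def grade(counts: Dict[str, int]) -> Grade:
    """Map per-class lesion counts to a severity grade."""
    c = {cls: int(counts.get(cls, 0)) for cls in LESION_CLASSES}
    if any(v < 0 for v in c.values()):
        raise ValueError("lesion counts must be non-negative")
    if c["nodule"] + c["cyst"] > 0:
        return Grade.IV
    if c["pustule"] > 0:
        return Grade.III
    if c["papule"] > 0:
        return Grade.II
    if c["comedone"] > 0:
        return Grade.I
    return Grade.NONE


def grade_image(detections: Sequence[Detection],
                seg_instances: Sequence[LesionInstance] = (),
                score_min: float = 0.3) -> Tuple[Dict[str, int], Grade]:
    """Count score-thresholded detections plus segmentation instances, then grade."""
    counts = {cls: 0 for cls in LESION_CLASSES}
    for det in detections:
        if det.score >= score_min:
            counts[det.cls] += 1
    for inst in seg_instances:
        if inst.cls not in POLYGON_CLASSES:
            raise ValueError(f"segmentation instance of box class {inst.cls!r}")
        counts[inst.cls] += 1
    return counts, grade(counts)
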