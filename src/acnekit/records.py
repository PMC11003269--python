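"""Shared image containers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

Box = Tuple[float, float, float, float]  # (x, y, w, h), half-open pixel extent

SPLITS = ("train", "val", "test", "none")


@dataclass
class ImageRecord:
    """One RGB photograph plus bookkeeping.

    ``pixels`` is an H×W×3 uint8 array.  ``face_region`` is an optional
    axis-aligned (x, y, w, h) box in pixel coordinates that must lie inside
    the image; it stands in for an external face detector when one is not
    plugged in.
    """

    id: str
    pixels: np.ndarray
    split: str = "none"
    face_region: Optional[Box] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H×W×3")
        h, w = self.pixels.shape[:2]
        if h < 8 or w < 8:
            raise ValueError(f"image too small: {h}×{w}, need at least 8×8")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")
        if self.face_region is not None:
            x, y, bw, bh = self.face_region
            if not (0 <= x and 0 <= y and bw > 0 and bh > 0
                    and x + bw <= w and y + bh <= h):
                raise ValueError("face_region outside image bounds")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]

    def gray(self) -> np.ndarray:
        """Luma grayscale (0.299 R + 0.587 G + 0.114 B), float64 in [0, 255]."""
        p = self.pixels.astype(np.float64)
        return 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]
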