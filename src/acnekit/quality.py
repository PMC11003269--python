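"""Image usability gate: face crop, sharpness scoring, exposure screening.

A photograph passes the gate when (a) a face region can be obtained,
(b) a six-feature logistic-regression sharpness score clears a threshold,
and (c) the HSV lightness (V) channel flags neither under- nor
over-exposure.  The face region comes from a pluggable provider callback so
any external detector can be wired in; fixtures and the synthetic generator
supply known boxes instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from sklearn.linear_model import LogisticRegression

from .records import Box, ImageRecord

FaceProvider = Callable[[ImageRecord], Optional[Box]]

N_FEATURES = 6
FEATURE_NAMES = ("laplacian_var", "tenengrad", "brenner", "rms_contrast",
                 "edge_fraction", "highfreq_ratio")


@dataclass
class SharpnessModel:
    """Standardized logistic regression over the six sharpness features."""

    weights: np.ndarray
    bias: float
    feature_means: np.ndarray
    feature_scales: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(N_FEATURES)
        self.feature_means = np.asarray(self.feature_means, dtype=np.float64).reshape(N_FEATURES)
        self.feature_scales = np.asarray(self.feature_scales, dtype=np.float64).reshape(N_FEATURES)
        if not (np.isfinite(self.weights).all() and np.isfinite(self.bias)
                and np.isfinite(self.feature_means).all()
                and np.isfinite(self.feature_scales).all()):
            raise ValueError("model parameters must be finite")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"weights": self.weights.tolist(), "bias": self.bias,
                       "means": self.feature_means.tolist(),
                       "scales": self.feature_scales.tolist()}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SharpnessModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["weights"]), float(d["bias"]),
                   np.array(d["means"]), np.array(d["scales"]))


@dataclass
class QualityReport:
    sharpness_features: Optional[np.ndarray]
    sharpness_prob: Optional[float]
    exposure: str  # ok | too_dark | overexposed
    usable: bool
    reason: str = ""


def crop_face(image: ImageRecord, provider: Optional[FaceProvider] = None
              ) -> Tuple[ImageRecord, bool]:
    """Crop to the provided face box.

    Falls back to ``image.face_region`` when the provider abstains, and to a
    central 80%×80% crop (flagged via the returned boolean) when no region
    is known at all.
    """
    h, w = image.shape
    box = provider(image) if provider is not None else None
    fallback = False
    if box is None:
        box = image.face_region
    if box is None:
        bw, bh = int(round(w * 0.8)), int(round(h * 0.8))
        box = ((w - bw) // 2, (h - bh) // 2, bw, bh)
        fallback = True
    x, y, bw, bh = (int(round(v)) for v in box)
    if x < 0 or y < 0 or bw <= 0 or bh <= 0 or x + bw > w or y + bh > h:
        raise ValueError(f"face region {box} outside {h}×{w} image")
    sub = image.pixels[y:y + bh, x:x + bw]
    return ImageRecord(id=image.id + "/face", pixels=sub, split=image.split), fallback


def sharpness_features(image: ImageRecord) -> np.ndarray:
    """Six complementary blur cues on the luma channel.

    [variance of Laplacian, Tenengrad (mean squared Sobel gradient),
    Brenner gradient, RMS local contrast, Canny edge-pixel fraction,
    high-frequency spectral energy ratio] — all non-negative, all larger
    for sharper content.
    """
    g = image.gray()
    h, w = g.shape
    lap = ndimage.laplace(g, mode="nearest")
    lap_var = lap.var()
    gx = ndimage.sobel(g, axis=1, mode="nearest")
    gy = ndimage.sobel(g, axis=0, mode="nearest")
    tenengrad = float(np.mean(gx ** 2 + gy ** 2))
    brenner = float(np.mean((g[:, 2:] - g[:, :-2]) ** 2))
    local_mean = ndimage.uniform_filter(g, size=5, mode="nearest")
    rms_contrast = float(np.sqrt(np.mean((g - local_mean) ** 2)))
    edges = canny(g / 255.0, sigma=1.0)
    edge_fraction = float(edges.mean())
    spec = np.abs(np.fft.fft2(g - g.mean())) ** 2
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    high = np.sqrt(fy ** 2 + fx ** 2) > 0.15  # cycles/pixel
    total = spec.sum()
    highfreq_ratio = float(spec[high].sum() / total) if total > 0 else 0.0
    return np.array([lap_var, tenengrad, brenner, rms_contrast,
                     edge_fraction, highfreq_ratio])


def fit_sharpness_model(features: Sequence[np.ndarray],
                        labels: Sequence[int]) -> SharpnessModel:
    """Maximum-likelihood logistic fit after per-feature standardization.

    ``labels`` are 1 for sharp, 0 for blurred; both classes must appear.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"need n×{N_FEATURES} feature matrix")
    if len(set(y.tolist())) < 2:
        raise ValueError("degenerate labels: both classes required")
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    Z = (X - means) / scales
    clf = LogisticRegression(C=np.inf, tol=1e-6, max_iter=500)  # unpenalized ML fit
    clf.fit(Z, y)
    return SharpnessModel(weights=clf.coef_[0], bias=float(clf.intercept_[0]),
                          feature_means=means, feature_scales=scales)


def predict_sharpness(model: SharpnessModel, features: np.ndarray) -> float:
    """Probability that the image is sharp, via the standardized logistic."""
    x = np.asarray(features, dtype=np.float64).reshape(N_FEATURES)
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature vector")
    z = (x - model.feature_means) / model.feature_scales
    t = float(model.weights @ z + model.bias)
    if t >= 0:
        return float(1.0 / (1.0 + np.exp(-t)))
    e = np.exp(t)
    return float(e / (1.0 + e))


def exposure_check(image: ImageRecord, v_lo: float = 0.25,
                   s_hi: float = 0.30) -> str:
    """Classify exposure from the HSV V channel (max of R, G, B).

    Over-exposure (fraction of near-saturated pixels above ``s_hi``) takes
    precedence over darkness (mean V below ``v_lo``).
    """
    v = image.pixels.max(axis=2).astype(np.float64) / 255.0
    saturated = float((v > 0.98).mean())
    if saturated > s_hi:
        return "overexposed"
    if float(v.mean()) < v_lo:
        return "too_dark"
    return "ok"


def quality_gate(image: ImageRecord, model: SharpnessModel,
                 provider: Optional[FaceProvider] = None,
                 theta_sharp: float = 0.5, v_lo: float = 0.25,
                 s_hi: float = 0.30) -> QualityReport:
    """Run the full usability gate on one photograph.

    When a provider is wired in, its abstention means "no usable face"
    (occlusion, non-face content) and rejects the image outright; without a
    provider, ``crop_face``'s fallback chain applies.
    """
    if provider is not None and provider(image) is None:
        return QualityReport(None, None, exposure="ok", usable=False,
                             reason="no_face")
    face, fallback = crop_face(image, provider)
    feats = sharpness_features(face)
    prob = predict_sharpness(model, feats)
    exposure = exposure_check(face, v_lo=v_lo, s_hi=s_hi)
    usable = prob >= theta_sharp and exposure == "ok"
    reason = ""
    if exposure != "ok":
        reason = exposure
    elif prob < theta_sharp:
        reason = "blurred"
    elif fallback:
        reason = "central_crop_fallback"
    return QualityReport(feats, prob, exposure, usable, reason)
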