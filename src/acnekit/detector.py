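"""Center-point lesion detector with a segmentation branch.

A small encoder–decoder in the spirit of deep layer aggregation: a strided
encoder produces features at strides 1, 2, …, R; aggregation nodes fuse the
down-path features upward by channel concatenation and 1×1 mixing, both
toward the stride-R detection trunk (center heatmap, offset and size heads)
and toward a full-resolution segmentation head for cysts and scars.  The
network is sized for desk-scale synthetic benchmarks and trains on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import losses as L
from .annotations import BOX_CLASSES, POLYGON_CLASSES, AnnotationSet, LesionInstance
from .codec import Detection, TargetTensors, decode, encode, masks_to_instances
from .nn import Adam, Conv2d, Param, ReLU, Upsample2, sigmoid
from .records import ImageRecord

HEATMAP_PRIOR = 0.01  # untrained heatmap probability via head bias init


@dataclass
class ModelConfig:
    input_size: Tuple[int, int] = (64, 64)
    stride: int = 4
    box_classes: int = len(BOX_CLASSES)
    seg_classes: int = len(POLYGON_CLASSES)
    base_channels: int = 16
    aggregation_levels: int = 3
    use_deformable: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        H, W = self.input_size
        if H % self.stride or W % self.stride:
            raise ValueError("input size must be divisible by the stride")
        if self.base_channels < 4:
            raise ValueError("need at least 4 base channels")
        if 2 ** (self.aggregation_levels - 1) != self.stride:
            raise ValueError("aggregation_levels must satisfy 2^(levels-1) == stride")
        if self.use_deformable:
            raise NotImplementedError(
                "deformable convolution plug-in not included in this build; "
                "set use_deformable=False")


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    loss: L.LossConfig = field(default_factory=L.LossConfig)
    checkpoint_path: Optional[str] = None
    log_path: Optional[str] = None


class CenterNetLite:
    """Aggregation CNN mapping B×3×H×W to detection grids and seg maps."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        c1, c2, c3 = c, 2 * c, 3 * c
        self.stem = Conv2d(3, c1, 3, rng=rng)
        self.r_stem = ReLU()
        self.down1 = Conv2d(c1, c2, 3, stride=2, rng=rng)
        self.r_d1 = ReLU()
        self.down2 = Conv2d(c2, c3, 3, stride=2, rng=rng)
        self.r_d2 = ReLU()
        # upward aggregation nodes (concat + 1×1 mix)
        self.up32 = Upsample2()
        self.mix2 = Conv2d(c2 + c3, c2, 1, rng=rng)
        self.r_m2 = ReLU()
        self.up21 = Upsample2()
        self.mix1 = Conv2d(c1 + c2, c1, 1, rng=rng)
        self.r_m1 = ReLU()
        # detection trunk: re-aggregate mid-level context at stride R
        self.dagg = Conv2d(c2, c2, 3, stride=2, rng=rng)
        self.r_dagg = ReLU()
        self.mixd = Conv2d(c3 + c2, c3, 1, rng=rng)
        self.r_md = ReLU()
        # heads
        bias0 = float(np.log(HEATMAP_PRIOR / (1.0 - HEATMAP_PRIOR)))
        self.head_hm = Conv2d(c3, cfg.box_classes, 3, rng=rng, bias_init=bias0)
        self.head_off = Conv2d(c3, 2, 3, rng=rng)
        self.head_size = Conv2d(c3, 2, 3, rng=rng)
        self.head_seg = Conv2d(c1, cfg.seg_classes, 3, rng=rng,
                               bias_init=bias0)
        self._cache: dict = {}

    # -- plumbing -----------------------------------------------------------
    def layers(self):
        return [self.stem, self.down1, self.down2, self.mix2, self.mix1,
                self.dagg, self.mixd, self.head_hm, self.head_off,
                self.head_size, self.head_seg]

    def params(self) -> List[Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.params()))

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> Dict[str, np.ndarray]:
        """Raw (pre-sigmoid) head outputs for a normalized B×3×H×W batch."""
        f1 = self.r_stem.forward(self.stem.forward(x))
        f2 = self.r_d1.forward(self.down1.forward(f1))
        f3 = self.r_d2.forward(self.down2.forward(f2))
        a2 = self.r_m2.forward(self.mix2.forward(
            np.concatenate([f2, self.up32.forward(f3)], axis=1)))
        a1 = self.r_m1.forward(self.mix1.forward(
            np.concatenate([f1, self.up21.forward(a2)], axis=1)))
        d3 = self.r_dagg.forward(self.dagg.forward(a2))
        det = self.r_md.forward(self.mixd.forward(
            np.concatenate([f3, d3], axis=1)))
        out = {
            "heatmap": self.head_hm.forward(det),
            "offset": self.head_off.forward(det),
            "size": self.head_size.forward(det),
            "seg": self.head_seg.forward(a1),
        }
        c1 = f1.shape[1]
        c2 = f2.shape[1]
        c3 = f3.shape[1]
        self._cache = {"splits": (c1, c2, c3)}
        return out

    def backward(self, grads: Dict[str, np.ndarray]) -> None:
        """Accumulate parameter gradients from head-output gradients."""
        c1, c2, c3 = self._cache["splits"]
        g_det = (self.head_hm.backward(grads["heatmap"])
                 + self.head_off.backward(grads["offset"])
                 + self.head_size.backward(grads["size"]))
        g_cat_d = self.mixd.backward(self.r_md.backward(g_det))
        g_f3 = g_cat_d[:, :c3]
        g_a2 = self.dagg.backward(self.r_dagg.backward(g_cat_d[:, c3:]))
        g_a1 = self.head_seg.backward(grads["seg"])
        g_cat1 = self.mix1.backward(self.r_m1.backward(g_a1))
        g_f1 = g_cat1[:, :c1]
        g_a2 += self.up21.backward(g_cat1[:, c1:])
        g_cat2 = self.mix2.backward(self.r_m2.backward(g_a2))
        g_f2 = g_cat2[:, :c2]
        g_f3 += self.up32.backward(g_cat2[:, c2:])
        g_f2 += self.down2.backward(self.r_d2.backward(g_f3))
        g_f1 += self.down1.backward(self.r_d1.backward(g_f2))
        self.stem.backward(self.r_stem.backward(g_f1))

    # -- persistence --------------------------------------------------------
    def save(self, path, optimizer: Optional[Adam] = None,
             extra: Optional[dict] = None) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        meta = {"cfg": {"input_size": list(self.cfg.input_size),
                        "stride": self.cfg.stride,
                        "box_classes": self.cfg.box_classes,
                        "seg_classes": self.cfg.seg_classes,
                        "base_channels": self.cfg.base_channels,
                        "aggregation_levels": self.cfg.aggregation_levels,
                        "use_deformable": self.cfg.use_deformable,
                        "seed": self.cfg.seed},
                "extra": extra or {}}
        if optimizer is not None:
            arrays.update({f"m{i}": m for i, m in enumerate(optimizer.m)})
            arrays.update({f"v{i}": v for i, v in enumerate(optimizer.v)})
            meta["adam_t"] = optimizer.t
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path, with_optimizer: bool = False):
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        cfgd = meta["cfg"]
        cfgd["input_size"] = tuple(cfgd["input_size"])
        model = cls(ModelConfig(**cfgd))
        for i, p in enumerate(model.params()):
            p.data[...] = data[f"p{i}"]
        optimizer = None
        if with_optimizer and "adam_t" in meta:
            optimizer = Adam(model.params())
            optimizer.t = int(meta["adam_t"])
            for i in range(len(optimizer.m)):
                optimizer.m[i][...] = data[f"m{i}"]
                optimizer.v[i][...] = data[f"v{i}"]
        return model, optimizer, meta["extra"]


def build_model(cfg: ModelConfig) -> CenterNetLite:
    return CenterNetLite(cfg)


def normalize_image(rec: ImageRecord) -> np.ndarray:
    """HWC uint8 → CHW float64 with fixed affine normalization."""
    x = rec.pixels.astype(np.float64) / 255.0
    return np.transpose((x - 0.5) / 0.25, (2, 0, 1))


def _batch_loss_and_grads(out: Dict[str, np.ndarray],
                          targets: Sequence[TargetTensors],
                          cfg: L.LossConfig):
    """Per-batch LossBreakdown plus gradients w.r.t. raw head outputs."""
    B = out["heatmap"].shape[0]
    hm_p = sigmoid(out["heatmap"])
    seg_p = sigmoid(out["seg"])
    grads = {k: np.zeros_like(v) for k, v in out.items()}
    acc = np.zeros(4)
    for i, t in enumerate(targets):
        lk, g_hm = L.center_loss_grad(hm_p[i], t.heatmap, cfg)
        lo, g_off = L.offset_loss_grad(out["offset"][i], t.offset, t.center_mask)
        ls, g_sz = L.size_loss_grad(out["size"][i], t.size, t.center_mask)
        lg, g_seg = L.seg_loss_grad(seg_p[i], t.seg)
        grads["heatmap"][i] = g_hm * hm_p[i] * (1.0 - hm_p[i])
        grads["offset"][i] = g_off * cfg.lambda_off
        grads["size"][i] = g_sz * cfg.lambda_size
        grads["seg"][i] = g_seg * seg_p[i] * (1.0 - seg_p[i])
        acc += (lk, lo, ls, lg)
    acc /= B
    for g in grads.values():
        g /= B
    return L.total_loss(*acc, cfg), grads


def train(model: CenterNetLite, dataset: Sequence[Tuple[ImageRecord, AnnotationSet]],
          cfg: TrainConfig) -> List[L.LossBreakdown]:
    """Minimize the total multi-task loss with Adam; returns per-epoch losses."""
    stride = model.cfg.stride
    xs = [normalize_image(rec) for rec, _ in dataset]
    ts = [encode(ann, stride=stride) for _, ann in dataset]
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    log: List[L.LossBreakdown] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(xs))
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = np.stack([xs[i] for i in idx])
            out = model.forward(x)
            breakdown, grads = _batch_loss_and_grads(
                out, [ts[i] for i in idx], cfg.loss)
            if not np.isfinite(breakdown.total):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}: {breakdown.as_dict()}")
            opt.zero_grad()
            model.backward(grads)
            opt.step()
            sums += (breakdown.center, breakdown.offset,
                     breakdown.size, breakdown.seg)
            n_batches += 1
        log.append(L.total_loss(*(sums / n_batches), cfg.loss))
        if cfg.checkpoint_path:
            model.save(cfg.checkpoint_path, optimizer=opt,
                       extra={"epoch": epoch + 1,
                              "rng_state": rng.bit_generator.state})
    if cfg.log_path:
        with open(cfg.log_path, "w") as fh:
            fh.write("epoch,L_k,L_off,L_size,L_seg,L_det,L_total\n")
            for e, b in enumerate(log):
                fh.write(f"{e},{b.center},{b.offset},{b.size},"
                         f"{b.seg},{b.det},{b.total}\n")
    return log


def resume(checkpoint_path, dataset, cfg: TrainConfig) -> List[L.LossBreakdown]:
    """Continue training from a checkpoint saved by ``train``."""
    model, opt, extra = CenterNetLite.load(checkpoint_path, with_optimizer=True)
    start_epoch = int(extra["epoch"])
    stride = model.cfg.stride
    xs = [normalize_image(rec) for rec, _ in dataset]
    ts = [encode(ann, stride=stride) for _, ann in dataset]
    opt.lr = cfg.learning_rate
    rng = np.random.default_rng(cfg.seed)
    rng.bit_generator.state = extra["rng_state"]
    log: List[L.LossBreakdown] = []
    for epoch in range(start_epoch, cfg.epochs):
        order = rng.permutation(len(xs))
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = np.stack([xs[i] for i in idx])
            out = model.forward(x)
            breakdown, grads = _batch_loss_and_grads(
                out, [ts[i] for i in idx], cfg.loss)
            opt.zero_grad()
            model.backward(grads)
            opt.step()
            sums += (breakdown.center, breakdown.offset,
                     breakdown.size, breakdown.seg)
            n_batches += 1
        log.append(L.total_loss(*(sums / n_batches), cfg.loss))
    return log


def infer(model: CenterNetLite, rec: ImageRecord, score_min: float = 0.3,
          top_k: int = 100, seg_threshold: float = 0.5,
          min_area: int = 16) -> Tuple[List[Detection], List[LesionInstance], np.ndarray]:
    """Detections, segmentation instances and raw seg probabilities."""
    if rec.shape != tuple(model.cfg.input_size):
        raise ValueError(f"image size {rec.shape} does not match model "
                         f"input {model.cfg.input_size}")
    x = normalize_image(rec)[None]
    out = model.forward(x)
    hm = sigmoid(out["heatmap"][0])
    seg = sigmoid(out["seg"][0])
    dets = decode(hm, out["offset"][0], out["size"][0],
                  stride=model.cfg.stride, top_k=top_k, score_min=score_min)
    seg_instances = masks_to_instances(seg, threshold=seg_threshold,
                                      min_area=min_area)
    return dets, seg_instances, seg
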