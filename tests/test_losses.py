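"""Loss family: hand values, loop oracles, identities, gradient checks."""

import numpy as np
import pytest

from acnekit.losses import (LossConfig, center_loss, center_loss_grad,
                            compute_all, offset_loss, offset_loss_grad,
                            seg_loss, seg_loss_grad, size_loss,
                            size_loss_grad, total_loss)


# ---------------------------------------------------------------------------
# naive loop oracles

def oracle_center_loss(pred, target, cfg):
    a, b, eps = cfg.alpha, cfg.beta, cfg.epsilon
    C, h, w = pred.shape
    total = 0.0
    for c in range(C):
        for i in range(h):
            for j in range(w):
                y = min(max(pred[c, i, j], eps), 1 - eps)
                t = target[c, i, j]
                if t == 1.0:
                    total += (1 - y) ** a * np.log(y)
                else:
                    total += (1 - t) ** b * y ** a * np.log(1 - y)
    return -total / (h * w)


def oracle_masked_l1(pred, target, mask):
    n, total = 0, 0.0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                n += 1
                for k in range(pred.shape[0]):
                    total += abs(pred[k, i, j] - target[k, i, j])
    return total / n if n else 0.0


def oracle_seg_loss(pred, target):
    total = 0.0
    for v, t in zip(pred.ravel(), target.ravel()):
        total += (v - t) ** 2
    return total / pred.size


# ---------------------------------------------------------------------------

class TestHandValues:
    def test_center_loss_single_cell(self):
        # Y=1, Ŷ=0.5, α=2: −(1−0.5)²·ln 0.5
        v = center_loss(np.array([[[0.5]]]), np.array([[[1.0]]]))
        assert v == pytest.approx(0.17329, abs=1e-5)

    def test_center_loss_near_perfect(self):
        cfg = LossConfig()
        pred = np.full((1, 4, 4), cfg.epsilon)
        target = np.zeros((1, 4, 4))
        target[0, 2, 2] = 1.0
        pred[0, 2, 2] = 1.0 - cfg.epsilon
        assert center_loss(pred, target, cfg) <= 1e-3

    def test_offset_loss_hand_value(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 1] = True
        target = np.zeros((2, 2, 2))
        target[:, 0, 1] = (0.25, 0.75)
        assert offset_loss(np.zeros((2, 2, 2)), target, mask) == 1.0

    def test_size_loss_hand_value(self):
        mask = np.zeros((1, 1), dtype=bool)
        mask[0, 0] = True
        pred = np.array([[[8.0]], [[15.0]]])
        target = np.array([[[10.0]], [[12.0]]])
        assert size_loss(pred, target, mask) == 5.0

    def test_seg_loss_hand_value(self):
        assert seg_loss(np.array([0.5, 0.5]), np.array([0.0, 1.0])) == 0.25

    def test_zero_object_losses_are_zero(self):
        mask = np.zeros((4, 4), dtype=bool)
        assert offset_loss(np.ones((2, 4, 4)), np.zeros((2, 4, 4)), mask) == 0.0
        assert size_loss(np.ones((2, 4, 4)), np.zeros((2, 4, 4)), mask) == 0.0

    def test_perfect_predictions_zero(self):
        mask = np.ones((2, 2), dtype=bool)
        x = np.random.default_rng(0).uniform(0, 1, (2, 2, 2))
        assert offset_loss(x, x, mask) == 0.0
        assert seg_loss(x, x) == 0.0


class TestIdentities:
    def test_det_loss_weighted_sum(self):
        b = total_loss(center=1.0, offset=3.0, size=2.0, seg=0.3)
        assert b.det == pytest.approx(1.0 + 0.1 * 2.0 + 1.0 * 3.0)
        assert b.det == 4.2

    def test_total_is_det_plus_seg(self):
        b = total_loss(center=1.0, offset=3.0, size=2.0, seg=0.3)
        assert b.total == b.det + b.seg == 4.5

    def test_all_zero(self):
        b = total_loss(0.0, 0.0, 0.0, 0.0)
        assert b.as_dict() == {k: 0.0 for k in b.as_dict()}

    def test_breakdown_identities_on_random_inputs(self, rng):
        for _ in range(10):
            vals = rng.uniform(0, 5, 4)
            b = total_loss(*vals)
            assert b.det == pytest.approx(b.center + 0.1 * b.size + b.offset)
            assert b.total == pytest.approx(b.det + b.seg)


class TestLoopOracles:
    def test_center_loss_matches_loop(self):
        cfg = LossConfig()
        rng = np.random.default_rng(11)
        for _ in range(50):
            pred = rng.uniform(0.01, 0.99, (3, 8, 8))
            target = np.round(rng.uniform(0, 1, (3, 8, 8)), 3)
            target[rng.uniform(size=(3, 8, 8)) < 0.05] = 1.0
            assert center_loss(pred, target, cfg) == pytest.approx(
                oracle_center_loss(pred, target, cfg), abs=1e-9)

    def test_masked_l1_losses_match_loop(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            pred = rng.uniform(-2, 2, (2, 6, 6))
            target = rng.uniform(-2, 2, (2, 6, 6))
            mask = rng.uniform(size=(6, 6)) < 0.3
            assert offset_loss(pred, target, mask) == pytest.approx(
                oracle_masked_l1(pred, target, mask), abs=1e-9)
            assert size_loss(pred, target, mask) == pytest.approx(
                oracle_masked_l1(pred, target, mask), abs=1e-9)

    def test_seg_loss_matches_loop(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            pred = rng.uniform(0, 1, (2, 5, 5))
            target = (rng.uniform(size=(2, 5, 5)) < 0.5).astype(float)
            assert seg_loss(pred, target) == pytest.approx(
                oracle_seg_loss(pred, target), abs=1e-9)

    def test_seg_loss_permutation_invariant(self, rng):
        pred = rng.uniform(0, 1, (2, 4, 4))
        target = (rng.uniform(size=(2, 4, 4)) < 0.5).astype(float)
        perm = rng.permutation(pred.size)
        assert seg_loss(pred, target) == pytest.approx(
            seg_loss(pred.ravel()[perm], target.ravel()[perm]), abs=1e-12)


class TestGradients:
    """Analytic gradients match central finite differences."""

    @staticmethod
    def _check(fn, x, analytic, h=1e-6, rtol=1e-4):
        flat = x.ravel()
        g = analytic.ravel()
        rng = np.random.default_rng(0)
        for idx in rng.choice(flat.size, size=min(20, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + h
            up = fn(x)
            flat[idx] = orig - h
            down = fn(x)
            flat[idx] = orig
            num = (up - down) / (2 * h)
            assert num == pytest.approx(g[idx], rel=rtol, abs=1e-7)

    def test_center_loss_gradient(self):
        cfg = LossConfig()
        rng = np.random.default_rng(21)
        pred = rng.uniform(0.05, 0.95, (2, 5, 5))
        target = np.zeros((2, 5, 5))
        target[0, 2, 2] = 1.0
        target[1, 1:4, 1:4] = 0.4
        _, grad = center_loss_grad(pred, target, cfg)
        self._check(lambda x: center_loss(x, target, cfg), pred, grad)

    def test_offset_loss_gradient(self):
        rng = np.random.default_rng(22)
        pred = rng.uniform(-1, 1, (2, 4, 4))
        target = rng.uniform(-1, 1, (2, 4, 4))
        mask = rng.uniform(size=(4, 4)) < 0.4
        _, grad = offset_loss_grad(pred, target, mask)
        self._check(lambda x: offset_loss(x, target, mask), pred, grad)

    def test_seg_loss_gradient(self):
        rng = np.random.default_rng(23)
        pred = rng.uniform(0, 1, (2, 4, 4))
        target = (rng.uniform(size=(2, 4, 4)) < 0.5).astype(float)
        _, grad = seg_loss_grad(pred, target)
        self._check(lambda x: seg_loss(x, target), pred, grad)


class TestContracts:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            center_loss(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))
        with pytest.raises(ValueError):
            seg_loss(np.zeros((2, 4, 4)), np.zeros((2, 5, 5)))

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            center_loss(np.full((1, 2, 2), 0.5), np.full((1, 2, 2), 1.5))

    def test_losses_nonnegative(self, rng):
        for _ in range(20):
            pred = rng.uniform(0.01, 0.99, (2, 6, 6))
            target = np.zeros((2, 6, 6))
            target[tuple(rng.integers(0, (2, 6, 6)))] = 1.0
            mask = rng.uniform(size=(6, 6)) < 0.3
            assert center_loss(pred, target) >= 0
            assert offset_loss(pred, target, mask) >= 0
            assert seg_loss(pred, (target > 0.5).astype(float)) >= 0

    def test_object_normalization_option(self):
        # two marked centers: object norm divides by 2 instead of h·w
        target = np.zeros((1, 4, 4))
        target[0, 0, 0] = target[0, 3, 3] = 1.0
        pred = np.full((1, 4, 4), 0.5)
        pix = center_loss(pred, target, LossConfig(center_loss_norm="pixels"))
        obj = center_loss(pred, target, LossConfig(center_loss_norm="objects"))
        assert obj == pytest.approx(pix * 16 / 2)
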