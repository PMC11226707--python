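"""IoU/CIoU geometry, target assignment and the composite loss."""

import math

import numpy as np
import pytest

from polypdet import nn as N
from polypdet.detector import ModelConfig, build_model
from polypdet.loss import (AssignmentMask, Box, LossConfig, assign_targets,
                           box_loss, ciou, iou, total_loss)


def _b(x1, y1, x2, y2):
    return Box("xyxy_px", (x1, y1, x2, y2))


class TestBox:
    def test_format_roundtrip_is_exact(self):
        b = Box("cxcywh_norm", (0.5, 0.25, 0.2, 0.1))
        back = b.to_xyxy(640).to_cxcywh_norm(640)
        assert np.allclose(back.coords, b.coords)

    def test_invalid_boxes_rejected(self):
        with pytest.raises(ValueError):
            Box("cxcywh_norm", (0.5, 0.5, 1.5, 0.1))
        with pytest.raises(ValueError):
            Box("xyxy_px", (10, 0, 5, 5))
        with pytest.raises(ValueError):
            Box("corner", (0, 0, 1, 1))


class TestIoU:
    def test_identical_boxes(self):
        assert iou(_b(0, 0, 2, 2), _b(0, 0, 2, 2)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(_b(0, 0, 1, 1), _b(5, 5, 6, 6)) == 0.0

    def test_hand_geometry_one_seventh(self):
        # intersection 1, union 4 + 4 - 1 = 7
        assert iou(_b(0, 0, 2, 2), _b(1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_symmetry_and_range(self, rng):
        for _ in range(50):
            a = np.sort(rng.uniform(0, 10, 4)).astype(float)
            b = np.sort(rng.uniform(0, 10, 4)).astype(float)
            ba, bb = _b(a[0], a[1], a[2], a[3]), _b(b[0], b[1], b[2], b[3])
            assert iou(ba, bb) == pytest.approx(iou(bb, ba))
            assert 0.0 <= iou(ba, bb) <= 1.0

    def test_zero_area_convention(self):
        assert iou(_b(1, 1, 1, 1), _b(0, 0, 2, 2)) == 0.0


class TestCIoU:
    def test_identical_boxes_give_one(self):
        assert ciou(_b(0, 0, 2, 2), _b(0, 0, 2, 2)) == pytest.approx(1.0)

    def test_hand_computation_two_sixty_thirds(self):
        # same aspect ratio -> v=0; d^2 = 2, enclosing diagonal^2 = 18
        assert ciou(_b(0, 0, 2, 2), _b(1, 1, 3, 3)) == pytest.approx(2 / 63)

    def test_never_exceeds_iou(self, rng):
        for _ in range(100):
            a = np.sort(rng.uniform(0, 10, 4))
            b = np.sort(rng.uniform(0, 10, 4))
            ba, bb = _b(*a), _b(*b)
            assert ciou(ba, bb) <= iou(ba, bb) + 1e-12

    def test_equals_iou_when_centered_and_same_aspect(self, rng):
        """d = 0 and v = 0 leave only the IoU term."""
        for _ in range(50):
            cx, cy = rng.uniform(2, 8, 2)
            w, h = rng.uniform(0.5, 3, 2)
            k = rng.uniform(0.3, 2.0)
            inner = _b(cx - w, cy - h, cx + w, cy + h)
            outer = _b(cx - k * w, cy - k * h, cx + k * w, cy + k * h)
            assert ciou(inner, outer) == pytest.approx(iou(inner, outer), abs=1e-9)

    def test_degenerate_aspect_uses_half_pi_convention(self):
        flat = _b(0, 0, 2, 0)            # zero height
        square = _b(0, 0, 2, 2)
        v = (4 / math.pi ** 2) * (math.atan(1.0) - math.pi / 2) ** 2
        got = ciou(square, flat)
        assert got == pytest.approx(0.0 - 1.0 / 8.0 - v * v / (1.0 + v), abs=1e-6)


class TestBoxLoss:
    def test_perfect_predictions_give_zero(self):
        boxes = [_b(0, 0, 4, 4), _b(2, 2, 5, 9)]
        assert box_loss(boxes, boxes) == pytest.approx(0.0)

    def test_single_pair_hand_value(self):
        # 1 - 2/63 = 61/63 at lambda 1
        assert box_loss([_b(0, 0, 2, 2)], [_b(1, 1, 3, 3)]) == pytest.approx(61 / 63)

    def test_lambda_scales_linearly(self):
        p, g = [_b(0, 0, 2, 2)], [_b(1, 1, 3, 3)]
        assert box_loss(p, g, 3.0) == pytest.approx(3 * box_loss(p, g, 1.0))


class TestAssignment:
    CFG = ModelConfig(input_size=64, width_multiple=0.125)

    def _assign(self, boxes, thr=4.0):
        cfg = self.CFG
        return assign_targets([boxes], [[0] * len(boxes)], cfg.anchors_per_scale(),
                              cfg.strides, cfg.input_size, ratio_threshold=thr)

    def test_anchor_shaped_gt_at_cell_center_is_assigned(self):
        cfg = self.CFG
        aw, ah = cfg.anchors_per_scale()[1, 1]       # mid-scale anchor, pixels
        gt = Box("cxcywh_norm", (0.5, 0.5, aw / 64, ah / 64))
        mask = self._assign([gt])
        img, anc, gy, gx = mask.indices[1]
        assert 1 in anc                              # its own anchor matched
        assert mask.total_assigned() >= 1

    def test_extreme_aspect_falls_back_to_best_anchor(self):
        gt = Box("cxcywh_norm", (0.5, 0.5, 0.9, 0.02))
        mask = self._assign([gt], thr=1.05)          # nothing passes the ratio test
        assert mask.total_assigned() == 1            # no orphan ground truths

    def test_counts_match_brute_force_rule(self, rng):
        """Re-derive the rule independently: for every (scale, anchor) with
        shape ratio < 4 the gt's cell and its two nearest neighbours are
        assigned (deduplicated), else one fallback."""
        cfg = self.CFG
        anchors = cfg.anchors_per_scale()
        for trial in range(20):
            n = int(rng.integers(1, 4))
            boxes = []
            for _ in range(n):
                w, h = rng.uniform(0.05, 0.4, 2)
                cx = rng.uniform(w / 2, 1 - w / 2)
                cy = rng.uniform(h / 2, 1 - h / 2)
                boxes.append(Box("cxcywh_norm", (cx, cy, w, h)))
            mask = self._assign(boxes)

            expected = [set(), set(), set()]
            for b in boxes:
                cx, cy, bw, bh = b.coords
                matched = False
                best = (np.inf, None, None)
                for s in range(3):
                    g = cfg.input_size / cfg.strides[s]
                    for a in range(3):
                        aw, ah = anchors[s, a]
                        wp, hp = bw * cfg.input_size, bh * cfg.input_size
                        r = max(wp / aw, aw / max(wp, 1e-9), hp / ah, ah / max(hp, 1e-9))
                        if r < best[0]:
                            best = (r, s, a)
                        if r < 4.0:
                            matched = True
                            gx_f, gy_f = cx * g, cy * g
                            gxi, gyi = int(gx_f), int(gy_f)
                            dx = 1 if gx_f - gxi > 0.5 else -1
                            dy = 1 if gy_f - gyi > 0.5 else -1
                            for (yy, xx) in ((gyi, gxi), (gyi, gxi + dx), (gyi + dy, gxi)):
                                if 0 <= yy < g and 0 <= xx < g:
                                    expected[s].add((a, min(max(yy, 0), int(g) - 1),
                                                     min(max(xx, 0), int(g) - 1)))
                if not matched:
                    _, s, a = best
                    g = cfg.input_size / cfg.strides[s]
                    expected[s].add((a, int(cy * g), int(cx * g)))
            for s in range(3):
                got = set(zip(*[arr.tolist() for arr in mask.indices[s][1:]])) \
                    if len(mask.indices[s][0]) else set()
                assert got == expected[s]


class TestTotalLoss:
    def _setup(self, rng, boxes):
        cfg = ModelConfig(input_size=64, width_multiple=0.125)
        model = build_model(cfg, seed=0)
        model.train()
        imgs = rng.random((1, 3, 64, 64)).astype(np.float32)
        mask = assign_targets([boxes], [[0] * len(boxes)], cfg.anchors_per_scale(),
                              cfg.strides, cfg.input_size)
        preds = model(N.Tensor(imgs))
        return cfg, preds, mask

    def test_additivity_of_components(self, rng):
        cfg, preds, mask = self._setup(rng, [Box("cxcywh_norm", (0.5, 0.5, 0.3, 0.3))])
        bd, _ = total_loss(preds, mask, LossConfig(), 1, cfg.input_size)
        assert bd.total == pytest.approx(bd.l_cls + bd.l_box + bd.l_obj, rel=1e-6)
        assert min(bd.l_cls, bd.l_box, bd.l_obj) >= 0.0

    def test_empty_image_trains_only_objectness(self, rng):
        cfg, preds, mask = self._setup(rng, [])
        bd, _ = total_loss(preds, mask, LossConfig(), 1, cfg.input_size)
        assert bd.l_box == 0.0
        assert bd.l_cls == 0.0
        assert bd.l_obj > 0.0

    def test_objectness_toward_negative_infinity_drives_total_to_zero(self, rng):
        cfg, preds, mask = self._setup(rng, [])
        for p in preds:
            p.values.data[..., 4] = -60.0      # sigmoid ~ 0 exactly in f32
        bd, _ = total_loss(preds, mask, LossConfig(), 1, cfg.input_size)
        assert bd.total == pytest.approx(0.0, abs=1e-6)

    def test_fifty_descent_steps_decrease_loss(self, rng):
        """Gradient sanity: full-batch descent on a 2-image fixture."""
        cfg = ModelConfig(input_size=64, width_multiple=0.125)
        model = build_model(cfg, seed=0)
        model.train()
        imgs = rng.random((2, 3, 64, 64)).astype(np.float32)
        boxes = [[Box("cxcywh_norm", (0.4, 0.5, 0.3, 0.25))],
                 [Box("cxcywh_norm", (0.6, 0.3, 0.2, 0.2))]]
        mask = assign_targets(boxes, [[0], [0]], cfg.anchors_per_scale(),
                              cfg.strides, cfg.input_size)
        opt = N.SGD(model.parameters(), lr=0.005, momentum=0.9)
        losses = []
        for step in range(50):
            preds = model(N.Tensor(imgs))
            bd, lt = total_loss(preds, mask, LossConfig(), 1, cfg.input_size)
            losses.append(bd.total)
            model.zero_grad()
            lt.backward()
            opt.step()
        assert losses[-1] < losses[0]
        # monotone on the smoothed trajectory: late average beats early average
        assert np.mean(losses[-10:]) < np.mean(losses[:10])
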