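"""Boxes, IoU/CIoU, anchor-target assignment and the composite training loss.

The objective is the sum of three terms — classification, box regression and
objectness — evaluated over anchor-assigned grid cells on all three scales:

    loss = L_cls + L_box + L_obj

L_box is ``lambda_coord * sum(1 - CIoU)`` over assigned (cell, anchor) pairs,
where CIoU augments IoU with a normalised centre-distance penalty d^2/c^2
(d = centre distance, c = diagonal of the smallest enclosing box) and an
aspect-ratio consistency penalty alpha*v with

    v = (4 / pi^2) * (atan(w_g / h_g) - atan(w / h))^2,
    alpha = v / ((1 - IoU) + v).

L_cls and L_obj are binary cross-entropies on sigmoid outputs; the
objectness regression target for an assigned pair is its CIoU clamped to
[0, 1] (a switch selects plain 0/1 targets).

Assignment follows the deterministic shape-ratio rule: a ground-truth box is
assigned to every anchor with max(w_g/w_a, w_a/w_g, h_g/h_a, h_a/h_g) below
the threshold (4.0) in its own cell and in the two nearest neighbour cells;
a ground truth matched by no anchor anywhere falls back to its best-ratio
anchor at its own cell, so no target is ever orphaned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .detector import ScalePrediction
from .nn import Tensor

__all__ = ["Box", "iou", "ciou", "box_loss", "total_loss", "assign_targets",
           "AssignmentMask", "LossBreakdown", "LossConfig"]


# ---------------------------------------------------------------------------
# boxes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """A bounding box with an explicit format tag.

    ``cxcywh_norm``: centre/size, all coordinates in [0, 1].
    ``xyxy_px``: corner coordinates in pixels, half-open [x1, x2) x [y1, y2).
    """

    format: str
    coords: tuple[float, float, float, float]

    def __post_init__(self):
        if self.format not in ("cxcywh_norm", "xyxy_px"):
            raise ValueError(f"unknown box format {self.format!r}")
        c = tuple(float(v) for v in self.coords)
        object.__setattr__(self, "coords", c)
        if self.format == "cxcywh_norm":
            if not all(0.0 <= v <= 1.0 for v in c):
                raise ValueError(f"normalized coords outside [0,1]: {c}")
        else:
            if c[0] > c[2] or c[1] > c[3]:
                raise ValueError(f"xyxy box with x1>x2 or y1>y2: {c}")

    @property
    def width(self) -> float:
        if self.format == "cxcywh_norm":
            return self.coords[2]
        return self.coords[2] - self.coords[0]

    @property
    def height(self) -> float:
        if self.format == "cxcywh_norm":
            return self.coords[3]
        return self.coords[3] - self.coords[1]

    def to_xyxy(self, image_size: float = 1.0) -> "Box":
        if self.format == "xyxy_px":
            return self
        cx, cy, w, h = self.coords
        return Box("xyxy_px", ((cx - w / 2) * image_size, (cy - h / 2) * image_size,
                               (cx + w / 2) * image_size, (cy + h / 2) * image_size))

    def to_cxcywh_norm(self, image_size: float) -> "Box":
        if self.format == "cxcywh_norm":
            return self
        x1, y1, x2, y2 = self.coords
        return Box("cxcywh_norm", (((x1 + x2) / 2) / image_size, ((y1 + y2) / 2) / image_size,
                                   (x2 - x1) / image_size, (y2 - y1) / image_size))


def _xyxy(b: Box) -> tuple[float, float, float, float]:
    return b.to_xyxy().coords


def iou(a: Box, b: Box) -> float:
    """Intersection over union; zero-area boxes give 0 by convention."""
    ax1, ay1, ax2, ay2 = _xyxy(a)
    bx1, by1, bx2, by2 = _xyxy(b)
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def _atan_ratio(w: float, h: float) -> float:
    """atan(w/h) with the degenerate convention atan(x/0) = pi/2."""
    if h == 0.0:
        return math.pi / 2 if w > 0 else 0.0
    return math.atan(w / h)


def ciou(pred: Box, gt: Box) -> float:
    """Complete IoU: IoU - d^2/c^2 - alpha*v.  In (-1, 1]; == IoU when the
    centres coincide and the aspect ratios match."""
    px1, py1, px2, py2 = _xyxy(pred)
    gx1, gy1, gx2, gy2 = _xyxy(gt)
    i = iou(pred, gt)
    # centre distance over enclosing diagonal
    d2 = (((px1 + px2) - (gx1 + gx2)) ** 2 + ((py1 + py2) - (gy1 + gy2)) ** 2) / 4.0
    cw = max(px2, gx2) - min(px1, gx1)
    ch = max(py2, gy2) - min(py1, gy1)
    c2 = cw ** 2 + ch ** 2
    dist = d2 / c2 if c2 > 0 else 0.0
    v = (4.0 / math.pi ** 2) * (_atan_ratio(gx2 - gx1, gy2 - gy1)
                                - _atan_ratio(px2 - px1, py2 - py1)) ** 2
    if v == 0.0:
        av = 0.0
    else:
        av = v * v / ((1.0 - i) + v)
    return i - dist - av


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentMask:
    """Per-scale target assignment.

    For scale s, ``indices[s]`` is a tuple of integer arrays
    (image, anchor, gy, gx) and ``targets[s]`` the matched ground-truth boxes
    as an (M, 4) array of normalized cxcywh, with ``classes[s]`` the class
    ids and ``anchor_wh[s]`` the matched anchor sizes in pixels.
    """

    indices: list[tuple[np.ndarray, ...]]
    targets: list[np.ndarray]
    classes: list[np.ndarray]
    anchor_wh: list[np.ndarray]

    def total_assigned(self) -> int:
        return sum(len(t) for t in self.targets)


def assign_targets(gt_boxes: list[list[Box]], gt_classes: list[list[int]],
                   anchors: np.ndarray, strides: tuple[int, ...], input_size: int,
                   ratio_threshold: float = 4.0) -> AssignmentMask:
    """Deterministic shape-ratio assignment with a 3-cell neighbourhood.

    ``gt_boxes`` is one list of normalized cxcywh boxes per image.  Boxes
    larger than the image are clipped before assignment.  Every ground truth
    is assigned at least once (fallback to its best-ratio anchor).
    """
    n_scales = len(strides)
    per_scale: list[dict] = [
        {"img": [], "anc": [], "gy": [], "gx": [], "tgt": [], "cls": [], "awh": []}
        for _ in range(n_scales)
    ]

    def push(s, im, a, gy, gx, box, cls_id):
        g = input_size / strides[s]
        gy = int(np.clip(gy, 0, g - 1))
        gx = int(np.clip(gx, 0, g - 1))
        key = (im, a, gy, gx)
        rec = per_scale[s]
        if key in rec.setdefault("_seen", set()):
            return
        rec["_seen"].add(key)
        rec["img"].append(im)
        rec["anc"].append(a)
        rec["gy"].append(gy)
        rec["gx"].append(gx)
        rec["tgt"].append(box)
        rec["cls"].append(cls_id)
        rec["awh"].append(anchors[s, a])

    for im, (boxes, classes) in enumerate(zip(gt_boxes, gt_classes)):
        for box, cls_id in zip(boxes, classes):
            cx, cy, bw, bh = box.to_cxcywh_norm(1.0).coords if box.format == "cxcywh_norm" \
                else box.to_cxcywh_norm(input_size).coords
            # clip oversized boxes to the image frame
            bw, bh = min(bw, 1.0), min(bh, 1.0)
            clipped = np.array([cx, cy, bw, bh], dtype=np.float32)
            best = None  # (ratio, scale, anchor)
            matched = False
            for s, stride in enumerate(strides):
                g = input_size / stride
                gx_f, gy_f = cx * g, cy * g
                w_px, h_px = bw * input_size, bh * input_size
                for a in range(anchors.shape[1]):
                    aw, ah = anchors[s, a]
                    r = max(w_px / aw, aw / max(w_px, 1e-9),
                            h_px / ah, ah / max(h_px, 1e-9))
                    if best is None or r < best[0]:
                        best = (r, s, a)
                    if r < ratio_threshold:
                        matched = True
                        cells = [(int(gy_f), int(gx_f))]
                        # the two nearest neighbour cells along x and y
                        dx = 1 if (gx_f - int(gx_f)) > 0.5 else -1
                        dy = 1 if (gy_f - int(gy_f)) > 0.5 else -1
                        cells.append((int(gy_f), int(gx_f) + dx))
                        cells.append((int(gy_f) + dy, int(gx_f)))
                        for gy, gx in cells:
                            if 0 <= gy < g and 0 <= gx < g:
                                push(s, im, a, gy, gx, clipped, cls_id)
            if not matched and best is not None:
                _, s, a = best
                g = input_size / strides[s]
                push(s, im, a, int(cy * g), int(cx * g), clipped, cls_id)

    indices, targets, classes_out, anchor_wh = [], [], [], []
    for rec in per_scale:
        indices.append((np.asarray(rec["img"], dtype=np.int64),
                        np.asarray(rec["anc"], dtype=np.int64),
                        np.asarray(rec["gy"], dtype=np.int64),
                        np.asarray(rec["gx"], dtype=np.int64)))
        targets.append(np.asarray(rec["tgt"], dtype=np.float32).reshape(-1, 4))
        classes_out.append(np.asarray(rec["cls"], dtype=np.int64))
        anchor_wh.append(np.asarray(rec["awh"], dtype=np.float32).reshape(-1, 2))
    return AssignmentMask(indices, targets, classes_out, anchor_wh)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossConfig:
    lambda_coord: float = 0.25
    obj_weight: float = 1.0
    cls_weight: float = 0.5
    per_scale_obj_balance: tuple[float, float, float] = (4.0, 1.0, 0.4)
    obj_target: str = "ciou"          # "ciou" | "binary"
    ratio_threshold: float = 4.0


@dataclass
class LossBreakdown:
    """The three components and their sum; total == l_cls + l_box + l_obj."""

    l_cls: float
    l_box: float
    l_obj: float
    total: float


def _ciou_tensor(px, py, pw, ph, tgt: np.ndarray) -> Tensor:
    """Differentiable CIoU between decoded predictions and fixed targets.

    All inputs are in normalized image units; ``tgt`` is (M, 4) cxcywh.
    """
    eps = 1e-9
    tx, ty, tw, th = tgt[:, 0], tgt[:, 1], tgt[:, 2], tgt[:, 3]
    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    gx1, gx2 = tx - tw * 0.5, tx + tw * 0.5
    gy1, gy2 = ty - th * 0.5, ty + th * 0.5
    iw = nn.clip(nn.minimum(px2, Tensor(gx2)) - nn.maximum(px1, Tensor(gx1)), 0.0, None)
    ih = nn.clip(nn.minimum(py2, Tensor(gy2)) - nn.maximum(py1, Tensor(gy1)), 0.0, None)
    inter = iw * ih
    union = pw * ph + Tensor(tw * th) - inter
    i = inter / (union + eps)
    d2 = (px - Tensor(tx)) ** 2 + (py - Tensor(ty)) ** 2
    cw = nn.maximum(px2, Tensor(gx2)) - nn.minimum(px1, Tensor(gx1))
    ch = nn.maximum(py2, Tensor(gy2)) - nn.minimum(py1, Tensor(gy1))
    c2 = cw ** 2 + ch ** 2 + eps
    v = nn.mul((nn.arctan(Tensor(tw / np.maximum(th, eps))) - nn.arctan(pw / (ph + eps))) ** 2,
               4.0 / math.pi ** 2)
    alpha = Tensor((v.data / ((1.0 - i.data) + v.data + eps)))   # treated as a constant weight
    return i - d2 / c2 - alpha * v


def total_loss(preds: list[ScalePrediction], mask: AssignmentMask,
               cfg: LossConfig, num_classes: int, input_size: int) -> LossBreakdown | tuple:
    """Composite objective over three scales; returns (breakdown, loss_tensor)."""
    n_img = preds[0].values.shape[0]
    l_box = Tensor(0.0)
    l_cls = Tensor(0.0)
    l_obj = Tensor(0.0)
    n_assigned = mask.total_assigned()

    for s, pred in enumerate(preds):
        v = pred.values                                   # (n, 3, gh, gw, 5+nc)
        img, anc, gy, gx = mask.indices[s]
        obj_target = np.zeros(v.shape[:4], dtype=np.float32)
        if len(img):
            tgt = mask.targets[s]
            awh = mask.anchor_wh[s]
            sel = nn.take(v, (img, anc, gy, gx))          # (M, 5+nc)
            sxy = nn.sigmoid(nn.take(sel, (slice(None), slice(0, 2))))
            swh = nn.sigmoid(nn.take(sel, (slice(None), slice(2, 4))))
            g = input_size / pred.stride
            # decoded centre in normalized units: (2*sig - 0.5 + cell) / grid
            px = (nn.take(sxy, (slice(None), 0)) * 2.0 - 0.5 + Tensor(gx.astype(np.float32))) / g
            py = (nn.take(sxy, (slice(None), 1)) * 2.0 - 0.5 + Tensor(gy.astype(np.float32))) / g
            pw = ((nn.take(swh, (slice(None), 0)) * 2.0) ** 2) * Tensor(awh[:, 0] / input_size)
            ph = ((nn.take(swh, (slice(None), 1)) * 2.0) ** 2) * Tensor(awh[:, 1] / input_size)
            ci = _ciou_tensor(px, py, pw, ph, tgt)
            l_box = l_box + nn.tsum(1.0 - ci) * (cfg.lambda_coord / max(n_assigned, 1))
            if cfg.obj_target == "ciou":
                score = np.clip(ci.data, 0.0, 1.0)
            else:
                score = np.ones(len(img), dtype=np.float32)
            obj_target[img, anc, gy, gx] = score
            if num_classes > 1:
                cls_logits = nn.take(sel, (slice(None), slice(5, 5 + num_classes)))
                cls_t = np.zeros((len(img), num_classes), dtype=np.float32)
                cls_t[np.arange(len(img)), mask.classes[s]] = 1.0
                l_cls = l_cls + nn.bce_with_logits(cls_logits, cls_t) * cfg.cls_weight
            else:
                cls_logits = nn.take(sel, (slice(None), slice(5, 6)))
                l_cls = l_cls + nn.bce_with_logits(
                    cls_logits, np.ones((len(img), 1), dtype=np.float32)) * cfg.cls_weight
        obj_logits = nn.take(v, (slice(None), slice(None), slice(None), slice(None), 4))
        l_obj = l_obj + nn.bce_with_logits(obj_logits, obj_target) \
            * (cfg.obj_weight * cfg.per_scale_obj_balance[s])

    total = l_box + l_cls + l_obj
    breakdown = LossBreakdown(l_cls=float(l_cls.data), l_box=float(l_box.data),
                              l_obj=float(l_obj.data), total=float(total.data))
    return breakdown, total


def box_loss(pred_boxes: list[Box], gt_boxes: list[Box], lambda_coord: float = 1.0) -> float:
    """``lambda_coord * sum(1 - CIoU)`` over already-matched pairs."""
    if len(pred_boxes) != len(gt_boxes):
        raise ValueError("box_loss expects matched pred/gt lists")
    return lambda_coord * sum(1.0 - ciou(p, g) for p, g in zip(pred_boxes, gt_boxes))
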