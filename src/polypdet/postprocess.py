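"""Decode head outputs into detections and score them.

Decoding follows the documented grid formula per (anchor a, cell gx, gy) at
stride s with anchor size (aw, ah):

    x = (2*sigmoid(tx) - 0.5 + gx) * s        w = (2*sigmoid(tw))**2 * aw
    y = (2*sigmoid(ty) - 0.5 + gy) * s        h = (2*sigmoid(th))**2 * ah

confidence = sigmoid(objectness) * sigmoid(best class score).  Greedy NMS
suppresses overlaps; evaluation pools TP/FP/FN and reports

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F = 2 * precision * recall / (precision + recall)

with the 0-denominator convention of 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import ScalePrediction
from .loss import Box, iou

__all__ = ["Detection", "MetricsReport", "decode", "nms", "match_and_score",
           "f_score", "average_precision"]


@dataclass(frozen=True)
class Detection:
    box: Box                      # xyxy_px, clipped to the image frame
    confidence: float
    class_id: int


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "MetricsReport":
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        return cls(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f_score=f_score(p, r))


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def decode(preds: list[ScalePrediction], anchors: np.ndarray, input_size: int,
           conf_threshold: float = 0.25, image_index: int = 0) -> list[Detection]:
    """Decode one image's raw predictions into pixel-frame detections."""
    if not (0.0 <= conf_threshold <= 1.0):
        raise ValueError("conf_threshold must lie in [0, 1]")
    out: list[Detection] = []
    for s_idx, pred in enumerate(preds):
        v = pred.values.data[image_index]          # (3, gh, gw, 5+nc)
        na, gh, gw, no = v.shape
        nc = no - 5
        sig = _sigmoid(v)
        obj = sig[..., 4]
        cls_scores = sig[..., 5:]
        best_cls = cls_scores.argmax(axis=-1)
        conf = obj * np.take_along_axis(cls_scores, best_cls[..., None], axis=-1)[..., 0]
        keep = np.argwhere(conf >= conf_threshold)
        for a, gy, gx in keep:
            sx, sy, sw, sh = sig[a, gy, gx, :4]
            cx = (2 * sx - 0.5 + gx) * pred.stride
            cy = (2 * sy - 0.5 + gy) * pred.stride
            aw, ah = anchors[s_idx, a]
            bw = (2 * sw) ** 2 * aw
            bh = (2 * sh) ** 2 * ah
            x1 = float(np.clip(cx - bw / 2, 0, input_size))
            y1 = float(np.clip(cy - bh / 2, 0, input_size))
            x2 = float(np.clip(cx + bw / 2, 0, input_size))
            y2 = float(np.clip(cy + bh / 2, 0, input_size))
            if x2 <= x1 or y2 <= y1:
                continue
            out.append(Detection(box=Box("xyxy_px", (x1, y1, x2, y2)),
                                 confidence=float(conf[a, gy, gx]),
                                 class_id=int(best_cls[a, gy, gx])))
    return out


def nms(dets: list[Detection], iou_threshold: float = 0.45) -> list[Detection]:
    """Greedy descending-confidence suppression; confidence-then-area tie-break."""
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must lie in (0, 1)")
    order = sorted(dets, key=lambda d: (-d.confidence,
                                        -(d.box.width * d.box.height)))
    kept: list[Detection] = []
    for d in order:
        if all(d.class_id != k.class_id or iou(d.box, k.box) <= iou_threshold
               for k in kept):
            kept.append(d)
    return kept


def match_and_score(dets: list[Detection], gts: list[Box],
                    match_iou: float = 0.5) -> MetricsReport:
    """Greedy one-to-one matching of detections (confidence-descending) to
    ground truths; a detection matching no unclaimed gt at IoU >= match_iou
    is a false positive, an unclaimed gt a false negative."""
    order = sorted(dets, key=lambda d: -d.confidence)
    claimed = [False] * len(gts)
    tp = 0
    for d in order:
        best_j, best_iou = -1, match_iou
        for j, g in enumerate(gts):
            if claimed[j]:
                continue
            i = iou(d.box, g)
            if i >= best_iou:
                best_j, best_iou = j, i
        if best_j >= 0:
            claimed[best_j] = True
            tp += 1
    fp = len(dets) - tp
    fn = len(gts) - tp
    return MetricsReport.from_counts(tp, fp, fn)


def average_precision(per_image: list[tuple[list[Detection], list[Box]]],
                      match_iou: float = 0.5) -> float:
    """AP@match_iou over a set of images (11-point-free, trapezoid on the
    monotonised precision envelope).  Used only for model selection."""
    records = []          # (confidence, is_tp)
    n_gt = 0
    for dets, gts in per_image:
        n_gt += len(gts)
        claimed = [False] * len(gts)
        for d in sorted(dets, key=lambda d: -d.confidence):
            best_j, best_iou = -1, match_iou
            for j, g in enumerate(gts):
                if not claimed[j]:
                    i = iou(d.box, g)
                    if i >= best_iou:
                        best_j, best_iou = j, i
            if best_j >= 0:
                claimed[best_j] = True
                records.append((d.confidence, 1))
            else:
                records.append((d.confidence, 0))
    if not records or n_gt == 0:
        return 0.0
    records.sort(key=lambda r: -r[0])
    tps = np.cumsum([r[1] for r in records])
    fps = np.cumsum([1 - r[1] for r in records])
    recall = tps / n_gt
    precision = tps / np.maximum(tps + fps, 1)
    # precision envelope
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    return float(np.trapezoid(precision, recall))
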