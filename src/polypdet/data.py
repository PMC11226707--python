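"""Dataset I/O, adaptive letterbox scaling, Mosaic augmentation and
kmeans++ anchor estimation.

Labels are one text file per image with rows ``class cx cy w h`` in
normalized centre format.  Pixel frames are 0-based with half-open boxes
[x1, x2) x [y1, y2); no operation ever produces a normalized coordinate
outside [0, 1] or a negative box dimension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .loss import Box, iou

__all__ = ["LabeledImage", "AnchorSet", "MosaicSpec", "read_dataset",
           "read_label_file", "write_label_file", "letterbox", "mosaic",
           "kmeans_anchors", "split_dataset"]

log = logging.getLogger("polypdet")

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass
class LabeledImage:
    """An RGB image with its normalized ground-truth boxes."""

    image: np.ndarray                 # (H, W, 3) uint8
    boxes: list[Box]
    class_ids: list[int]
    source_id: str = ""
    letterbox_params: tuple | None = None   # (scale, pad_x, pad_y) when letterboxed

    def __post_init__(self):
        if len(self.boxes) != len(self.class_ids):
            raise ValueError("boxes and class_ids must have equal length")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


@dataclass(frozen=True)
class AnchorSet:
    """Nine (w, h) pixel pairs sorted ascending by area, three per stride."""

    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.pairs) != 9:
            raise ValueError("an anchor set holds nine (w, h) pairs")
        pairs = tuple((float(w), float(h)) for w, h in self.pairs)
        if any(w <= 0 or h <= 0 for w, h in pairs):
            raise ValueError("anchor sizes must be positive")
        areas = [w * h for w, h in pairs]
        if areas != sorted(areas):
            pairs = tuple(sorted(pairs, key=lambda p: p[0] * p[1]))
        object.__setattr__(self, "pairs", pairs)

    def grouped(self) -> np.ndarray:
        """(3, 3, 2) array grouped per stride, small anchors first."""
        return np.asarray(self.pairs, dtype=np.float32).reshape(3, 3, 2)


@dataclass(frozen=True)
class MosaicSpec:
    """Geometric ranges for four-image Mosaic composition.

    The canvas is twice the training size; a jittered centre partitions it
    into four quadrants, one transformed source per quadrant.
    """

    canvas: int
    center_jitter: float = 0.25
    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.5, 1.5)
    shear_deg: float = 2.0
    min_visibility: float = 0.2
    min_side_px: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.center_jitter <= 0.25):
            raise ValueError("center_jitter must keep the centre in the middle half")


# ---------------------------------------------------------------------------
# label I/O
# ---------------------------------------------------------------------------

def read_label_file(path: Path) -> tuple[list[Box], list[int]]:
    boxes: list[Box] = []
    classes: list[int] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 'class cx cy w h', got {line!r}")
        try:
            cls_id = int(parts[0])
            vals = [float(p) for p in parts[1:]]
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: malformed number in {line!r}") from e
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError(f"{path}:{lineno}: coordinate outside [0,1]: {vals}")
        boxes.append(Box("cxcywh_norm", tuple(vals)))
        classes.append(cls_id)
    return boxes, classes


def write_label_file(path: Path, boxes: list[Box], class_ids: list[int],
                     confidences: list[float] | None = None) -> None:
    lines = []
    for i, (b, c) in enumerate(zip(boxes, class_ids)):
        cx, cy, w, h = b.to_cxcywh_norm(1.0).coords if b.format == "cxcywh_norm" else b.coords
        row = f"{c} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
        if confidences is not None:
            row += f" {confidences[i]:.6f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_dataset(image_dir: Path, label_dir: Path) -> list[LabeledImage]:
    """Load every image with its label file; a missing label file yields an
    empty box list with a logged warning."""
    image_dir, label_dir = Path(image_dir), Path(label_dir)
    items: list[LabeledImage] = []
    for img_path in sorted(p for p in image_dir.iterdir()
                           if p.suffix.lower() in IMAGE_SUFFIXES):
        label_path = label_dir / (img_path.stem + ".txt")
        if label_path.exists():
            boxes, classes = read_label_file(label_path)
        else:
            log.warning("no label file for %s; treating as background-only", img_path.name)
            boxes, classes = [], []
        image = np.asarray(Image.open(img_path).convert("RGB"))
        items.append(LabeledImage(image=image, boxes=boxes, class_ids=classes,
                                  source_id=img_path.stem))
    return items


# ---------------------------------------------------------------------------
# letterbox
# ---------------------------------------------------------------------------

def letterbox(item: LabeledImage, target: int, pad_value: int = 114) -> LabeledImage:
    """Aspect-preserving resize with symmetric gray padding to target x target.

    The applied (scale, pad_x, pad_y) is stored on the result so detections
    can be mapped back to the source frame.
    """
    if target % 32:
        raise ValueError("letterbox target must be a multiple of 32")
    h, w = item.image.shape[:2]
    scale = min(target / h, target / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    resized = np.asarray(Image.fromarray(item.image).resize((nw, nh), Image.BILINEAR)) \
        if (nh, nw) != (h, w) else item.image
    pad_y, pad_x = (target - nh) // 2, (target - nw) // 2
    canvas = np.full((target, target, 3), pad_value, dtype=np.uint8)
    canvas[pad_y: pad_y + nh, pad_x: pad_x + nw] = resized

    boxes = []
    for b in item.boxes:
        cx, cy, bw, bh = b.coords
        boxes.append(Box("cxcywh_norm", (
            (cx * nw + pad_x) / target, (cy * nh + pad_y) / target,
            bw * nw / target, bh * nh / target)))
    return LabeledImage(image=canvas, boxes=boxes, class_ids=list(item.class_ids),
                        source_id=item.source_id,
                        letterbox_params=(scale, float(pad_x), float(pad_y)))


def unletterbox_box(box_px: tuple[float, float, float, float],
                    params: tuple, source_hw: tuple[int, int]) -> tuple[float, ...]:
    """Map an xyxy pixel box from the letterboxed frame back to the source."""
    scale, pad_x, pad_y = params
    h, w = source_hw
    x1 = np.clip((box_px[0] - pad_x) / scale, 0, w)
    y1 = np.clip((box_px[1] - pad_y) / scale, 0, h)
    x2 = np.clip((box_px[2] - pad_x) / scale, 0, w)
    y2 = np.clip((box_px[3] - pad_y) / scale, 0, h)
    return (float(x1), float(y1), float(x2), float(y2))


# ---------------------------------------------------------------------------
# mosaic
# ---------------------------------------------------------------------------

def _affine_matrix(angle_deg: float, scale: float, shear_deg: float,
                   center: tuple[float, float]) -> np.ndarray:
    """Rotation+scale+shear about ``center``, as a 3x3 forward matrix."""
    a = math.radians(angle_deg)
    sh = math.tan(math.radians(shear_deg))
    cx, cy = center
    rot = np.array([[math.cos(a) * scale, -math.sin(a) * scale, 0],
                    [math.sin(a) * scale, math.cos(a) * scale, 0],
                    [0, 0, 1]])
    shear = np.array([[1, sh, 0], [0, 1, 0], [0, 0, 1]])
    t_neg = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]])
    t_pos = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]])
    return t_pos @ shear @ rot @ t_neg


def _warp_into(canvas: np.ndarray, img: np.ndarray, mat: np.ndarray,
               region: tuple[int, int, int, int]) -> None:
    """Inverse-map ``region`` of the canvas through ``mat`` into ``img``."""
    x1, y1, x2, y2 = region
    inv = np.linalg.inv(mat)
    ys, xs = np.mgrid[y1:y2, x1:x2]
    coords = np.stack([xs.ravel(), ys.ravel(), np.ones(xs.size)])
    src = inv @ coords
    sx = np.round(src[0]).astype(int)
    sy = np.round(src[1]).astype(int)
    valid = (sx >= 0) & (sx < img.shape[1]) & (sy >= 0) & (sy < img.shape[0])
    out = canvas[y1:y2, x1:x2].reshape(-1, 3)
    out[valid] = img[sy[valid], sx[valid]]
    canvas[y1:y2, x1:x2] = out.reshape(y2 - y1, x2 - x1, 3)


def mosaic(four: list[LabeledImage], spec: MosaicSpec) -> LabeledImage:
    """Compose four rotated/scaled/sheared images around a jittered centre.

    Boxes are transformed with their images, clipped to the visible quadrant,
    and dropped when the clipped area falls below ``min_visibility`` of the
    transformed box or either side drops under ``min_side_px``.  Deterministic
    given ``rng_seed``.
    """
    if len(four) != 4:
        raise ValueError(f"mosaic requires exactly four images, got {len(four)}")
    rng = np.random.default_rng(spec.rng_seed)
    s = spec.canvas
    jx = rng.uniform(-spec.center_jitter, spec.center_jitter)
    jy = rng.uniform(-spec.center_jitter, spec.center_jitter)
    mx = int(round(s * (0.5 + jx)))
    my = int(round(s * (0.5 + jy)))
    canvas = np.full((s, s, 3), 114, dtype=np.uint8)
    regions = [(0, 0, mx, my), (mx, 0, s, my), (0, my, mx, s), (mx, my, s, s)]
    # quadrant anchor corners: each source is placed so its centre sits at the
    # mosaic centre corner of its quadrant before the geometric transform
    out_boxes: list[Box] = []
    out_classes: list[int] = []
    for item, region in zip(four, regions):
        x1, y1, x2, y2 = region
        h, w = item.image.shape[:2]
        angle = rng.uniform(-spec.rotation_deg, spec.rotation_deg)
        scale = rng.uniform(*spec.scale_range)
        shear = rng.uniform(-spec.shear_deg, spec.shear_deg)
        # translation placing the image centre at the quadrant centre
        qcx, qcy = (x1 + x2) / 2, (y1 + y2) / 2
        base = np.array([[1, 0, qcx - w / 2], [0, 1, qcy - h / 2], [0, 0, 1]])
        mat = _affine_matrix(angle, scale, shear, (qcx, qcy)) @ base
        _warp_into(canvas, item.image, mat, region)
        for b, c in zip(item.boxes, item.class_ids):
            bx = b.to_xyxy(1.0).coords
            corners = np.array([
                [bx[0] * w, bx[1] * h, 1], [bx[2] * w, bx[1] * h, 1],
                [bx[0] * w, bx[3] * h, 1], [bx[2] * w, bx[3] * h, 1]]).T
            warped = mat @ corners
            wx1, wy1 = warped[0].min(), warped[1].min()
            wx2, wy2 = warped[0].max(), warped[1].max()
            full_area = max((wx2 - wx1) * (wy2 - wy1), 1e-9)
            cx1, cy1 = max(wx1, x1), max(wy1, y1)
            cx2, cy2 = min(wx2, x2), min(wy2, y2)
            if cx2 - cx1 < spec.min_side_px or cy2 - cy1 < spec.min_side_px:
                continue
            if (cx2 - cx1) * (cy2 - cy1) / full_area < spec.min_visibility:
                continue
            out_boxes.append(Box("cxcywh_norm", (
                ((cx1 + cx2) / 2) / s, ((cy1 + cy2) / 2) / s,
                (cx2 - cx1) / s, (cy2 - cy1) / s)))
            out_classes.append(c)
    return LabeledImage(image=canvas, boxes=out_boxes, class_ids=out_classes,
                        source_id="mosaic")


# ---------------------------------------------------------------------------
# kmeans++ anchors
# ---------------------------------------------------------------------------

def _wh_iou_matrix(wh: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """IoU of (w, h) pairs anchored at a common corner: (N, K)."""
    inter = np.minimum(wh[:, None, 0], centers[None, :, 0]) * \
        np.minimum(wh[:, None, 1], centers[None, :, 1])
    union = wh[:, 0:1] * wh[:, 1:2] + (centers[:, 0] * centers[:, 1])[None, :] - inter
    return inter / np.maximum(union, 1e-12)


def kmeans_anchors(wh: np.ndarray | list, k: int = 9, seed: int = 0,
                   iters: int = 100, metric: str = "iou") -> AnchorSet | np.ndarray:
    """kmeans++ seeding then Lloyd iterations under the 1 - IoU(w, h) distance.

    ``metric='euclidean'`` switches to squared-Euclidean distance.  Returns an
    :class:`AnchorSet` when k == 9, else the raw (k, 2) centers sorted by area.
    """
    wh = np.asarray(wh, dtype=np.float64).reshape(-1, 2)
    if len(wh) < k:
        raise ValueError(
            f"need at least {k} boxes to fit {k} anchors (got {len(wh)}); "
            "fall back to the default anchor set")
    rng = np.random.default_rng(seed)

    def dist(points, centers):
        if metric == "iou":
            return 1.0 - _wh_iou_matrix(points, centers)
        d = points[:, None, :] - centers[None, :, :]
        return (d ** 2).sum(-1)

    # kmeans++ seeding
    centers = [wh[rng.integers(len(wh))]]
    for _ in range(1, k):
        d2 = dist(wh, np.asarray(centers)).min(axis=1) ** 2
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(len(wh), 1 / len(wh))
        centers.append(wh[rng.choice(len(wh), p=probs)])
    centers = np.asarray(centers)

    for _ in range(iters):
        assign = dist(wh, centers).argmin(axis=1)
        new = centers.copy()
        for j in range(k):
            pts = wh[assign == j]
            if len(pts):
                new[j] = pts.mean(axis=0)
        if np.allclose(new, centers):
            break
        centers = new

    centers = centers[np.argsort(centers.prod(axis=1))]
    if k == 9:
        return AnchorSet(tuple(map(tuple, centers)))
    return centers


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_dataset(ids: list[str], seed: int,
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)) -> dict:
    """Deterministic seeded 8:1:1 shuffle-split into train/val/test.

    Sizes are floor(n * fraction) for val and test with the remainder going
    to train, so n=20 gives 16/2/2.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    ids = sorted(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_val = int(len(ids) * fractions[1])
    n_test = int(len(ids) * fractions[2])
    n_train = len(ids) - n_val - n_test
    shuffled = [ids[i] for i in order]
    return {"train": sorted(shuffled[:n_train]),
            "val": sorted(shuffled[n_train:n_train + n_val]),
            "test": sorted(shuffled[n_train + n_val:])}
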