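"""Training loop, checkpointing and split evaluation.

Optimisation is stochastic gradient descent with momentum 0.9 from an
initial learning rate of 0.01, batch size 16, with a 3-epoch linear warmup
followed by cosine decay (training-length defaults mirror the reference
protocol of 200 epochs; the smoke configurations use far fewer).  Each epoch
appends a JSON line with the loss breakdown and, at the evaluation interval,
pooled precision/recall/F on the validation split; the best checkpoint by
validation F-score is retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .data import LabeledImage, MosaicSpec, letterbox, mosaic, read_dataset, \
    unletterbox_box
from .detector import DetectorModel, ModelConfig, build_model
from .loss import LossConfig, assign_targets, total_loss
from .postprocess import Detection, MetricsReport, decode, match_and_score, nms
from .loss import Box

__all__ = ["TrainConfig", "train", "evaluate", "detect_image",
           "save_checkpoint", "load_checkpoint", "load_dataset_yaml"]

log = logging.getLogger("polypdet")


@dataclass
class TrainConfig:
    optimizer: str = "sgd"
    lr0: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 16
    epochs: int = 200
    warmup_epochs: int = 3
    final_lr_fraction: float = 0.01
    seed: int = 0
    mosaic: bool = False
    eval_interval: int = 10
    device: str = "cpu"
    # fraction of training after which batch-norm statistics are pinned to
    # exact training-set moments and frozen; None disables
    bn_freeze_fraction: float | None = 0.8
    clip_grad_norm: float | None = 10.0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.optimizer != "sgd":
            raise ValueError("config key 'optimizer': only 'sgd' is supported")
        if isinstance(self.loss, dict):
            self.loss = LossConfig(**self.loss)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        d = yaml.safe_load(text) or {}
        d = d.get("train", d)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown train config keys: {sorted(bad)}")
        return cls(**d)


def load_dataset_yaml(path: Path) -> dict:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("path", "images_dir", "labels_dir", "splits"):
        if key not in d:
            raise ValueError(f"dataset yaml missing key {key!r}")
    return d


def load_split(dataset: dict, split: str) -> list[LabeledImage]:
    root = Path(dataset["path"])
    items = read_dataset(root / dataset["images_dir"], root / dataset["labels_dir"])
    wanted = set(dataset["splits"][split])
    return [it for it in items if it.source_id in wanted]


def _lr_at(epoch: int, cfg: TrainConfig) -> float:
    if epoch < cfg.warmup_epochs:
        return cfg.lr0 * (epoch + 1) / cfg.warmup_epochs
    span = max(cfg.epochs - cfg.warmup_epochs, 1)
    t = (epoch - cfg.warmup_epochs) / span
    lo = cfg.lr0 * cfg.final_lr_fraction
    return lo + 0.5 * (cfg.lr0 - lo) * (1 + math.cos(math.pi * t))


def _prepare_batches(items: list[LabeledImage], model_cfg: ModelConfig,
                     train_cfg: TrainConfig):
    """Letterbox, normalize and pre-assign targets for fixed seeded batches."""
    rng = np.random.default_rng(train_cfg.seed)
    order = rng.permutation(len(items))
    batches = []
    bs = train_cfg.batch_size
    anchors = model_cfg.anchors_per_scale()
    for start in range(0, len(items), bs):
        chunk = [items[i] for i in order[start:start + bs]]
        boxed = [letterbox(it, model_cfg.input_size) for it in chunk]
        images = np.stack([b.image for b in boxed]).astype(np.float32) / 255.0
        images = images.transpose(0, 3, 1, 2)
        mask = assign_targets([b.boxes for b in boxed],
                              [b.class_ids for b in boxed],
                              anchors, model_cfg.strides, model_cfg.input_size,
                              ratio_threshold=train_cfg.loss.ratio_threshold)
        batches.append((images, mask))
    return batches


def expand_with_mosaic(items: list[LabeledImage], n_new: int, input_size: int,
                       seed: int) -> list[LabeledImage]:
    """Offline Mosaic expansion: append ``n_new`` composed scenes."""
    rng = np.random.default_rng(seed)
    out = list(items)
    for i in range(n_new):
        four = [items[j] for j in rng.choice(len(items), 4, replace=len(items) < 4)]
        spec = MosaicSpec(canvas=2 * input_size, rng_seed=int(rng.integers(2 ** 31)))
        out.append(mosaic(four, spec))
    return out


def recalibrate_bn(model: DetectorModel, batches) -> None:
    """Replace batch-norm running statistics with exact training-set moments.

    Optional utility for very small batch sizes, where incremental running
    averages can drift far from the statistics the final weights were trained
    under; not invoked by default.
    """
    from .nn import BatchNorm2d
    images = np.concatenate([b[0] for b in batches])
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    model.train()
    model(nn.Tensor(images))
    for bn, mom in zip(bns, saved):
        bn.momentum = mom
    model.eval()


def train(model: DetectorModel, train_items: list[LabeledImage],
          val_items: list[LabeledImage], cfg: TrainConfig,
          log_path: Path | None = None,
          checkpoint_path: Path | None = None) -> dict:
    """Run the optimisation; returns a summary with the best epoch/F-score."""
    model_cfg = model.cfg
    if cfg.mosaic and len(train_items) >= 4:
        train_items = expand_with_mosaic(train_items, len(train_items),
                                         model_cfg.input_size, cfg.seed)
    batches = _prepare_batches(train_items, model_cfg, cfg)
    opt = nn.SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay, clip_norm=cfg.clip_grad_norm)
    run_meta = {
        "config_hash": hashlib.sha256(
            (model_cfg.to_yaml() + json.dumps(asdict(cfg), sort_keys=True, default=str))
            .encode()).hexdigest()[:16],
        "seed": cfg.seed,
        "n_train": len(train_items),
        "n_val": len(val_items),
        "switches": {"stem": model_cfg.stem, "activation": model_cfg.activation,
                     "cam_strict_gate": model_cfg.cam_strict_gate,
                     "obj_target": cfg.loss.obj_target, "mosaic": cfg.mosaic},
    }
    lines = [json.dumps({"event": "start", **run_meta})]
    best = {"epoch": -1, "f_score": -1.0}
    model.train()
    freeze_at = None if cfg.bn_freeze_fraction is None else \
        int(cfg.bn_freeze_fraction * cfg.epochs)
    for epoch in range(cfg.epochs):
        if freeze_at is not None and epoch == freeze_at:
            recalibrate_bn(model, batches)
            for m in model.modules():
                if isinstance(m, nn.BatchNorm2d):
                    m.frozen = True
            model.train()
        opt.lr = _lr_at(epoch, cfg)
        sums = {"l_cls": 0.0, "l_box": 0.0, "l_obj": 0.0, "total": 0.0}
        for images, mask in batches:
            model.zero_grad()
            preds = model(nn.Tensor(images))
            breakdown, loss_t = total_loss(preds, mask, cfg.loss,
                                           model_cfg.num_classes, model_cfg.input_size)
            # gradients scale with batch size (the per-scale terms are means)
            loss_t = loss_t * float(len(images))
            loss_t.backward()
            opt.step()
            for k in sums:
                sums[k] += getattr(breakdown, k)
        rec = {"epoch": epoch, "lr": round(opt.lr, 6),
               **{k: round(v / len(batches), 6) for k, v in sums.items()}}
        run_eval = val_items and (epoch % cfg.eval_interval == cfg.eval_interval - 1
                                  or epoch == cfg.epochs - 1)
        if run_eval:
            report = evaluate(model, val_items)
            rec["val"] = {"precision": round(report.precision, 4),
                          "recall": round(report.recall, 4),
                          "f_score": round(report.f_score, 4)}
            model.train()
            if report.f_score > best["f_score"]:
                best = {"epoch": epoch, "f_score": report.f_score}
                if checkpoint_path is not None:
                    save_checkpoint(checkpoint_path, model)
        lines.append(json.dumps(rec))
        if log_path is not None:
            Path(log_path).write_text("\n".join(lines) + "\n")
    if checkpoint_path is not None and best["epoch"] < 0:
        save_checkpoint(checkpoint_path, model)
    model.eval()
    return {"best": best, "meta": run_meta, "final_loss": rec.get("total", None)}


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def detect_image(model: DetectorModel, item: LabeledImage, conf: float = 0.25,
                 iou_threshold: float = 0.45) -> list[Detection]:
    """Letterbox -> forward -> decode -> NMS -> map back to the source frame."""
    model.eval()
    cfg = model.cfg
    boxed = letterbox(item, cfg.input_size)
    images = boxed.image.astype(np.float32)[None].transpose(0, 3, 1, 2) / 255.0
    preds = model(nn.Tensor(images))
    dets = decode(preds, cfg.anchors_per_scale(), cfg.input_size, conf_threshold=conf)
    dets = nms(dets, iou_threshold)
    out = []
    for d in dets:
        coords = unletterbox_box(d.box.coords, boxed.letterbox_params,
                                 (item.height, item.width))
        if coords[2] <= coords[0] or coords[3] <= coords[1]:
            continue
        out.append(Detection(box=Box("xyxy_px", coords), confidence=d.confidence,
                             class_id=d.class_id))
    return out


def evaluate(model: DetectorModel, items: list[LabeledImage], conf: float = 0.25,
             iou_threshold: float = 0.45, match_iou: float = 0.5) -> MetricsReport:
    """Pool TP/FP/FN over the split, then compute precision/recall/F once."""
    if not items:
        raise ValueError("cannot evaluate an empty split")
    tp = fp = fn = 0
    for item in items:
        dets = detect_image(model, item, conf=conf, iou_threshold=iou_threshold)
        # normalized boxes scale by width on x and height on y
        gts = []
        for b in item.boxes:
            cx, cy, w, h = b.coords
            gts.append(Box("xyxy_px", ((cx - w / 2) * item.width,
                                       (cy - h / 2) * item.height,
                                       (cx + w / 2) * item.width,
                                       (cy + h / 2) * item.height)))
        rep = match_and_score(dets, gts, match_iou=match_iou)
        tp += rep.tp
        fp += rep.fp
        fn += rep.fn
    return MetricsReport.from_counts(tp, fp, fn)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: Path, model: DetectorModel) -> None:
    arrays = model.state_arrays()
    np.savez_compressed(path, __config__=np.array(model.cfg.to_yaml()), **arrays)


def load_checkpoint(path: Path) -> DetectorModel:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig.from_yaml(str(data["__config__"]))
        model = build_model(cfg, seed=0)
        arrays = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_arrays(arrays)
    model.eval()
    return model
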