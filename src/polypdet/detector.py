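"""Detector assembly: CSP-Darknet-style backbone, PAN neck, three heads.

The backbone runs stem -> CBL -> C3 stages at strides 4/8/16/32 with SPPF on
the deepest map, optionally followed by context feature augmentation (CFA)
and a coordinate-attention block.  The neck is a path aggregation network:
top-down upsampling with lateral concatenations, then bottom-up strided
convolutions; coordinate attention can gate each concatenation output.
Three 1x1 convolutions emit ``3 * (5 + num_classes)`` channels per scale.

``ablation_config`` returns the four calibrated configurations whose
trainable-parameter counts the package documents (baseline, +CFA, +CFA+CAM,
full with P-C3); ``symbolic_parameter_count`` is the closed-form count used
to cross-check the enumerated one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from . import nn
from .attention import CAMConfig, CoordinateAttention, cam_parameter_count
from .blocks import (C3, ConvBNAct, ConvSpec, Focus, SPPF, StemConv,
                     conv_bn_act_params)
from .cfa import CFA, CFAConfig, cfa_parameter_count
from .nn import Module, Tensor

__all__ = ["ModelConfig", "ScalePrediction", "DetectorModel", "build_model",
           "count_parameters", "symbolic_parameter_count", "ablation_config",
           "DEFAULT_ANCHORS"]

# anchor (w, h) priors in pixels at a 640 input, three per stride
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (10, 13), (16, 30), (33, 23),
    (30, 61), (62, 45), (59, 119),
    (116, 90), (156, 198), (373, 326),
)


def _make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(round(x / divisor) * divisor))


@dataclass
class ModelConfig:
    """All architecture hyperparameters, YAML-serialisable.

    ``width_multiple`` scales the base channel widths (64..1024),
    ``depth_multiple`` the base stage depths (3, 6, 9, 3).  The switches
    mirror the ablation groups: ``use_cfa``, ``use_cam`` and ``use_pc3``
    (P-C3 in the backbone stages); ``pc3_neck`` additionally converts the
    neck C3 blocks (off in the calibrated configuration).
    """

    num_classes: int = 1
    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    input_size: int = 640
    anchors: tuple = DEFAULT_ANCHORS
    strides: tuple = (8, 16, 32)
    activation: str = "silu"
    stem: str = "focus"                     # "focus" | "conv6" (equal parameter counts)
    use_cfa: bool = False
    use_cam: bool = False
    use_pc3: bool = False
    pc3_neck: bool = False
    cam_reduction: int = 16
    cam_strict_gate: bool = False
    # "fusion": after CFA + on the four PAN concat outputs (calibrated);
    # "heads": after CFA + on each PAN output before its head
    cam_placement: str = "fusion"
    cfa_reduce: int | None = None           # None -> channels // 4
    cfa_conv_mode: str = "cbl"
    cfa_reduce_mode: str = "cbl"
    cfa_fuse_mode: str = "cbl"

    def __post_init__(self):
        if self.input_size % max(self.strides) != 0:
            raise ValueError("input_size must be divisible by the largest stride")
        if len(self.anchors) != 3 * len(self.strides):
            raise ValueError("anchors must come three per stride")
        if self.stem not in ("focus", "conv6"):
            raise ValueError("stem must be 'focus' or 'conv6'")
        if self.cam_placement not in ("fusion", "heads"):
            raise ValueError("cam_placement must be 'fusion' or 'heads'")
        if tuple(self.anchors) == DEFAULT_ANCHORS and self.input_size != 640:
            # the default priors are stated at a 640 input; keep them
            # proportionate for other training resolutions
            f = self.input_size / 640.0
            self.anchors = tuple((w * f, h * f) for w, h in DEFAULT_ANCHORS)
        self.anchors = tuple((float(w), float(h)) for w, h in self.anchors)
        self.strides = tuple(int(s) for s in self.strides)

    # -- derived quantities -------------------------------------------------
    @property
    def channels(self) -> list[int]:
        return [_make_divisible(b * self.width_multiple) for b in (64, 128, 256, 512, 1024)]

    @property
    def stage_depths(self) -> list[int]:
        return [max(1, round(b * self.depth_multiple)) for b in (3, 6, 9, 3)]

    @property
    def neck_depth(self) -> int:
        return max(1, round(3 * self.depth_multiple))

    def cfa_config(self) -> CFAConfig:
        c4 = self.channels[4]
        return CFAConfig(channels=c4, reduce_channels=self.cfa_reduce,
                         conv_mode=self.cfa_conv_mode, reduce_mode=self.cfa_reduce_mode,
                         fuse_mode=self.cfa_fuse_mode, activation=self.activation)

    def cam_config(self, channels: int) -> CAMConfig:
        return CAMConfig(channels=channels, reduction=self.cam_reduction,
                         strict_gate_nonlinearity=self.cam_strict_gate)

    def anchors_per_scale(self) -> np.ndarray:
        """(n_scales, 3, 2) anchor array in input pixels."""
        a = np.asarray(self.anchors, dtype=np.float32)
        return a.reshape(len(self.strides), 3, 2)

    # -- serialization ------------------------------------------------------
    SCHEMA_VERSION = 1

    def to_yaml(self) -> str:
        d = asdict(self)
        d["anchors"] = [list(a) for a in self.anchors]
        d["strides"] = list(self.strides)
        return yaml.safe_dump({"schema": self.SCHEMA_VERSION, "model": d},
                              sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        doc = yaml.safe_load(text)
        if doc.get("schema", 1) != cls.SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {doc.get('schema')!r}")
        d = doc["model"]
        d["anchors"] = tuple(tuple(a) for a in d["anchors"])
        d["strides"] = tuple(d["strides"])
        return cls(**d)


@dataclass
class ScalePrediction:
    """Raw head output at one scale: (batch, anchor, gy, gx, 5 + nc) logits.

    Channel layout along the last axis: x, y, w, h offsets, objectness, then
    class scores.
    """

    stride: int
    grid_h: int
    grid_w: int
    values: Tensor


class DetectorModel(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.channels
        d = cfg.stage_depths
        act = cfg.activation
        bb_kind = "p" if cfg.use_pc3 else "plain"
        nk_kind = "p" if (cfg.use_pc3 and cfg.pc3_neck) else "plain"

        def cbl(cin, cout, k, s=1):
            return ConvBNAct(ConvSpec(cin, cout, k, stride=s, activation=act), rng=rng)

        # backbone
        if cfg.stem == "focus":
            self.stem = Focus(3, c[0], act=act, rng=rng)
        else:
            self.stem = StemConv(3, c[0], act=act, rng=rng)
        self.b_conv1 = cbl(c[0], c[1], 3, 2)
        self.b_c3_1 = C3(c[1], c[1], d[0], True, bb_kind, act, rng)
        self.b_conv2 = cbl(c[1], c[2], 3, 2)
        self.b_c3_2 = C3(c[2], c[2], d[1], True, bb_kind, act, rng)
        self.b_conv3 = cbl(c[2], c[3], 3, 2)
        self.b_c3_3 = C3(c[3], c[3], d[2], True, bb_kind, act, rng)
        self.b_conv4 = cbl(c[3], c[4], 3, 2)
        self.b_c3_4 = C3(c[4], c[4], d[3], True, bb_kind, act, rng)
        self.sppf = SPPF(c[4], c[4], 5, act=act, rng=rng)
        self.cfa = CFA(cfg.cfa_config(), rng=rng) if cfg.use_cfa else None
        fusion_layout = cfg.cam_placement == "fusion"
        cam = (lambda ch, on=True: CoordinateAttention(cfg.cam_config(ch), rng=rng)
               if (cfg.use_cam and on) else None)
        self.cam_top = cam(c[4])

        # neck (PAN): top-down then bottom-up, attention on fusion outputs
        # (or, under the "heads" layout, on the three PAN outputs instead)
        nd = cfg.neck_depth
        self.n_red1 = cbl(c[4], c[3], 1)
        self.cam_td1 = cam(c[4], fusion_layout)
        self.n_c3_1 = C3(c[4], c[3], nd, False, nk_kind, act, rng)
        self.n_red2 = cbl(c[3], c[2], 1)
        self.cam_td2 = cam(c[3], fusion_layout)
        self.n_c3_2 = C3(c[3], c[2], nd, False, nk_kind, act, rng)
        self.n_down1 = cbl(c[2], c[2], 3, 2)
        self.cam_bu1 = cam(c[3], fusion_layout)
        self.n_c3_3 = C3(c[3], c[3], nd, False, nk_kind, act, rng)
        self.n_down2 = cbl(c[3], c[3], 3, 2)
        self.cam_bu2 = cam(c[4], fusion_layout)
        self.n_c3_4 = C3(c[4], c[4], nd, False, nk_kind, act, rng)
        self.cam_h3 = cam(c[2], not fusion_layout)
        self.cam_h4 = cam(c[3], not fusion_layout)
        self.cam_h5 = cam(c[4], not fusion_layout)

        # heads
        no = 3 * (5 + cfg.num_classes)
        self.head_p3 = nn.Conv2d(c[2], no, 1, bias=True, rng=rng)
        self.head_p4 = nn.Conv2d(c[3], no, 1, bias=True, rng=rng)
        self.head_p5 = nn.Conv2d(c[4], no, 1, bias=True, rng=rng)
        self._init_head_biases()

    def _init_head_biases(self):
        """Start the heads near the anchor prior.

        Head conv weights are shrunk so initial box logits sit at ~0: the
        decoded box then equals the anchor size at the cell centre, which the
        regression only has to refine.  Objectness biases start at the prior
        of ~8 objects per image so early training is not swamped by the
        background gradient.
        """
        nc = self.cfg.num_classes
        for head, s in zip((self.head_p3, self.head_p4, self.head_p5), self.cfg.strides):
            head.weight.data *= 0.01
            b = head.bias.data.reshape(3, 5 + nc)
            b[:, 4] = np.log(8.0 / (self.cfg.input_size / s) ** 2)
            head.bias.data = b.reshape(-1)

    # -- forward ------------------------------------------------------------
    def forward(self, images: Tensor) -> list[ScalePrediction]:
        cfg = self.cfg
        n, c, h, w = images.shape
        if c != 3 or h != cfg.input_size or w != cfg.input_size:
            raise ValueError(
                f"expected {n}x3x{cfg.input_size}x{cfg.input_size} input, got {images.shape}")

        def gate(block, x):
            return block(x) if block is not None else x

        x = self.stem(images)
        x = self.b_conv1(x)
        x = self.b_c3_1(x)
        x = self.b_conv2(x)
        p3src = self.b_c3_2(x)
        x = self.b_conv3(p3src)
        p4src = self.b_c3_3(x)
        x = self.b_conv4(p4src)
        x = self.b_c3_4(x)
        x = self.sppf(x)
        if self.cfa is not None:
            x = self.cfa(x)
        x = gate(self.cam_top, x)

        lat1 = self.n_red1(x)
        y = nn.concat([nn.upsample_nearest2x(lat1), p4src], axis=1)
        y = gate(self.cam_td1, y)
        y = self.n_c3_1(y)
        lat2 = self.n_red2(y)
        y = nn.concat([nn.upsample_nearest2x(lat2), p3src], axis=1)
        y = gate(self.cam_td2, y)
        p3 = self.n_c3_2(y)
        y = nn.concat([self.n_down1(p3), lat2], axis=1)
        y = gate(self.cam_bu1, y)
        p4 = self.n_c3_3(y)
        y = nn.concat([self.n_down2(p4), lat1], axis=1)
        y = gate(self.cam_bu2, y)
        p5 = self.n_c3_4(y)
        p3 = gate(self.cam_h3, p3)
        p4 = gate(self.cam_h4, p4)
        p5 = gate(self.cam_h5, p5)

        out = []
        nc_out = 5 + cfg.num_classes
        for feat, head, stride in zip((p3, p4, p5),
                                      (self.head_p3, self.head_p4, self.head_p5),
                                      cfg.strides):
            raw = head(feat)                                   # (n, 3*(5+nc), gh, gw)
            gh, gw = raw.shape[2], raw.shape[3]
            v = nn.reshape(raw, (n, 3, nc_out, gh, gw))
            v = nn.transpose(v, (0, 1, 3, 4, 2))               # (n, 3, gh, gw, 5+nc)
            out.append(ScalePrediction(stride=stride, grid_h=gh, grid_w=gw, values=v))
        return out


def build_model(cfg: ModelConfig, seed: int = 0) -> DetectorModel:
    return DetectorModel(cfg, seed=seed)


def count_parameters(model: DetectorModel) -> int:
    """Total trainable scalar parameters, by enumeration."""
    return model.count_parameters()


# ---------------------------------------------------------------------------
# closed-form parameter count
# ---------------------------------------------------------------------------

def _cbl_p(cin, cout, k):
    return conv_bn_act_params(ConvSpec(cin, cout, k))


def _bottleneck_p(h, kind):
    plain = _cbl_p(h, h, 1) + _cbl_p(h, h, 3)
    if kind == "plain":
        return plain
    return plain + _cbl_p(h, h, 1) + _cbl_p(h, h, 3)   # extra 1x1 path + final 3x3


def _c3_p(cin, cout, n, kind):
    h = cout // 2
    return (_cbl_p(cin, h, 1) + _cbl_p(cin, h, 1) + _cbl_p(2 * h, cout, 1)
            + n * _bottleneck_p(h, kind))


def symbolic_parameter_count(cfg: ModelConfig) -> int:
    """Closed-form total matching :func:`count_parameters` term by term."""
    c = cfg.channels
    d = cfg.stage_depths
    nd = cfg.neck_depth
    bb = "p" if cfg.use_pc3 else "plain"
    nk = "p" if (cfg.use_pc3 and cfg.pc3_neck) else "plain"
    p = _cbl_p(12, c[0], 3) if cfg.stem == "focus" else \
        conv_bn_act_params(ConvSpec(3, c[0], 6, stride=2))
    p += _cbl_p(c[0], c[1], 3) + _c3_p(c[1], c[1], d[0], bb)
    p += _cbl_p(c[1], c[2], 3) + _c3_p(c[2], c[2], d[1], bb)
    p += _cbl_p(c[2], c[3], 3) + _c3_p(c[3], c[3], d[2], bb)
    p += _cbl_p(c[3], c[4], 3) + _c3_p(c[4], c[4], d[3], bb)
    p += _cbl_p(c[4], c[4] // 2, 1) + _cbl_p(2 * c[4], c[4], 1)        # SPPF
    if cfg.use_cfa:
        p += cfa_parameter_count(cfg.cfa_config())
    if cfg.use_cam:
        sites = (c[4], c[4], c[3], c[3], c[4]) if cfg.cam_placement == "fusion" \
            else (c[4], c[2], c[3], c[4])
        for ch in sites:
            p += cam_parameter_count(ch, cfg.cam_reduction)
    p += _cbl_p(c[4], c[3], 1) + _c3_p(c[4], c[3], nd, nk)
    p += _cbl_p(c[3], c[2], 1) + _c3_p(c[3], c[2], nd, nk)
    p += _cbl_p(c[2], c[2], 3) + _c3_p(c[3], c[3], nd, nk)
    p += _cbl_p(c[3], c[3], 3) + _c3_p(c[4], c[4], nd, nk)
    no = 3 * (5 + cfg.num_classes)
    p += sum(ci * no + no for ci in (c[2], c[3], c[4]))
    return p


def ablation_config(group: int, input_size: int = 640) -> ModelConfig:
    """The four calibrated ablation configurations.

    1: baseline; 2: +CFA; 3: +CFA+CAM; 4: +CFA+CAM+P-C3.  The CFA reduce
    width (82) and conv modes, the attention reduction (16) and its five
    insertion points, and backbone-only P-C3 conversion are the calibrated
    values documented in docs/methods.md.
    """
    if group not in (1, 2, 3, 4):
        raise ValueError("ablation group must be 1..4")
    return ModelConfig(
        input_size=input_size,
        use_cfa=group >= 2,
        use_cam=group >= 3,
        use_pc3=group >= 4,
        cfa_reduce=82,
        cfa_conv_mode="cbl",
        cfa_reduce_mode="bare",
        cfa_fuse_mode="bare",
        cam_reduction=16,
    )
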