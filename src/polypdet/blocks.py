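"""Elementary convolutional blocks of the detector.

CBL (conv + batch norm + activation) is the basic unit; on top of it sit the
Focus stem, SPPF (serial spatial pyramid pooling), the standard C3
cross-stage-partial block, and the P-BottleNeck / P-C3 variants that add a
second parallel convolution path and an extra shortcut inside each
bottleneck.

Every block exposes ``count_parameters`` (enumerated) and there are matching
closed-form counters (``conv_bn_act_params`` etc.) used to cross-check the
enumeration in tests.

Wiring of P-BottleNeck
----------------------
``path A`` = 1x1 CBL -> 3x3 CBL; ``path B`` = 1x1 CBL; ``shortcut`` =
identity.  The three are combined element-wise (addition by default; a
concatenation switch exists), passed through a final 3x3 CBL, and an optional
residual link adds the block input to the result.  With addition-combine the
parameter count is exactly twice that of the plain bottleneck:
``20*h**2 + 8*h`` versus ``10*h**2 + 4*h`` for hidden width ``h``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Tensor

__all__ = [
    "ConvSpec",
    "ConvBNAct",
    "Focus",
    "focus_slice",
    "SPPF",
    "Bottleneck",
    "PBottleneck",
    "C3",
    "PC3",
    "conv_bn_act_params",
]

_KERNELS = (1, 3, 5, 6)


@dataclass(frozen=True)
class ConvSpec:
    """Declarative description of a convolution unit."""

    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    padding: int | None = None
    dilation: int = 1
    has_norm: bool = True
    activation: str = "silu"

    def __post_init__(self):
        if self.kernel not in _KERNELS:
            raise ValueError(f"kernel must be one of {_KERNELS}, got {self.kernel}")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if min(self.in_channels, self.out_channels) < 1:
            raise ValueError("channel counts must be positive")


def conv_bn_act_params(spec: ConvSpec) -> int:
    """Closed-form trainable-parameter count of a CBL unit.

    The convolution carries no additive bias when followed by normalisation
    (it would be absorbed by the norm shift); a bare conv keeps its bias.
    """
    p = spec.in_channels * spec.out_channels * spec.kernel ** 2
    if spec.has_norm:
        p += 2 * spec.out_channels
    else:
        p += spec.out_channels          # conv bias
    return p


class ConvBNAct(Module):
    """CBL: convolution + batch normalisation + activation.

    The activation defaults to SiLU (config-switchable to ReLU and friends);
    normalisation uses per-channel batch statistics with momentum 0.03 and
    epsilon 1e-3.
    """

    def __init__(self, spec: ConvSpec, rng: np.random.Generator | None = None):
        super().__init__()
        self.spec = spec
        self.conv = nn.Conv2d(spec.in_channels, spec.out_channels, spec.kernel,
                              stride=spec.stride, padding=spec.padding,
                              dilation=spec.dilation, bias=not spec.has_norm,
                              rng=rng)
        self.bn = nn.BatchNorm2d(spec.out_channels) if spec.has_norm else None
        self.act = nn.ACTIVATIONS[spec.activation]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}")
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        return self.act(y)


def _cbl(cin: int, cout: int, k: int, s: int = 1, d: int = 1, act: str = "silu",
         rng=None) -> ConvBNAct:
    return ConvBNAct(ConvSpec(cin, cout, k, stride=s, dilation=d, activation=act), rng=rng)


def focus_slice(x: Tensor) -> Tensor:
    """Pixel-parity slicing: (c, H, W) -> (4c, H/2, W/2), parameter-free.

    Slice order along channels: (even,even), (odd,even), (even,odd),
    (odd,odd) where the first index is the row parity.
    """
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"focus_slice needs even spatial dims, got {h}x{w}")
    idx = np.arange(n)
    parts = [
        nn.take(x, (idx[:, None, None, None], np.arange(c)[None, :, None, None],
                    np.arange(0, h, 2)[None, None, :, None],
                    np.arange(0, w, 2)[None, None, None, :])),
        nn.take(x, (idx[:, None, None, None], np.arange(c)[None, :, None, None],
                    np.arange(1, h, 2)[None, None, :, None],
                    np.arange(0, w, 2)[None, None, None, :])),
        nn.take(x, (idx[:, None, None, None], np.arange(c)[None, :, None, None],
                    np.arange(0, h, 2)[None, None, :, None],
                    np.arange(1, w, 2)[None, None, None, :])),
        nn.take(x, (idx[:, None, None, None], np.arange(c)[None, :, None, None],
                    np.arange(1, h, 2)[None, None, :, None],
                    np.arange(1, w, 2)[None, None, None, :])),
    ]
    return nn.concat(parts, axis=1)


class Focus(Module):
    """Stem: parity slice to 4x channels at half resolution, then a CBL."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, act: str = "silu", rng=None):
        super().__init__()
        self.conv = _cbl(4 * cin, cout, kernel, act=act, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(focus_slice(x))


class StemConv(Module):
    """Strided 6x6 stem, the slice-free equivalent of Focus."""

    def __init__(self, cin: int, cout: int, act: str = "silu", rng=None):
        super().__init__()
        self.conv = ConvBNAct(ConvSpec(cin, cout, 6, stride=2, padding=2,
                                       activation=act), rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class SPPF(Module):
    """Spatial pyramid pooling, fast variant.

    A 1x1 CBL halves the channels, three identical stride-1 max poolings are
    applied in series, the four stages (0..3 poolings) are concatenated and a
    1x1 CBL fuses them back.  Serial k=5 pooling is exactly equivalent to
    parallel pools with kernels 5, 9, 13.
    """

    def __init__(self, cin: int, cout: int, pool_kernel: int = 5, act: str = "silu", rng=None):
        super().__init__()
        self.pool_kernel = pool_kernel
        hidden = cin // 2
        self.cv1 = _cbl(cin, hidden, 1, act=act, rng=rng)
        self.cv2 = _cbl(hidden * 4, cout, 1, act=act, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        k = self.pool_kernel
        y0 = self.cv1(x)
        y1 = nn.maxpool2d(y0, k, 1, k // 2)
        y2 = nn.maxpool2d(y1, k, 1, k // 2)
        y3 = nn.maxpool2d(y2, k, 1, k // 2)
        return self.cv2(nn.concat([y0, y1, y2, y3], axis=1))


class Bottleneck(Module):
    """Plain bottleneck: 1x1 CBL -> 3x3 CBL with optional residual add."""

    def __init__(self, c: int, use_residual: bool = True, act: str = "silu", rng=None):
        super().__init__()
        self.use_residual = use_residual
        self.cv1 = _cbl(c, c, 1, act=act, rng=rng)
        self.cv2 = _cbl(c, c, 3, act=act, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return nn.add(x, y) if self.use_residual else y


class PBottleneck(Module):
    """Bottleneck with two parallel conv paths and an extra shortcut.

    See the module docstring for the wiring; ``combine='concat'`` switches the
    three-way merge from addition to channel concatenation (followed by the
    same final 3x3, whose input width then triples).
    """

    def __init__(self, c: int, use_residual: bool = True, combine: str = "add",
                 act: str = "silu", rng=None):
        super().__init__()
        if combine not in ("add", "concat"):
            raise ValueError("combine must be 'add' or 'concat'")
        self.use_residual = use_residual
        self.combine = combine
        self.cv_a1 = _cbl(c, c, 1, act=act, rng=rng)
        self.cv_a2 = _cbl(c, c, 3, act=act, rng=rng)
        self.cv_b = _cbl(c, c, 1, act=act, rng=rng)
        fin = 3 * c if combine == "concat" else c
        self.cv_out = _cbl(fin, c, 3, act=act, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        a = self.cv_a2(self.cv_a1(x))
        b = self.cv_b(x)
        if self.combine == "add":
            merged = nn.add(nn.add(a, b), x)
        else:
            merged = nn.concat([a, b, x], axis=1)
        y = self.cv_out(merged)
        return nn.add(x, y) if self.use_residual else y


class C3(Module):
    """Cross-stage-partial block: a bottleneck stack beside a 1x1 bypass.

    ``bottleneck='p'`` swaps in P-BottleNeck, giving the P-C3 variant.
    """

    def __init__(self, cin: int, cout: int, n: int = 1, use_residual: bool = True,
                 bottleneck: str = "plain", act: str = "silu", rng=None):
        super().__init__()
        if n < 1:
            raise ValueError("C3 needs n_bottlenecks >= 1")
        hidden = cout // 2
        self.cv1 = _cbl(cin, hidden, 1, act=act, rng=rng)
        self.cv2 = _cbl(cin, hidden, 1, act=act, rng=rng)
        self.cv3 = _cbl(2 * hidden, cout, 1, act=act, rng=rng)
        if use_residual and cin != cout:
            raise ValueError("residual bottlenecks require cin == cout")
        maker = PBottleneck if bottleneck == "p" else Bottleneck
        self.m = [maker(hidden, use_residual, act=act, rng=rng) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        for blk in self.m:
            y = blk(y)
        return self.cv3(nn.concat([y, self.cv2(x)], axis=1))


def PC3(cin: int, cout: int, n: int = 1, use_residual: bool = True,
        act: str = "silu", rng=None) -> C3:
    """P-C3: the C3 block built from P-BottleNecks."""
    return C3(cin, cout, n, use_residual, bottleneck="p", act=act, rng=rng)
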