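"""Context Feature Augmentation (CFA).

Four parallel dilated-convolution branches enrich the deepest backbone map
with context at growing receptive fields before it enters the neck:

* branch 1 — one 3x3 conv, dilation 1 (receptive extent 3),
* branch 2 — one 3x3 conv, dilation 2 (extent 5),
* branch 3 — two 3x3 convs, dilations 2 and 4 (extent 13),
* branch 4 — two 3x3 convs, dilations 3 and 6 (extent 19).

Each branch is reduced by a 1x1 convolution, the four reduced maps are
concatenated along channels, and a final 1x1 convolution fuses them back to
the input width.  Every dilated conv pads by its dilation rate, so spatial
dimensions are always preserved.

The dilated 3x3 convs are CBL units; whether the 1x1 reduce and fusion convs
carry norm/activation or are bare linear maps is a calibration switch
(``reduce_mode`` / ``fuse_mode``), as is the per-branch reduce width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import ConvBNAct, ConvSpec
from .nn import Module, Tensor

__all__ = ["CFAConfig", "CFA", "cfa_parameter_count", "branch_receptive_fields"]

_DEFAULT_DILATIONS = ((1,), (2,), (2, 4), (3, 6))


@dataclass(frozen=True)
class CFAConfig:
    """Configuration of the context-augmentation block.

    ``reduce_channels`` defaults to ``channels // 4`` so that the concatenated
    reduced maps return to ``channels`` before fusion; calibrated full-scale
    configurations may override it.  ``conv_mode`` applies to the dilated 3x3
    convs, ``reduce_mode``/``fuse_mode`` to the 1x1 convs; each is one of
    ``"cbl"`` (conv+norm+act), ``"bias"`` (bare conv with bias) or ``"bare"``
    (bare conv, no bias).
    """

    channels: int
    branch_dilations: tuple[tuple[int, ...], ...] = _DEFAULT_DILATIONS
    reduce_channels: int | None = None
    conv_mode: str = "cbl"
    reduce_mode: str = "cbl"
    fuse_mode: str = "cbl"
    activation: str = "silu"

    def __post_init__(self):
        if len(self.branch_dilations) != 4:
            raise ValueError("CFA requires exactly four branches")
        for m in (self.conv_mode, self.reduce_mode, self.fuse_mode):
            if m not in ("cbl", "bias", "bare"):
                raise ValueError(f"unknown conv mode {m!r}")

    @property
    def reduce(self) -> int:
        return self.reduce_channels if self.reduce_channels else self.channels // 4


def _unit(cin: int, cout: int, k: int, dilation: int, mode: str, act: str, rng):
    if mode == "cbl":
        return ConvBNAct(ConvSpec(cin, cout, k, dilation=dilation, activation=act),
                         rng=rng)
    return nn.Conv2d(cin, cout, k, dilation=dilation,
                     padding=dilation * (k - 1) // 2, bias=(mode == "bias"), rng=rng)


class CFA(Module):
    """Four-branch dilated context aggregation; output shape equals input shape."""

    def __init__(self, cfg: CFAConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        c, w_r = cfg.channels, cfg.reduce
        self.branches = [
            [_unit(c, c, 3, d, cfg.conv_mode, cfg.activation, rng) for d in dils]
            for dils in cfg.branch_dilations
        ]
        self.reduces = [_unit(c, w_r, 1, 1, cfg.reduce_mode, cfg.activation, rng)
                        for _ in range(4)]
        self.fuse = _unit(4 * w_r, c, 1, 1, cfg.fuse_mode, cfg.activation, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"CFA expects {self.cfg.channels} channels, got {x.shape[1]}")
        reduced = []
        for branch, reduce in zip(self.branches, self.reduces):
            y = x
            for conv in branch:
                y = conv(y)
            reduced.append(reduce(y))
        return self.fuse(nn.concat(reduced, axis=1))


def _unit_params(cin: int, cout: int, k: int, mode: str) -> int:
    p = cin * cout * k * k
    if mode == "cbl":
        p += 2 * cout
    elif mode == "bias":
        p += cout
    return p


def cfa_parameter_count(cfg: CFAConfig) -> int:
    """Closed-form trainable-parameter count of a CFA block.

    Sum of the dilated 3x3 convs (one or two per branch, channels -> channels),
    four 1x1 reduce convs (channels -> reduce) and the 1x1 fusion
    (4*reduce -> channels), each with norm/bias terms per its mode.
    """
    c, w_r = cfg.channels, cfg.reduce
    p = 0  # dilation does not change counts
    for dils in cfg.branch_dilations:
        p += len(dils) * _unit_params(c, c, 3, cfg.conv_mode)
    p += 4 * _unit_params(c, w_r, 1, cfg.reduce_mode)
    p += _unit_params(4 * w_r, c, 1, cfg.fuse_mode)
    return p


def branch_receptive_fields(cfg: CFAConfig) -> tuple[int, ...]:
    """Theoretical receptive extent of each branch's stacked 3x3 convs.

    A single 3x3 conv with dilation d spans ``2d + 1`` pixels; stacking convs
    composes extents as ``e1 + e2 - 1``.
    """
    out = []
    for dils in cfg.branch_dilations:
        extent = 1
        for d in dils:
            extent += 2 * d          # (2d + 1) - 1 added per conv
        out.append(extent)
    return tuple(out)
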