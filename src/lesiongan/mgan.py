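"""MGAN generator: inverted-residual encoder at output stride 8 + ASPP decoder.

A lightweight segmentation network for low-compute settings, combining a
MobileNetV2-style encoder (depthwise-separable inverted residual blocks) with
a DeepLab-style head.  The encoder's last two naturally stride-2 stages run
at stride 1 with dilations 2 and 4 instead, so the deepest feature sits at
1/8 of the input resolution (output stride 8) while keeping the enlarged
context of the original strides.  Atrous spatial pyramid pooling (ASPP) with
dilation rates 1, 6, 12 and 18 fuses multi-scale context by concatenation;
the result is upsampled and merged with a projected low-level encoder
feature, refined by two 3x3 convolutions, and mapped to a per-pixel lesion
probability by a 1x1 convolution + sigmoid.

Default widths put the generator at ~2.2M trainable parameters — an order of
magnitude below the EGAN generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .errors import ConfigurationError, ContractError
from .nn import Tensor, bilinear_resize, concat

__all__ = [
    "MganConfig",
    "InvertedResidualSpec",
    "InvertedResidual",
    "ASPP",
    "MganGenerator",
    "build_mgan",
    "aspp_forward",
    "mgan_forward",
]


@dataclass(frozen=True)
class InvertedResidualSpec:
    """One encoder stage: expansion factor, output channels, repeats, stride, dilation."""

    expand: int
    channels: int
    repeats: int
    stride: int
    dilation: int = 1


# MobileNetV2 stage layout modified for output stride 8: the two stages that
# would naturally stride to 1/16 and 1/32 run at stride 1 with dilation 2 / 4.
BASE_STAGES: tuple[InvertedResidualSpec, ...] = (
    InvertedResidualSpec(1, 16, 1, 1, 1),    # 1/2
    InvertedResidualSpec(6, 24, 2, 2, 1),    # 1/4
    InvertedResidualSpec(6, 32, 3, 2, 1),    # 1/8
    InvertedResidualSpec(6, 64, 4, 1, 2),    # 1/8, was stride 2
    InvertedResidualSpec(6, 96, 3, 1, 2),    # 1/8
    InvertedResidualSpec(6, 160, 3, 1, 4),   # 1/8, was stride 2
    InvertedResidualSpec(6, 320, 1, 1, 4),   # 1/8
)


def _round_ch(c: float, divisor: int = 8) -> int:
    new = max(divisor, int(c + divisor / 2) // divisor * divisor)
    if new < 0.9 * c:
        new += divisor
    return new


@dataclass(frozen=True)
class MganConfig:
    input_size: int = 512
    output_stride: int = 8
    aspp_rates: tuple[int, ...] = (1, 6, 12, 18)
    aspp_width: int = 128
    width_mult: float = 0.75
    stem_width: int = 32
    stages: tuple[InvertedResidualSpec, ...] = BASE_STAGES
    low_level_stage: int = 1      # stage at output stride 2 feeds the decoder
    low_level_width: int = 48
    decoder_width: int = 96
    width_scale: float = 1.0      # extra uniform factor for reduced test models

    def __post_init__(self):
        if self.output_stride != 8:
            raise ConfigurationError("the encoder is designed for output stride 8")
        if self.input_size % self.output_stride:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by {self.output_stride}")
        if len(self.aspp_rates) < 1:
            raise ConfigurationError("at least one ASPP rate is required")
        if not (1 <= self.low_level_stage <= len(self.stages)):
            raise ConfigurationError("low_level_stage out of range")

    def with_width_scale(self, factor: float) -> "MganConfig":
        return replace(
            self, width_scale=factor,
            aspp_width=max(8, int(self.aspp_width * factor)),
            low_level_width=max(4, int(self.low_level_width * factor)),
            decoder_width=max(8, int(self.decoder_width * factor)),
        )

    def stage_channels(self) -> list[int]:
        f = self.width_mult * self.width_scale
        return [_round_ch(s.channels * f) for s in self.stages]


class InvertedResidual(nn.Module):
    """Expand (1x1) -> depthwise 3x3 -> project (1x1); shortcut when shapes allow."""

    def __init__(self, cin: int, cout: int, expand: int, stride: int, dilation: int):
        super().__init__()
        mid = cin * expand
        self.use_expand = expand != 1
        if self.use_expand:
            self.expand_conv = nn.Conv2d(cin, mid, 1, bias=False)
            self.expand_bn = nn.BatchNorm2d(mid)
        self.dw = nn.Conv2d(mid, mid, 3, stride=stride, padding=dilation,
                            dilation=dilation, groups=mid, bias=False)
        self.dw_bn = nn.BatchNorm2d(mid)
        self.project = nn.Conv2d(mid, cout, 1, bias=False)
        self.project_bn = nn.BatchNorm2d(cout)
        self.residual = stride == 1 and cin == cout

    def forward(self, x: Tensor) -> Tensor:
        h = x
        if self.use_expand:
            h = self.expand_bn(self.expand_conv(h)).relu()
        h = self.dw_bn(self.dw(h)).relu()
        h = self.project_bn(self.project(h))
        return h + x if self.residual else h


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: parallel dilated 3x3 branches (rate 1 as
    1x1), concatenated and projected.  Every branch preserves spatial size."""

    def __init__(self, cin: int, width: int, rates: tuple[int, ...]):
        super().__init__()
        self.rates = tuple(rates)
        self.branches = nn.ModuleList()
        for r in self.rates:
            if r == 1:
                conv = nn.Conv2d(cin, width, 1, bias=False)
            else:
                conv = nn.Conv2d(cin, width, 3, padding=r, dilation=r, bias=False)
            self.branches.append(nn.Sequential(conv, nn.BatchNorm2d(width), nn.ReLU()))
        self.project = nn.Sequential(
            nn.Conv2d(width * len(self.rates), width, 1, bias=False),
            nn.BatchNorm2d(width), nn.ReLU())

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[-2:]
        if h < 1 or w < 1:
            raise ContractError("ASPP input feature map is empty")
        outs = [b(x) for b in self.branches]
        return self.project(concat(outs, axis=1))


def aspp_forward(aspp: ASPP, features) -> np.ndarray | Tensor:
    """Run an ASPP module; array input (CHW or NCHW) returns an array."""
    if isinstance(features, Tensor):
        return aspp(features)
    arr = np.asarray(features, dtype=np.float32)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    out = aspp(Tensor(arr)).data
    return out[0] if squeeze else out


class MganGenerator(nn.Module):
    def __init__(self, config: MganConfig):
        super().__init__()
        self.config = config
        chans = config.stage_channels()
        stem_w = _round_ch(config.stem_width * config.width_mult * config.width_scale)
        self.stem = nn.Conv2d(3, stem_w, 3, stride=2, padding=1, bias=False)
        self.stem_bn = nn.BatchNorm2d(stem_w)

        self.stages = nn.ModuleList()
        cin = stem_w
        for spec, c in zip(config.stages, chans):
            blocks = nn.ModuleList()
            for k in range(spec.repeats):
                blocks.append(InvertedResidual(cin, c, spec.expand,
                                               spec.stride if k == 0 else 1, spec.dilation))
                cin = c
            self.stages.append(blocks)

        self.aspp = ASPP(chans[-1], config.aspp_width, config.aspp_rates)
        ll_ch = chans[config.low_level_stage - 1]
        self.low_proj = nn.Sequential(
            nn.Conv2d(ll_ch, config.low_level_width, 1, bias=False),
            nn.BatchNorm2d(config.low_level_width), nn.ReLU())
        dw = config.decoder_width
        self.dec1 = nn.Sequential(
            nn.Conv2d(config.aspp_width + config.low_level_width, dw, 3, padding=1, bias=False),
            nn.BatchNorm2d(dw), nn.ReLU())
        self.dec2 = nn.Sequential(
            nn.Conv2d(dw, dw, 3, padding=1, bias=False), nn.BatchNorm2d(dw), nn.ReLU())
        self.head = nn.Conv2d(dw, 1, 1, bias=True)

    def forward(self, x: Tensor, capture: dict | None = None) -> Tensor:
        h = self.stem_bn(self.stem(x)).relu()
        low = None
        for i, stage in enumerate(self.stages):
            for blk in stage:
                h = blk(h)
            if capture is not None:
                capture[f"Enc{i + 1}"] = h.data
            if i == self.config.low_level_stage - 1:
                low = h
        if capture is not None:
            capture["EncoderOut"] = h.data
        a = self.aspp(h)
        if capture is not None:
            capture["ASPP"] = a.data
        low = self.low_proj(low)
        a = bilinear_resize(a, low.data.shape[-2:])
        d = self.dec1(concat([a, low], axis=1))
        d = self.dec2(d)
        d = bilinear_resize(d, x.data.shape[-2:])
        return self.head(d).sigmoid()

    def encoder_output_stride(self, input_size: int) -> float:
        """Measured ratio input size / deepest encoder feature size."""
        x = Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
        cap: dict = {}
        was_training = self.training
        self.eval()
        self(x, capture=cap)
        if was_training:
            self.train()
        return input_size / cap["EncoderOut"].shape[-1]


def build_mgan(config: MganConfig | None = None) -> MganGenerator:
    return MganGenerator(config or MganConfig())


def mgan_forward(model: MganGenerator, images) -> np.ndarray | Tensor:
    """Run the generator; returns probability map(s) at input resolution."""
    if isinstance(images, Tensor):
        x, was_array = images, False
    else:
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ContractError(f"expected HxWx3 image(s), got shape {arr.shape}")
        x, was_array = Tensor(arr.transpose(0, 3, 1, 2)), True
    h, w = x.data.shape[-2:]
    if h % model.config.output_stride or w % model.config.output_stride:
        raise ContractError(
            f"input size {h}x{w} must be divisible by {model.config.output_stride}")
    out = model(x)
    if was_array:
        maps = out.data[:, 0]
        return maps[0] if np.asarray(images).ndim == 3 else maps
    return out
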