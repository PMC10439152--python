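"""EGAN generator: compound-scaled squeeze-excitation encoder, asymmetric decoder.

The encoder is a seven-block mobile-inverted-bottleneck (MBConv) network with
squeeze-and-excitation gating and swish activations, scaled by the compound
coefficient ``phi``: depth multiplies by ``alpha**phi``, width by
``beta**phi`` and input resolution by ``gamma_r**phi``, with the base
multipliers constrained by ``alpha * beta**2 * gamma_r**2 ~ 2`` so one step of
``phi`` roughly doubles FLOPs.  The decoder is asymmetric: four stages of
bilinear upsampling and convolution, each concatenating a *skewed* selection
of encoder features — one lateral source per stage, chosen where the encoder
changes resolution, rather than mirroring every block as a symmetric U-shaped
network would.  A 1x1 convolution + sigmoid head emits the per-pixel lesion
probability map at input resolution.

Default widths put the generator at ~27M trainable parameters at any input
size (the body is fully convolutional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .errors import ConfigurationError, ContractError
from .nn import Tensor, bilinear_resize, concat, global_avg_pool

__all__ = [
    "CompoundScalingSpec",
    "BlockSpec",
    "EganConfig",
    "EganGenerator",
    "compound_scale",
    "build_egan",
    "egan_forward",
    "extract_activations",
    "ACTIVATION_NAMES",
]

ACTIVATION_NAMES = tuple(f"Block{i}" for i in range(1, 8)) + tuple(f"D{i}" for i in range(1, 5))


@dataclass(frozen=True)
class CompoundScalingSpec:
    """Compound-scaling coefficients: one knob (phi) scales depth/width/resolution."""

    phi: float = 0.0
    alpha: float = 1.2     # depth base
    beta: float = 1.1      # width base
    gamma_r: float = 1.15  # resolution base
    tolerance: float = 0.1

    def __post_init__(self):
        if self.phi < 0:
            raise ConfigurationError("phi must be >= 0")
        if min(self.alpha, self.beta, self.gamma_r) < 1.0:
            raise ConfigurationError("alpha, beta, gamma_r must each be >= 1")


def compound_scale(spec: CompoundScalingSpec) -> tuple[float, float, float]:
    """Return (depth, width, resolution) multipliers ``(alpha, beta, gamma_r)**phi``.

    Rejects base multipliers whose product ``alpha * beta^2 * gamma_r^2``
    strays from 2 by more than the spec tolerance.
    """
    product = spec.alpha * spec.beta**2 * spec.gamma_r**2
    if abs(product - 2.0) > spec.tolerance:
        raise ConfigurationError(
            f"alpha*beta^2*gamma_r^2 = {product:.4g} violates the ~2 constraint "
            f"(tolerance {spec.tolerance})")
    return spec.alpha**spec.phi, spec.beta**spec.phi, spec.gamma_r**spec.phi


@dataclass(frozen=True)
class BlockSpec:
    expand: int
    channels: int
    repeats: int
    stride: int
    kernel: int


# seven-block mobile-inverted-bottleneck skeleton (stem stride 2 precedes it)
BASE_BLOCKS: tuple[BlockSpec, ...] = (
    BlockSpec(1, 16, 1, 1, 3),
    BlockSpec(6, 24, 2, 2, 3),
    BlockSpec(6, 40, 2, 2, 5),
    BlockSpec(6, 80, 3, 2, 3),
    BlockSpec(6, 112, 3, 1, 5),
    BlockSpec(6, 192, 4, 2, 5),
    BlockSpec(6, 320, 1, 1, 3),
)


def _round_filters(c: float, divisor: int = 8) -> int:
    new = max(divisor, int(c + divisor / 2) // divisor * divisor)
    if new < 0.9 * c:
        new += divisor
    return new


@dataclass(frozen=True)
class EganConfig:
    input_size: int = 512
    scaling: CompoundScalingSpec = field(default_factory=lambda: CompoundScalingSpec(phi=4.0))
    stem_width: int = 32
    blocks: tuple[BlockSpec, ...] = BASE_BLOCKS
    se_ratio: float = 0.25
    # decoder stage widths D1..D4 and the encoder block feeding each stage
    decoder_widths: tuple[int, int, int, int] = (320, 160, 80, 40)
    lateral_sources: tuple[int, int, int, int] = (5, 3, 2, 1)
    width_scale: float = 1.0  # extra uniform width factor for reduced test models

    def __post_init__(self):
        if len(self.blocks) != 7:
            raise ConfigurationError("the encoder has exactly seven blocks")
        if len(self.decoder_widths) != 4 or len(self.lateral_sources) != 4:
            raise ConfigurationError("the decoder has exactly four stages")
        if not all(1 <= s <= 7 for s in self.lateral_sources):
            raise ConfigurationError("lateral sources must index encoder blocks 1..7")

    def scaled_blocks(self) -> tuple[list[int], list[int]]:
        """Resolved per-block (channels, repeats) after compound scaling."""
        dmult, wmult, _ = compound_scale(self.scaling)
        chans = [_round_filters(b.channels * wmult * self.width_scale) for b in self.blocks]
        reps = [max(1, math.ceil(b.repeats * dmult)) for b in self.blocks]
        return chans, reps

    def with_width_scale(self, factor: float) -> "EganConfig":
        return replace(self, width_scale=factor,
                       decoder_widths=tuple(max(4, int(w * factor)) for w in self.decoder_widths))

    def total_stride(self) -> int:
        s = 2  # stem
        for b in self.blocks:
            s *= b.stride
        return s


class SqueezeExcite(nn.Module):
    """Channel gating: global pool -> reduce -> swish -> expand -> sigmoid -> scale."""

    def __init__(self, channels: int, reduced: int):
        super().__init__()
        self.reduce = nn.Conv2d(channels, reduced, 1, bias=True)
        self.expand = nn.Conv2d(reduced, channels, 1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        s = global_avg_pool(x)
        s = self.reduce(s).swish()
        s = self.expand(s).sigmoid()
        return x * s


class MBConv(nn.Module):
    """Mobile inverted bottleneck: expand -> depthwise -> SE -> project."""

    def __init__(self, cin: int, cout: int, expand: int, kernel: int, stride: int,
                 se_ratio: float):
        super().__init__()
        mid = cin * expand
        self.use_expand = expand != 1
        if self.use_expand:
            self.expand_conv = nn.Conv2d(cin, mid, 1, bias=False)
            self.expand_bn = nn.BatchNorm2d(mid)
        self.dw = nn.Conv2d(mid, mid, kernel, stride=stride, padding=kernel // 2,
                            groups=mid, bias=False)
        self.dw_bn = nn.BatchNorm2d(mid)
        self.se = SqueezeExcite(mid, max(1, int(cin * se_ratio)))
        self.project = nn.Conv2d(mid, cout, 1, bias=False)
        self.project_bn = nn.BatchNorm2d(cout)
        self.residual = stride == 1 and cin == cout

    def forward(self, x: Tensor) -> Tensor:
        h = x
        if self.use_expand:
            h = self.expand_bn(self.expand_conv(h)).swish()
        h = self.dw_bn(self.dw(h)).swish()
        h = self.se(h)
        h = self.project_bn(self.project(h))
        return h + x if self.residual else h


class DecoderStage(nn.Module):
    """Bilinear upsample -> concat lateral -> two 3x3 conv+BN+swish."""

    def __init__(self, cin: int, lateral: int, cout: int):
        super().__init__()
        self.conv1 = nn.Conv2d(cin + lateral, cout, 3, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor, lateral: Tensor) -> Tensor:
        x = bilinear_resize(x, lateral.data.shape[-2:])
        x = concat([x, lateral], axis=1)
        x = self.bn1(self.conv1(x)).swish()
        return self.bn2(self.conv2(x)).swish()


class EganGenerator(nn.Module):
    def __init__(self, config: EganConfig):
        super().__init__()
        self.config = config
        chans, reps = config.scaled_blocks()
        stem_w = _round_filters(config.stem_width *
                                compound_scale(config.scaling)[1] * config.width_scale)
        self.stem = nn.Conv2d(3, stem_w, 3, stride=2, padding=1, bias=False)
        self.stem_bn = nn.BatchNorm2d(stem_w)

        self.blocks = nn.ModuleList()
        cin = stem_w
        self._block_strides = []
        for spec, c, r in zip(config.blocks, chans, reps):
            stage = nn.ModuleList()
            for k in range(r):
                stage.append(MBConv(cin, c, spec.expand, spec.kernel,
                                    spec.stride if k == 0 else 1, config.se_ratio))
                cin = c
            self.blocks.append(stage)
            self._block_strides.append(spec.stride)

        # spatial scale (relative to input) of each block's output
        scale = 2
        self._block_scales = []
        for s in self._block_strides:
            scale *= s
            self._block_scales.append(scale)

        # validate skewed laterals: each stage's source must sit at twice the
        # spatial resolution of the previous decoder stage input
        prev_scale = self._block_scales[-1]
        lat_ch = []
        for src in config.lateral_sources:
            src_scale = self._block_scales[src - 1]
            if src_scale >= prev_scale and prev_scale != src_scale:
                raise ConfigurationError(
                    f"lateral source Block{src} (1/{src_scale}) does not increase "
                    f"resolution over 1/{prev_scale}")
            prev_scale = src_scale
            lat_ch.append(chans[src - 1])

        self.decoder = nn.ModuleList()
        dcin = chans[-1]
        for w, lc in zip(config.decoder_widths, lat_ch):
            self.decoder.append(DecoderStage(dcin, lc, w))
            dcin = w
        self.head = nn.Conv2d(dcin, 1, 1, bias=True)

    def forward(self, x: Tensor, capture: dict | None = None) -> Tensor:
        h = self.stem_bn(self.stem(x)).swish()
        feats = []
        for i, stage in enumerate(self.blocks):
            for blk in stage:
                h = blk(h)
            feats.append(h)
            if capture is not None:
                capture[f"Block{i + 1}"] = h.data
        d = feats[-1]
        for i, (stage, src) in enumerate(zip(self.decoder, self.config.lateral_sources)):
            d = stage(d, feats[src - 1])
            if capture is not None:
                capture[f"D{i + 1}"] = d.data
        d = bilinear_resize(d, x.data.shape[-2:])
        return self.head(d).sigmoid()


def build_egan(config: EganConfig | None = None) -> EganGenerator:
    return EganGenerator(config or EganConfig())


def _images_to_nchw(images) -> tuple[Tensor, bool]:
    if isinstance(images, Tensor):
        return images, False
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ContractError(f"expected HxWx3 image(s), got shape {arr.shape}")
    return Tensor(arr.transpose(0, 3, 1, 2)), True


def egan_forward(model: EganGenerator, images) -> np.ndarray | Tensor:
    """Run the generator; returns probability map(s) at input resolution.

    Array input (H x W x 3 or batch) returns arrays with the batch axis
    mirrored from the input; Tensor NCHW input returns an NCHW Tensor.
    """
    x, was_array = _images_to_nchw(images)
    h, w = x.data.shape[-2:]
    stride = model.config.total_stride()
    if h % stride or w % stride:
        raise ContractError(f"input size {h}x{w} must be divisible by {stride}")
    out = model(x)
    if was_array:
        maps = out.data[:, 0]
        return maps[0] if np.asarray(images).ndim == 3 else maps
    return out


def extract_activations(model: EganGenerator, image, names) -> dict[str, np.ndarray]:
    """Return the named intermediate activations (CHW arrays) for one image."""
    names = list(names)
    unknown = set(names) - set(ACTIVATION_NAMES)
    if unknown:
        raise ContractError(f"unknown activation names: {sorted(unknown)}")
    if not names:
        return {}
    x, _ = _images_to_nchw(image)
    capture: dict[str, np.ndarray] = {}
    model(x, capture=capture)
    return {n: capture[n][0] for n in names}
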