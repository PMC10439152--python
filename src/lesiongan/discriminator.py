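"""PatchGAN discriminator and its output-shape / receptive-field geometry.

Five stride-2 convolutions (kernel 4, padding 1) with channel widths
64-128-256-512-1, LeakyReLU(0.2) after the first four and a sigmoid on the
last, scoring each local patch of the input mask/probability map as real or
fake.  Under this padding convention a 512 x 512 map yields a 16 x 16 score
grid, and one score unit sees a 94 x 94 patch of the input: the receptive
field follows the recurrence ``rf_k = rf_{k-1} + (k-1) * prod(previous
strides)``, i.e. 4 -> 10 -> 22 -> 46 -> 94 over the five layers.

The discriminator scores the mask/probability map alone (one input channel),
matching a setup where it distinguishes reference labels from generator
output.  No batch normalization is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ContractError
from .nn import Tensor

__all__ = [
    "DiscriminatorConfig",
    "PatchDiscriminator",
    "build_discriminator",
    "discriminator_forward",
    "patch_output_shape",
    "receptive_field",
    "empirical_receptive_field",
]

MIN_INPUT = 32  # smallest input whose score grid is >= 1x1


@dataclass(frozen=True)
class DiscriminatorConfig:
    widths: tuple[int, ...] = (64, 128, 256, 512, 1)
    kernel: int = 4
    stride: int = 2
    padding: int = 1
    leaky_slope: float = 0.2
    in_channels: int = 1

    def __post_init__(self):
        if len(self.widths) != 5:
            raise ConfigurationError("the patch discriminator has exactly five layers")
        if self.widths[-1] != 1:
            raise ConfigurationError("the last layer must produce one feature map")
        if min(self.widths) < 1 or self.kernel < 1 or self.stride < 1:
            raise ConfigurationError("widths, kernel and stride must be positive")

    def scaled(self, factor: float) -> "DiscriminatorConfig":
        """Thin-width variant for quick experiments; geometry is unchanged."""
        widths = tuple(max(1, int(round(w * factor))) for w in self.widths[:-1]) + (1,)
        return DiscriminatorConfig(widths=widths, kernel=self.kernel,
                                   stride=self.stride, padding=self.padding,
                                   leaky_slope=self.leaky_slope,
                                   in_channels=self.in_channels)


class PatchDiscriminator(nn.Module):
    def __init__(self, config: DiscriminatorConfig):
        super().__init__()
        self.config = config
        layers = []
        cin = config.in_channels
        for i, w in enumerate(config.widths):
            layers.append(nn.Conv2d(cin, w, config.kernel, stride=config.stride,
                                    padding=config.padding, bias=True))
            layers.append(nn.Sigmoid() if i == len(config.widths) - 1
                          else nn.LeakyReLU(config.leaky_slope))
            cin = w
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


def build_discriminator(config: DiscriminatorConfig | None = None) -> PatchDiscriminator:
    return PatchDiscriminator(config or DiscriminatorConfig())


def _to_nchw(m) -> tuple[Tensor, bool]:
    if isinstance(m, Tensor):
        return m, False
    arr = np.asarray(m, dtype=np.float32)
    if arr.ndim == 2:
        return Tensor(arr[None, None]), True
    if arr.ndim == 3:  # batch of 2-D maps
        return Tensor(arr[:, None]), True
    raise ContractError(f"expected a 2-D map or batch of maps, got shape {arr.shape}")


def discriminator_forward(model: PatchDiscriminator, m) -> np.ndarray | Tensor:
    """Score a mask or probability map; returns the m x n patch-score grid.

    Accepts a 2-D array (returns 2-D scores), a batch of 2-D arrays, or an
    NCHW Tensor (returns the Tensor with gradients attached).
    """
    x, was_array = _to_nchw(m)
    h, w = x.data.shape[-2:]
    if min(h, w) < MIN_INPUT:
        raise ContractError(f"input {h}x{w} too small; needs at least {MIN_INPUT} per side")
    scores = model(x)
    if was_array:
        out = scores.data
        return out[0, 0] if np.asarray(m).ndim == 2 else out[:, 0]
    return scores


def patch_output_shape(input_hw: int | tuple[int, int],
                       config: DiscriminatorConfig | None = None) -> tuple[int, int]:
    """Closed-form score-grid shape: each layer maps n -> floor((n+2p-k)/s)+1."""
    config = config or DiscriminatorConfig()
    h, w = (input_hw, input_hw) if np.isscalar(input_hw) else tuple(input_hw)
    if h < 1 or w < 1:
        raise ContractError("input size must be positive")
    for _ in config.widths:
        h = (h + 2 * config.padding - config.kernel) // config.stride + 1
        w = (w + 2 * config.padding - config.kernel) // config.stride + 1
    return h, w


def receptive_field(config: DiscriminatorConfig | None = None) -> int:
    """Receptive field (pixels per side) of one output unit.

    Standard recurrence: rf_0 = 1; rf_k = rf_{k-1} + (kernel-1) * prod of the
    strides of all earlier layers.
    """
    config = config or DiscriminatorConfig()
    rf, jump = 1, 1
    for _ in config.widths:
        rf += (config.kernel - 1) * jump
        jump *= config.stride
    return rf


def empirical_receptive_field(model: PatchDiscriminator, input_size: int = 160) -> int:
    """Measure the receptive field as the gradient-support footprint.

    Backpropagates one central score unit to the input and returns the side
    of the bounding box of nonzero input gradient.  The input must be large
    enough that the central unit's footprint does not clip at the borders.
    """
    x = Tensor(np.random.default_rng(0).uniform(0.2, 0.8,
               size=(1, model.config.in_channels, input_size, input_size)), requires_grad=True)
    scores = model(x)
    mh, mw = scores.data.shape[-2:]
    unit = scores[:, :, mh // 2, mw // 2].sum()
    unit.backward()
    g = np.abs(x.grad[0]).sum(axis=0)
    rows = np.flatnonzero(g.sum(axis=1) > 0)
    cols = np.flatnonzero(g.sum(axis=0) > 0)
    return int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))
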