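"""Patch-discriminator geometry: score-grid shape and receptive field.

The five kernel-4 / stride-2 / padding-1 convolutions halve the spatial size
each layer, so 512 -> 16 score patches per side, and the receptive-field
recurrence grows 4 -> 10 -> 22 -> 46 -> 94: every score unit judges one
94x94 patch of the input probability map.
"""

import numpy as np

from lesiongan import nn
from lesiongan.discriminator import (
    DiscriminatorConfig,
    build_discriminator,
    discriminator_forward,
    empirical_receptive_field,
    patch_output_shape,
    receptive_field,
)

cfg = DiscriminatorConfig()
print("layer widths:", cfg.widths)
for size in (512, 256, 96, 32):
    print(f"input {size:4d} -> score grid {patch_output_shape(size, cfg)}")
print("analytic receptive field:", receptive_field(cfg), "px")

nn.seed(0)
thin = build_discriminator(cfg.scaled(0.25))   # same geometry, fewer channels
print("empirical gradient footprint:", empirical_receptive_field(thin, 160), "px")

scores = discriminator_forward(thin, np.full((512, 512), 0.5, np.float32))
print("forward on 512x512 ->", scores.shape, "scores in (0,1):",
      bool(scores.min() > 0 and scores.max() < 1))
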