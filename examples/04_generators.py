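"""Build both generators and compare their parameter budgets.

EGAN is the precision model: a seven-block squeeze-excitation MBConv encoder
(compound-scaled) with an asymmetric four-stage decoder, ~27M parameters.
MGAN is the mobile model: inverted-residual encoder at output stride 8 with
ASPP (rates 1/6/12/18), ~2.2M parameters — an order of magnitude smaller.
"""

import numpy as np

from lesiongan import nn
from lesiongan.egan import EganConfig, build_egan, extract_activations
from lesiongan.mgan import MganConfig, build_mgan, mgan_forward

nn.seed(0)
egan = build_egan()
nn.seed(0)
mgan = build_mgan()
pe, pm = egan.parameter_count(), mgan.parameter_count()
print(f"EGAN parameters: {pe / 1e6:.2f} M")
print(f"MGAN parameters: {pm / 1e6:.2f} M  (ratio {pm / pe:.3f})")

# reduced-width twins run fast on CPU; full-resolution behaviour is identical
nn.seed(0)
small = build_mgan(MganConfig(input_size=64).with_width_scale(0.25))
prob = mgan_forward(small, np.random.default_rng(0).random((64, 64, 3), np.float32))
print("reduced MGAN on 64x64 ->", prob.shape, f"probabilities in [{prob.min():.3f}, {prob.max():.3f}]")
print("measured encoder output stride:", small.encoder_output_stride(64))

nn.seed(0)
small_e = build_egan(EganConfig(input_size=64).with_width_scale(0.125))
acts = extract_activations(small_e, np.random.default_rng(1).random((64, 64, 3), np.float32),
                           ["Block1", "Block7", "D1", "D4"])
for name, grid in acts.items():
    print(f"{name}: {grid.shape[0]} channels at {grid.shape[1]}x{grid.shape[2]}")
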