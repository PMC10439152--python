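"""Evaluate the loss suite on tiny hand-checkable inputs.

The dice loss measures soft overlap (0 = perfect, 1 = disjoint).  The
smoothing loss sums |p_i - p_j| over ordered 4-neighbour pairs whose
ground-truth labels agree and whose base pixel is foreground, penalizing
jagged predictions inside the lesion.  The adversarial term is the mean
binary cross-entropy of the discriminator's patch scores.
"""

import numpy as np

from lesiongan.losses import adversarial_bce, combined_loss, dice_loss, smoothing_loss

target = np.array([[1, 1], [0, 0]], float)
pred = np.array([[0.5, 1], [0.5, 0]], float)
print("dice loss:", dice_loss(pred, target))          # 1 - 3/3.5 = 0.142857...

target2 = np.ones((2, 2))
pred2 = np.array([[1, 0], [1, 1]], float)
print("smoothing loss:", smoothing_loss(pred2, target2))   # 4 pairs touch the 0-pixel
print("combined loss:", combined_loss(pred2, target2))     # 1/7 + 4

print("BCE at score 0.5 (real):", adversarial_bce(np.array([[0.5]]), True))  # log 2
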