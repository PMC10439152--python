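"""Segmentation and adversarial losses.

Three terms drive training:

* **Dice loss** — ``1 - 2*sum(p*t) / (sum(p^2) + sum(t^2))``, the soft overlap
  between the predicted probability map and the binary ground truth.
* **Boundary-smoothing loss** — a pairwise interaction over the 4-neighbour
  system: for every ordered pixel pair (i, j) with j a 4-neighbour of i, the
  term ``B(i,j) * y_i * |p_i - p_j|`` accumulates, where ``B(i,j) = 1`` iff
  the ground-truth labels agree.  It penalizes prediction jumps inside
  same-label foreground neighbourhoods, encouraging smooth lesion boundaries.
  Out-of-grid neighbours are skipped, so interior pixels contribute 4 ordered
  pairs, edge pixels 3 and corner pixels 2.
* **Patch adversarial loss** — binary cross-entropy over the discriminator's
  patch scores, averaged over patches.

Each function has two routes sharing one set of formulas: NumPy-array inputs
are evaluated in float64 and return a float; autograd
:class:`~lesiongan.nn.Tensor` inputs return a scalar Tensor so gradients flow
to the generator.  Ground-truth targets are always treated as constants.
"""

from __future__ import annotations

import numpy as np

from .errors import ContractError
from .nn import Tensor

__all__ = ["dice_loss", "smoothing_loss", "combined_loss", "adversarial_bce"]

EPS = 1e-7

# (slice for pixel i, slice for its neighbour j) per 4-neighbour offset,
# applied to the two trailing axes; border neighbours are simply absent.
_NEIGHBOUR_SLICES = (
    ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),   # j below i
    ((slice(1, None), slice(None)), (slice(None, -1), slice(None))),   # j above i
    ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),   # j right of i
    ((slice(None), slice(1, None)), (slice(None), slice(None, -1))),   # j left of i
)


def _target_array(target) -> np.ndarray:
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    return t.astype(np.float64)


def _check_shapes(pshape, tshape):
    if tuple(pshape) != tuple(tshape):
        raise ContractError(f"prediction shape {tuple(pshape)} != target shape {tuple(tshape)}")


def dice_loss(pred, target, eps: float = EPS):
    """Soft dice loss in [0, 1]; 0 at perfect overlap.

    Sums run over all pixels of each image (the trailing two axes); leading
    axes, if any, are batch axes whose per-image losses are averaged.  A small
    ``eps`` in the denominator guards the all-empty case.
    """
    t = _target_array(target)
    if not np.isin(t, (0.0, 1.0)).all():
        raise ContractError("target must be strictly binary")
    ax = (-2, -1)
    if isinstance(pred, Tensor):
        _check_shapes(pred.shape, t.shape)
        if np.any((pred.data < 0) | (pred.data > 1)):
            raise ContractError("prediction values must lie in [0, 1]")
        tf = t.astype(np.float32)
        num = (pred * Tensor(tf)).sum(axis=ax) * 2.0
        den = (pred * pred).sum(axis=ax) + Tensor(tf.sum(axis=ax)) + eps
        return (1.0 - num / den).mean()
    p = np.asarray(pred, dtype=np.float64)
    _check_shapes(p.shape, t.shape)
    if np.any((p < 0) | (p > 1)):
        raise ContractError("prediction values must lie in [0, 1]")
    num = 2.0 * (p * t).sum(axis=ax)
    den = (p * p).sum(axis=ax) + (t * t).sum(axis=ax) + eps
    return float(np.mean(1.0 - num / den))


def smoothing_loss(pred, target, normalize: bool = False):
    """Morphology-based boundary-smoothing loss (raw ordered-pair sum).

    With ``normalize=True`` the sum is divided by the pixel count, which keeps
    the term on a scale comparable to the dice loss during training; the raw
    sum is the reference definition.
    """
    t = _target_array(target)
    scale = 1.0 / float(np.prod(t.shape)) if normalize else 1.0
    if isinstance(pred, Tensor):
        _check_shapes(pred.shape, t.shape)
        total = None
        for si, sj in _NEIGHBOUR_SLICES:
            idx_i, idx_j = (Ellipsis,) + si, (Ellipsis,) + sj
            yi, yj = t[idx_i], t[idx_j]
            weight = ((yi == yj) * yi).astype(np.float32)  # B(i,j) * y_i
            term = ((pred[idx_i] - pred[idx_j]).abs() * Tensor(weight)).sum()
            total = term if total is None else total + term
        return total * scale if normalize else total
    p = np.asarray(pred, dtype=np.float64)
    _check_shapes(p.shape, t.shape)
    total = 0.0
    for si, sj in _NEIGHBOUR_SLICES:
        idx_i, idx_j = (Ellipsis,) + si, (Ellipsis,) + sj
        yi, yj = t[idx_i], t[idx_j]
        weight = (yi == yj) * yi
        total += float((np.abs(p[idx_i] - p[idx_j]) * weight).sum())
    return total * scale


def combined_loss(pred, target, smoothing_weight: float = 1.0,
                  normalize_smoothing: bool = False, eps: float = EPS):
    """Dice loss plus (optionally weighted) smoothing loss.

    The reference definition is the unweighted raw sum; the weight and the
    normalization flag are training conveniences.
    """
    d = dice_loss(pred, target, eps=eps)
    s = smoothing_loss(pred, target, normalize=normalize_smoothing)
    return d + smoothing_weight * s


def adversarial_bce(scores, is_real: bool, eps: float = EPS):
    """Mean binary cross-entropy over the discriminator's patch scores.

    ``is_real`` selects the label: 1 when the scored map is ground truth,
    0 when it came from the generator.  Scores are clamped to
    ``[eps, 1-eps]`` before the logs.
    """
    if isinstance(scores, Tensor):
        if np.any((scores.data < 0) | (scores.data > 1)):
            raise ContractError("scores must lie in [0, 1]")
        s = scores.clip(eps, 1.0 - eps)
        return -(s.log().mean()) if is_real else -((1.0 - s).log().mean())
    s = np.asarray(scores, dtype=np.float64)
    if np.any((s < 0) | (s > 1)):
        raise ContractError("scores must lie in [0, 1]")
    s = np.clip(s, eps, 1.0 - eps)
    return float(-np.mean(np.log(s))) if is_real else float(-np.mean(np.log(1.0 - s)))
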