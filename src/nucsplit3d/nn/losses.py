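"""Multi-task loss: Tversky + focal on the mask head, MSE on the vector head.

All three terms are nonnegative and vanish at the perfect prediction; the
combined loss is the weighted sum ``l_tv * L_TL + l_focal * L_FL + l_mse *
L_MSE``.  Every function accepts either plain ndarrays (returning a float) or
autodiff tensors (returning a differentiable scalar), so the training loop
and the user-facing API share one formula.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor, amean, asum, clip, log

__all__ = ["LossWeights", "tversky_loss", "focal_loss", "mse_vector_loss",
           "combined_loss"]

#: Smoothing constant in the Tversky ratio.
TVERSKY_EPS = 1e-6
#: Probability clipping bound in the focal loss.
FOCAL_CLIP = 1e-7


@dataclasses.dataclass
class LossWeights:
    """Weights of the combined loss and the per-term hyper-parameters.

    ``l_tv``, ``l_focal``, ``l_mse`` weight Tversky, focal and vector-MSE
    terms.  ``alpha_fn`` penalizes false negatives and ``alpha_fp`` false
    positives in the Tversky index (they must sum to 1); ``beta`` is the
    focal class weight for nucleus voxels and ``gamma`` the focusing
    exponent.
    """

    l_tv: float = 1.0
    l_focal: float = 10.0
    l_mse: float = 10.0
    alpha_fn: float = 0.3
    alpha_fp: float = 0.7
    beta: float = 0.8
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if abs(self.alpha_fn + self.alpha_fp - 1.0) > 1e-9:
            raise ValueError("alpha_fn + alpha_fp must equal 1")
        if not (0.0 < self.beta < 1.0):
            raise ValueError("beta must be in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if min(self.l_tv, self.l_focal, self.l_mse) < 0:
            raise ValueError("loss weights must be >= 0")


def _check_shapes(a, b) -> None:
    if tuple(a.shape) != tuple(b.shape):
        raise ValueError(f"shape mismatch: {tuple(a.shape)} vs {tuple(b.shape)}")


def tversky_loss(target, pred, alpha_fn: float = 0.3, alpha_fp: float = 0.7):
    """1 minus the Tversky index between a binary target and probabilities.

    ``TI = TP / (TP + alpha_fn * FN + alpha_fp * FP)`` with soft counts
    ``TP = sum(s * s_hat)``, ``FN = sum(s * (1 - s_hat))``,
    ``FP = sum((1 - s) * s_hat)``; a smoothing constant is added to numerator
    and denominator so the empty target is well defined.
    """
    _check_shapes(target, pred)
    tp = asum(target * pred)
    fn = asum(target * (1.0 - pred))
    fp = asum((1.0 - target) * pred)
    index = (tp + TVERSKY_EPS) / (tp + alpha_fn * fn + alpha_fp * fp + TVERSKY_EPS)
    return 1.0 - index


def focal_loss(target, pred, beta: float = 0.8, gamma: float = 2.0):
    """Class-weighted focal loss; subscript 1 = nucleus on both arguments.

    ``-(1/P) * sum(beta * s * (1-p)^gamma * log p
                   + (1-beta) * (1-s) * p^gamma * log(1-p))``
    with probabilities clipped away from 0 and 1.
    """
    _check_shapes(target, pred)
    p = clip(pred, FOCAL_CLIP, 1.0 - FOCAL_CLIP)
    pos = target * (1.0 - p) ** gamma * log(p) * beta
    neg = (1.0 - target) * p ** gamma * log(1.0 - p) * (1.0 - beta)
    return -amean(pos + neg)


def mse_vector_loss(target, pred):
    """Mean squared error over all scalar entries of the two vector fields."""
    _check_shapes(target, pred)
    return amean((target - pred) ** 2.0)


def combined_loss(mask_target, mask_pred, vec_target, vec_pred,
                  w: LossWeights = LossWeights()):
    """Weighted sum of the Tversky, focal and vector-MSE terms."""
    out = w.l_tv * tversky_loss(mask_target, mask_pred, w.alpha_fn, w.alpha_fp)
    out = out + w.l_focal * focal_loss(mask_target, mask_pred, w.beta, w.gamma)
    out = out + w.l_mse * mse_vector_loss(vec_target, vec_pred)
    return out
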