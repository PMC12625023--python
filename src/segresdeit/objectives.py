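"""Composite multi-task loss: weighted BCE + soft Dice for segmentation,
BCE for classification, and the loss-weight grid search.

``L_seg = lambda1 * L_BCE + lambda2 * L_DICE`` and
``L_total = L_seg + alpha * L_cls``.  Dice is soft (no thresholding of the
probability map) and is computed per sample then averaged over the batch, so
the batch loss is a mean over samples — this is what makes gradient
accumulation over micro-batches exactly equivalent to a full batch.

When the distillation token is active the classification term averages the
BCE of the class-token and distillation-token outputs (both supervised by
the ground-truth label absent a teacher).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .tensor import Tensor, as_tensor

EPS_CLIP = 1e-7  # probability clamp before logarithms


@dataclass(frozen=True)
class LossWeights:
    """lambda1/lambda2 balance BCE vs Dice (lambda1 + lambda2 = 1);
    alpha weights the classification task; epsilon smooths the Dice ratio."""

    lambda1: float = 0.6
    lambda2: float = 0.4
    alpha: float = 1.0
    epsilon: float = 1e-6


def _wrap(p, g) -> tuple[Tensor, Tensor, bool]:
    was_array = not isinstance(p, Tensor)
    return as_tensor(p), as_tensor(g), was_array


def _ret(value: Tensor, was_array: bool):
    return value.item() if was_array else value


def bce_pixel_loss(p, g):
    """Mean binary cross-entropy over all pixels (probabilities clamped)."""
    p, g, plain = _wrap(p, g)
    if p.shape != g.shape:
        raise ValueError("probability map and ground truth must share shape")
    pc = p.clip(EPS_CLIP, 1.0 - EPS_CLIP)
    loss = -(g * pc.log() + (1.0 - g) * (1.0 - pc).log()).mean()
    return _ret(loss, plain)


def dice_loss(p, g, epsilon: float = 1e-6):
    """Soft Dice loss ``1 - (2*sum(p*g)+eps) / (sum(p)+sum(g)+eps)``.

    For batched input (N, ...) the loss is computed per sample and averaged.
    """
    p, g, plain = _wrap(p, g)
    if p.shape != g.shape:
        raise ValueError("probability map and ground truth must share shape")
    if p.ndim >= 3:  # batched: reduce per sample over all but axis 0
        axes = tuple(range(1, p.ndim))
        inter = (p * g).sum(axis=axes)
        denom = p.sum(axis=axes) + g.sum(axis=axes)
        loss = (1.0 - (2.0 * inter + epsilon) / (denom + epsilon)).mean()
    else:
        inter = (p * g).sum()
        denom = p.sum() + g.sum()
        loss = 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)
    return _ret(loss, plain)


def seg_loss(p, g, weights: LossWeights = LossWeights()):
    """Weighted segmentation loss: lambda1*BCE + lambda2*Dice."""
    p, g, plain = _wrap(p, g)
    loss = weights.lambda1 * bce_pixel_loss(p, g) + weights.lambda2 * dice_loss(
        p, g, weights.epsilon
    )
    return _ret(loss, plain)


def cls_loss(y_hat, y):
    """Binary cross-entropy on scalar (or batched scalar) class probability."""
    y_hat, y, plain = _wrap(y_hat, y)
    pc = y_hat.clip(EPS_CLIP, 1.0 - EPS_CLIP)
    loss = -(y * pc.log() + (1.0 - y) * (1.0 - pc).log()).mean()
    return _ret(loss, plain)


def total_loss(mask_prob, mask_truth, class_probs, class_truth,
               weights: LossWeights = LossWeights()):
    """``L_total = L_seg + alpha * L_cls``.

    `class_probs` may be a single probability (array/Tensor) or a list of
    per-token probabilities (class + distillation); the classification term
    is the average of their BCE losses.
    """
    if not isinstance(class_probs, (list, tuple)):
        class_probs = [class_probs]
    plain = not isinstance(mask_prob, Tensor)
    seg = seg_loss(as_tensor(mask_prob), as_tensor(mask_truth), weights)
    cls_terms = [cls_loss(as_tensor(cp), as_tensor(class_truth)) for cp in class_probs]
    cls = cls_terms[0]
    for extra in cls_terms[1:]:
        cls = cls + extra
    cls = cls * (1.0 / len(cls_terms))
    loss = seg + weights.alpha * cls
    return _ret(loss, plain)


def default_weight_grid(
    lambda_pairs: Sequence[tuple[float, float]] = (
        (0.2, 0.8), (0.4, 0.6), (0.5, 0.5), (0.6, 0.4), (0.8, 0.2)
    ),
    alphas: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    epsilon: float = 1e-6,
) -> list[LossWeights]:
    return [
        LossWeights(l1, l2, a, epsilon) for l1, l2 in lambda_pairs for a in alphas
    ]


def grid_search_weights(
    candidates: Sequence[LossWeights],
    scorer: Callable[[LossWeights], float],
) -> LossWeights:
    """Return the candidate maximising `scorer`.

    Ties break towards smaller alpha, then larger lambda1.  Every candidate
    must satisfy lambda1 + lambda2 = 1.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate grid")
    for cand in candidates:
        if not math.isclose(cand.lambda1 + cand.lambda2, 1.0, abs_tol=1e-9):
            raise ValueError(f"lambda1 + lambda2 must be 1, got {cand}")
    scored = [(scorer(c), -c.alpha, c.lambda1, i) for i, c in enumerate(candidates)]
    best = max(scored)
    return candidates[best[-1]]
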