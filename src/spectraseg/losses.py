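"""Composite training objective: cross-entropy plus one-minus-soft-Dice.

The Dice term pools intersections and sums over all *foreground* classes
before taking the ratio (background, class 0, is excluded), while the
cross-entropy runs over all 13 classes and averages over the N = B*H*W
output voxels.  ``composite_loss`` also returns the analytic gradient with
respect to the logits, which the training loop feeds straight into the
network's backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "one_hot", "soft_dice_fg", "cross_entropy_loss",
           "composite_loss", "EPSILON", "PROB_FLOOR"]

EPSILON = 1e-6      # Dice denominator stabilizer
PROB_FLOOR = 1e-12  # probability clip before log


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int, dtype=np.float64) -> np.ndarray:
    """(B, H, W) integer labels -> (B, C, H, W) one-hot."""
    B, H, W = labels.shape
    g = np.zeros((B, n_classes, H, W), dtype=dtype)
    b, h, w = np.indices((B, H, W))
    g[b, labels, h, w] = 1.0
    return g


def soft_dice_fg(probs: np.ndarray, onehot: np.ndarray,
                 per_class: bool = False) -> float:
    """Pooled soft Dice over foreground classes (1..C-1).

    2 * sum_fg(p*g) / (sum_fg(p) + sum_fg(g) + eps), with the sums pooled
    over foreground classes before the ratio.  ``per_class=True`` instead
    averages per-class Dice ratios over foreground classes (exposed for
    comparison; the pooled form is the default used everywhere).
    """
    p = probs[:, 1:]
    g = onehot[:, 1:]
    if per_class:
        inter = (p * g).sum(axis=(0, 2, 3))
        denom = p.sum(axis=(0, 2, 3)) + g.sum(axis=(0, 2, 3)) + EPSILON
        return float(np.mean(2.0 * inter / denom))
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum()) + EPSILON
    return 2.0 * inter / denom


def cross_entropy_loss(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Multiclass CE: -(1/N) sum_i sum_c g_ci log p_ci over all classes."""
    if probs.shape != onehot.shape:
        raise ValueError("shape mismatch between probs and onehot")
    N = probs.shape[0] * probs.shape[2] * probs.shape[3]
    p = np.clip(probs, PROB_FLOOR, None)
    return float(-(onehot * np.log(p)).sum() / N)


def composite_loss(logits: np.ndarray, labels: np.ndarray,
                   ) -> tuple[float, np.ndarray]:
    """Total loss CE + (1 - Dice_fg) and its gradient w.r.t. the logits."""
    B, C, H, W = logits.shape
    N = B * H * W
    p = softmax(logits.astype(np.float64), axis=1)
    g = one_hot(labels, C)
    ce = cross_entropy_loss(p, g)
    dice = soft_dice_fg(p, g)
    loss = ce + (1.0 - dice)

    # d(CE)/dlogits = (p - g)/N  (softmax+CE shortcut)
    dlogits = (p - g) / N
    # dice term: D = 2I/(P+G+eps) over foreground entries of p
    pf, gf = p[:, 1:], g[:, 1:]
    inter = float((pf * gf).sum())
    denom = float(pf.sum() + gf.sum()) + EPSILON
    dD_dp = np.zeros_like(p)
    dD_dp[:, 1:] = (2.0 * gf * denom - 2.0 * inter) / denom ** 2
    grad_p = -dD_dp  # loss carries (1 - D)
    # chain through softmax: dz = p * (grad_p - sum_c p_c grad_p_c)
    dlogits += p * (grad_p - (p * grad_p).sum(axis=1, keepdims=True))
    return float(loss), dlogits.astype(logits.dtype)
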