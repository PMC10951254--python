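"""Class-weighted focal loss for strongly imbalanced vessel segmentation.

Vessel pixels are typically ~1-10% of an angiogram, so plain cross-entropy
collapses toward the background class. Two remedies are combined: a
per-class weight (vessel 20, background 1) inside the cross-entropy term,
and the focal modulation (1 - p_t)^gamma that down-weights easy pixels,
scaled by alpha:

    FL = alpha * (1 - p_t)^gamma * ( -w_y * log p_t )

with p_t the predicted probability of the pixel's true class and w_y the
true class's weight; the scalar loss is the mean of the per-pixel terms.
A "literal" variant is available behind a switch: it feeds the scalar
weighted cross-entropy itself through the focal formula, the reading one
gets by taking the printed form at face value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, clip_min

EPS = 1e-7


@dataclass(frozen=True)
class FocalLossParams:
    alpha: float = 0.8
    gamma: float = 2.0
    class_weights: tuple = (1.0, 20.0)    # (background, vessel)
    literal_form: bool = False

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if min(self.class_weights) <= 0:
            raise ValueError("class weights must be > 0")


def _split_classes(probs: Tensor):
    """Background / vessel probability planes of a (N,2,H,W) tensor.

    Slicing is not an autograd primitive here, so select channels by a
    one-hot contraction over the class axis.
    """
    c = probs.shape[1]
    sel_bg = np.zeros((1, c, 1, 1), dtype=np.float32)
    sel_bg[0, 0] = 1.0
    sel_v = np.zeros((1, c, 1, 1), dtype=np.float32)
    sel_v[0, 1] = 1.0
    p_bg = (probs * Tensor(sel_bg)).sum(axis=1)
    p_v = (probs * Tensor(sel_v)).sum(axis=1)
    return p_bg, p_v


def weighted_ce(probs, target, class_weights=(1.0, 20.0), reduce: bool = True):
    """Weighted cross-entropy: per-pixel -w_y log p_y, scalar = pixel mean.

    ``probs``: (N,2,H,W) softmax output (Tensor or ndarray) on the simplex;
    ``target``: (N,H,W) binary vessel mask. Probabilities are clamped at
    ``EPS`` so a confidently wrong pixel yields a large finite value.
    """
    t = np.asarray(target, dtype=np.float32)
    w_bg, w_v = float(class_weights[0]), float(class_weights[1])
    wmap = w_v * t + w_bg * (1.0 - t)
    if isinstance(probs, Tensor):
        p_bg, p_v = _split_classes(probs)
        p_t = p_v * Tensor(t) + p_bg * Tensor(1.0 - t)
        pix = nn.log(clip_min(p_t, EPS)) * Tensor(-wmap)
        return pix.mean()
    p = np.asarray(probs, dtype=np.float64)
    if p.shape[1] != 2 or t.shape != p[:, 0].shape:
        raise ValueError(f"shape mismatch: probs {p.shape}, target {t.shape}")
    p_t = p[:, 1] * t + p[:, 0] * (1.0 - t)
    pix = -wmap * np.log(np.maximum(p_t, EPS))
    return pix if not reduce else float(pix.mean())


def focal_loss(probs, target, params: FocalLossParams | None = None):
    """Scalar focal loss; differentiable when ``probs`` is a Tensor."""
    params = params or FocalLossParams()
    a, g = params.alpha, params.gamma
    t = np.asarray(target, dtype=np.float32)
    w_bg, w_v = params.class_weights
    wmap = w_v * t + w_bg * (1.0 - t)

    if params.literal_form:
        wce = weighted_ce(probs, target, params.class_weights)
        if isinstance(wce, Tensor):
            wce = clip_min(wce, EPS)
            return (nn.log(wce) * (1.0 - wce) ** g) * (-a)
        wce = max(wce, EPS)
        return float(-a * (1.0 - wce) ** g * np.log(wce))

    if isinstance(probs, Tensor):
        p_bg, p_v = _split_classes(probs)
        p_t = clip_min(p_v * Tensor(t) + p_bg * Tensor(1.0 - t), EPS)
        pix = nn.log(p_t) * Tensor(-wmap)
        if g:
            pix = pix * (1.0 - p_t) ** g
        return pix.mean() * a
    p = np.asarray(probs, dtype=np.float64)
    p_t = np.maximum(p[:, 1] * t + p[:, 0] * (1.0 - t), EPS)
    pix = a * (1.0 - p_t) ** g * (-wmap * np.log(p_t))
    return float(pix.mean())
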