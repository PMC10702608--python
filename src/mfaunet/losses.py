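"""Segmentation losses: binary cross-entropy, soft Dice and the
deep-supervision aggregate used by the multi-branch decoder head.

All functions accept either plain numpy arrays (returning a float) or
autodiff tensors (returning a differentiable scalar tensor), so the same
code path serves evaluation and training.  Probabilities are clipped to
``[eps, 1-eps]`` (eps = 1e-7) so gradients stay finite at p in {0, 1}.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

EPS = 1e-7


def _pair(p, y):
    tp, ty = ad.astensor(p), ad.astensor(y)
    if tp.shape != ty.shape:
        raise ValueError(f"prediction shape {tp.shape} != target shape {ty.shape}")
    return tp, ty


def _maybe_float(out: Tensor, *inputs) -> Tensor | float:
    if any(isinstance(x, Tensor) and x.requires_grad for x in inputs):
        return out
    return float(out.data)


def bce_loss(p, y):
    """Mean binary cross-entropy over all pixels in the batch."""
    tp, ty = _pair(p, y)
    pc = ad.clip(tp, EPS, 1.0 - EPS)
    ll = ty * ad.log(pc) + (1.0 - ty) * ad.log(1.0 - pc)
    out = -ad.tmean(ll)
    return _maybe_float(out, p, y)


def dice_loss(p, y, smooth: float = 1.0):
    """Soft Dice loss ``1 - (2<y,p> + s) / (|y|^2 + |p|^2 + s)`` in [0, 1].

    Computed on the foreground channel; for hard masks it equals
    ``1 - DSC`` as the smoothing term vanishes.
    """
    if smooth <= 0:
        raise ValueError("smooth must be positive")
    tp, ty = _pair(p, y)
    inter = ad.tsum(ty * tp)
    denom = ad.tsum(ad.square(ty) + ad.square(tp))
    out = 1.0 - ad.div(2.0 * inter + smooth, denom + smooth)
    return _maybe_float(out, p, y)


def deep_supervision_loss(probs, y, smooth: float = 1.0,
                          weights=(1.0, 1.0, 1.0)):
    """Aggregate loss over the three decoder branches.

    ``probs`` is (branch1, branch2, fusion) probability maps, all compared
    against the same ground truth: BCE on branch 1 (pixel-level, favours
    the majority macrovessels), Dice on branch 2 (overlap-level, favours
    microvessels) and BCE + Dice on the fusion output.  A single-output
    model (multi-branch head disabled) passes a 1-tuple and receives
    BCE + Dice on it.
    """
    if len(probs) == 1:
        w = weights[-1]
        out = w * (bce_loss_t(probs[0], y) + dice_loss_t(probs[0], y, smooth))
        return _maybe_float(out, probs[0], y)
    if len(probs) != 3:
        raise ValueError("expected (branch1, branch2, fusion) outputs")
    b1, b2, fus = probs
    out = (weights[0] * bce_loss_t(b1, y)
           + weights[1] * dice_loss_t(b2, y, smooth)
           + weights[2] * (bce_loss_t(fus, y) + dice_loss_t(fus, y, smooth)))
    return _maybe_float(out, b1, b2, fus, y)


def bce_loss_t(p, y) -> Tensor:
    tp, ty = _pair(p, y)
    pc = ad.clip(tp, EPS, 1.0 - EPS)
    return -ad.tmean(ty * ad.log(pc) + (1.0 - ty) * ad.log(1.0 - pc))


def dice_loss_t(p, y, smooth: float = 1.0) -> Tensor:
    tp, ty = _pair(p, y)
    inter = ad.tsum(ty * tp)
    denom = ad.tsum(ad.square(ty) + ad.square(tp))
    return 1.0 - ad.div(2.0 * inter + smooth, denom + smooth)


def soft_dice(p, y, smooth: float = 1.0) -> float:
    """Soft Dice coefficient (1 - dice_loss) of probabilities vs a mask."""
    return 1.0 - float(ad.astensor(dice_loss_t(np.asarray(p), np.asarray(y),
                                               smooth)).data)
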