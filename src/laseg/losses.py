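"""Segmentation losses for heavily imbalanced foregrounds.

The training objective is the sum of a soft Dice loss and a focal loss.
Dice measures relative overlap, so it is insensitive to how small the
foreground is; focal loss is a cross-entropy whose easy pixels are
down-weighted by ``(1 - p)^gamma``, keeping the gradient focused on the
ambiguous boundary and low-contrast pixels.  Padded sequence positions
are excluded through a validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .errors import ValidationError

__all__ = ["LossConfig", "dice_loss", "focal_loss", "combined_loss"]

_EPS = 1e-7   # probability clip before logarithms


@dataclass
class LossConfig:
    """Loss hyperparameters.

    ``focal_alpha`` balances positive versus negative pixels,
    ``focal_gamma`` is the focusing exponent, and ``smooth`` stabilises
    the Dice ratio on near-empty masks.
    """

    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    smooth: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.focal_alpha < 1:
            raise ValidationError("focal_alpha must be in (0, 1)")
        if self.focal_gamma < 0:
            raise ValidationError("focal_gamma must be >= 0")
        if self.smooth <= 0:
            raise ValidationError("smooth must be > 0")


def _prepare(pred, target, valid):
    pred = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred))
    target_arr = target.data if isinstance(target, Tensor) else np.asarray(target)
    if pred.shape != target_arr.shape:
        raise ValidationError(
            f"prediction shape {pred.shape} != target shape {target_arr.shape}")
    if valid is not None:
        valid = np.broadcast_to(np.asarray(valid, dtype=bool), pred.shape)
        weights = valid.astype(pred.data.dtype)
    else:
        weights = np.ones(pred.shape, dtype=pred.data.dtype)
    return pred, target_arr.astype(pred.data.dtype), weights


def dice_loss(pred_fg, target, cfg: LossConfig = LossConfig(),
              valid: np.ndarray | None = None) -> Tensor:
    """Soft Dice loss ``1 - (2 |P.G| + s) / (|P| + |G| + s)`` over the
    unmasked pixels, with probability-valued predictions."""
    pred, tgt, wts = _prepare(pred_fg, target, valid)
    inter = (pred * (tgt * wts)).sum()
    sums = (pred * wts).sum() + (tgt * wts).sum()
    return 1.0 - (2.0 * inter + cfg.smooth) / (sums + cfg.smooth)


def focal_loss(pred_fg, target, cfg: LossConfig = LossConfig(),
               valid: np.ndarray | None = None) -> Tensor:
    """Focal loss averaged over the unmasked pixels.

    ``-alpha y (1-p)^g log p - (1-alpha)(1-y) p^g log(1-p)`` with the
    prediction clipped away from 0 and 1 before the logarithms.
    """
    pred, tgt, wts = _prepare(pred_fg, target, valid)
    p = pred.clip(_EPS, 1.0 - _EPS)
    pos = (1.0 - p) ** cfg.focal_gamma * p.log() * (-cfg.focal_alpha * tgt)
    neg = p ** cfg.focal_gamma * (1.0 - p).log() * (-(1.0 - cfg.focal_alpha)
                                                    * (1.0 - tgt))
    total = ((pos + neg) * wts).sum()
    return total * (1.0 / max(float(wts.sum()), 1.0))


def combined_loss(pred_fg, target, cfg: LossConfig = LossConfig(),
                  valid: np.ndarray | None = None) -> Tensor:
    """Sum of the Dice and focal terms on identical inputs."""
    return (dice_loss(pred_fg, target, cfg, valid)
            + focal_loss(pred_fg, target, cfg, valid))
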