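"""Overlap and surface metrics for binary segmentations.

Dice and IoU are reported as percentages of set overlap; the Hausdorff
distance is the exact symmetric maximum of nearest-point distances
between the two foreground coordinate sets (no percentile relaxation),
in pixels, or in millimetres when a voxel spacing is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .errors import UndefinedMetricError, ValidationError

__all__ = ["MetricReport", "dice_iou", "hausdorff", "evaluate_volume"]


@dataclass
class MetricReport:
    """Per-volume evaluation summary.  ``hausdorff`` is None when the
    distance is undefined (one of the masks is empty)."""

    dice_pct: float
    iou_pct: float
    hausdorff: float | None
    per_slice_dice: list[float] | None = None

    def as_dict(self) -> dict:
        return {"dice_pct": self.dice_pct, "iou_pct": self.iou_pct,
                "hausdorff": self.hausdorff}


def _check_pair(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValidationError(
            f"prediction shape {pred.shape} != reference shape {ref.shape}")
    for name, m in (("prediction", pred), ("reference", ref)):
        if not np.isin(np.unique(m), (0, 1)).all():
            raise ValidationError(f"{name} mask must be binary")
    return pred.astype(bool), ref.astype(bool)


def dice_iou(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Dice and IoU percentages; two empty masks agree perfectly (100)."""
    p, g = _check_pair(pred, ref)
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        return 100.0, 100.0
    inter = int((p & g).sum())
    dice = 200.0 * inter / (np_ + ng)
    iou = 100.0 * inter / (np_ + ng - inter)
    return dice, iou


def hausdorff(pred: np.ndarray, ref: np.ndarray,
              spacing: tuple[float, ...] | None = None) -> float:
    """Exact symmetric Hausdorff distance between the foreground point
    sets, Euclidean, optionally scaled by per-axis spacing."""
    p, g = _check_pair(pred, ref)
    if not p.any() or not g.any():
        raise UndefinedMetricError(
            "Hausdorff distance is undefined for an empty mask")
    xp = np.argwhere(p).astype(float)
    xg = np.argwhere(g).astype(float)
    if spacing is not None:
        sp = np.asarray(spacing, dtype=float)
        if len(sp) != p.ndim or (sp <= 0).any():
            raise ValidationError(f"spacing must be {p.ndim} positive values")
        xp = xp * sp
        xg = xg * sp
    d1 = directed_hausdorff(xp, xg)[0]
    d2 = directed_hausdorff(xg, xp)[0]
    return float(max(d1, d2))


def evaluate_volume(pred_vol: np.ndarray, ref_vol: np.ndarray,
                    spacing: tuple[float, float, float] | None = None,
                    per_slice: bool = False) -> MetricReport:
    """Pooled-voxel Dice/IoU plus 3-D Hausdorff for one volume pair.

    Per-slice Dice values are attached on request; an undefined Hausdorff
    (empty mask on either side) is reported as a missing value.
    """
    p, g = _check_pair(pred_vol, ref_vol)
    if p.ndim != 3:
        raise ValidationError("evaluate_volume expects 3-D masks")
    dice, iou = dice_iou(p, g)
    try:
        hd = hausdorff(p, g, spacing)
    except UndefinedMetricError:
        hd = None
    slice_dice = None
    if per_slice:
        slice_dice = [dice_iou(p[k], g[k])[0] for k in range(p.shape[0])]
    return MetricReport(dice_pct=dice, iou_pct=iou, hausdorff=hd,
                        per_slice_dice=slice_dice)
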