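"""Seeded phantom volumes emulating cardiac MR slice-sequence statistics.

Each phantom reproduces, at configurable size, the four data features the
segmentation method is designed around:

1. *slice-to-slice continuity* — a single elliptical target whose centre
   follows a small random walk across slices;
2. *large scale variation* — the ellipse area follows a smooth sine bump
   along the scan axis, spanning at least a few-fold range;
3. *low contrast* — distractor blobs whose intensity lies within the
   configured contrast gap of the target, so brightness alone cannot
   identify it;
4. *class imbalance* — the target occupies well under ten percent of the
   pixels on every slice.

Distractors are re-drawn independently on each slice.  This mimics
through-plane structures that lack the target's continuity, and makes the
inter-slice correlation itself an informative cue: a per-slice model sees
target and distractor as near-identical, while a sequence model can
exploit persistence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .volume_io import Volume3D, save_volume

logger = logging.getLogger(__name__)

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset",
           "split_train_val", "write_dataset"]


@dataclass
class PhantomConfig:
    """Generation parameters for one phantom volume.

    ``fg_max_fraction`` bounds the peak per-slice foreground fraction and
    must stay below 0.10; ``contrast`` is the intensity gap between
    target and background on the [0, 1] scale, and also bounds how close
    distractor intensities sit to the target's.
    """

    n_slices: int = 20
    height: int = 64
    width: int = 64
    fg_max_fraction: float = 0.08
    contrast: float = 0.15
    n_distractors: int = 3
    noise_sd: float = 0.03
    jitter: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        if not 0 < self.fg_max_fraction < 0.10:
            raise ValidationError("fg_max_fraction must be in (0, 0.10)")
        if not 0 < self.contrast <= 1:
            raise ValidationError("contrast must be in (0, 1]")
        if self.height < 16 or self.width < 16:
            raise ValidationError("phantom slices must be at least 16x16")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


_ASPECT = 1.5          # fixed semi-axis ratio of the elliptical target
_MIN_SEMI_AXIS = 2.0   # pixels; keeps every slice's target non-degenerate
_AREA_RATIO = 4.0      # peak-to-minimum area ratio of the sine profile
_BG_LEVEL = 0.35       # background intensity before noise


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    return ((u / ry) ** 2 + (v / rx) ** 2) <= 1.0


def generate_phantom(cfg: PhantomConfig) -> Volume3D:
    """Generate one phantom volume with its ground-truth mask.

    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w, n = cfg.height, cfg.width, cfg.n_slices

    # area profile: sine bump between peak area and peak/_AREA_RATIO
    a_max = cfg.fg_max_fraction * h * w * 0.95   # headroom under the cap
    a_min = a_max / _AREA_RATIO
    if a_min < math.pi * _MIN_SEMI_AXIS ** 2 * _ASPECT:
        raise ValidationError(
            "requested foreground fraction is unreachable at this image "
            "size: the smallest slice's target would degenerate")
    t = (np.arange(n) + 0.5) / n
    areas = a_min + (a_max - a_min) * np.sin(math.pi * t) ** 2 if n > 1 \
        else np.array([a_max])

    theta = rng.uniform(0, math.pi)
    # start anywhere in the central 40% band: position alone must not
    # identify the target, persistence across slices does
    cy = rng.uniform(0.3 * h, 0.7 * h)
    cx = rng.uniform(0.3 * w, 0.7 * w)

    vol = np.empty((n, h, w), dtype=np.float32)
    mask = np.zeros((n, h, w), dtype=np.uint8)
    target_level = _BG_LEVEL + cfg.contrast

    for k in range(n):
        # semi-axes from the target area: pi * ry * rx, rx = _ASPECT * ry
        ry = math.sqrt(areas[k] / (math.pi * _ASPECT))
        rx = _ASPECT * ry
        m = _ellipse_mask(h, w, cy, cx, ry, rx, theta)
        img = np.full((h, w), _BG_LEVEL, dtype=np.float32)
        img[m] = target_level

        # distractors: drawn from the same shape/size/intensity family as
        # the target (ellipses of the same aspect, areas from the same
        # range, intensity within `contrast` of the target) but re-placed
        # independently on every slice — so within a single slice they are
        # near-indistinguishable from the target and only the slice-to-
        # slice persistence identifies it; they never overlap the
        # (slightly dilated) target
        placed = 0
        guard = 0
        while placed < cfg.n_distractors and guard < 50 * max(1, cfg.n_distractors):
            guard += 1
            d_area = rng.uniform(a_min, a_max)
            d_ry = math.sqrt(d_area / (math.pi * _ASPECT))
            d_rx = _ASPECT * d_ry
            d_theta = rng.uniform(0, math.pi)
            r_out = max(d_ry, d_rx)
            dy = rng.uniform(r_out, h - r_out)
            dx = rng.uniform(r_out, w - r_out)
            blob = _ellipse_mask(h, w, dy, dx, d_ry, d_rx, d_theta)
            near = _ellipse_mask(h, w, cy, cx, ry + 2, rx + 2, theta)
            if (blob & near).any():
                continue
            level = target_level + rng.uniform(-cfg.contrast / 2,
                                               cfg.contrast / 2)
            img[blob] = np.clip(level, 0.0, 1.0)
            placed += 1

        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, (h, w)).astype(np.float32)
        vol[k] = np.clip(img, 0.0, 1.0)
        mask[k] = m.astype(np.uint8)

        # random-walk jitter of the target centre between slices
        cy = float(np.clip(cy + rng.normal(0, cfg.jitter), h * 0.2, h * 0.8))
        cx = float(np.clip(cx + rng.normal(0, cfg.jitter), w * 0.2, w * 0.8))

    return Volume3D(intensities=vol, mask=mask, spacing=(1.0, 1.0, 1.0))


def generate_dataset(n_volumes: int, cfg: PhantomConfig, seed: int
                     ) -> list[Volume3D]:
    """Draw ``n_volumes`` phantoms with per-volume seeds derived from a
    master seed; two calls with the same arguments are identical."""
    if n_volumes < 1:
        raise ValidationError("n_volumes must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_volumes) % (2 ** 31)
    vols = []
    for s in child_seeds:
        c = PhantomConfig(**{**vars(cfg), "seed": int(s)})
        vols.append(generate_phantom(c))
    return vols


def split_train_val(volumes: list) -> tuple[list, list]:
    """Tag items (volumes, or any per-volume groups) into train and
    validation subsets at a 4:1 ratio."""
    n = len(volumes)
    n_val = n // 5
    if n_val == 0:
        if n > 1:
            n_val = 1
        else:
            logger.warning("single-volume dataset: assigning it to the "
                           "training split, validation set is empty")
    n_train = n - n_val
    return volumes[:n_train], volumes[n_train:]


def write_dataset(volumes: list[Volume3D], out_dir: str | Path) -> list[tuple[Path, Path]]:
    """Write phantoms as NIfTI image/label pairs; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, v in enumerate(volumes):
        img_p = out_dir / f"phantom_{i:03d}.nii.gz"
        msk_p = out_dir / f"phantom_{i:03d}_mask.nii.gz"
        save_volume(img_p, v.intensities, v.spacing)
        save_volume(msk_p, v.mask, v.spacing)
        paths.append((img_p, msk_p))
    return paths
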