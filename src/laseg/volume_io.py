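"""Reading, slicing and sequencing of 3-D cardiac MR volumes.

A scan is handled as an ordered stack of 2-D slices along the acquisition
axis.  For training, slices that contain no labelled target are dropped
(the atrium appears only on a central run of slices; the empty ends carry
no supervision signal).  Retained slices are intensity-normalised,
resized, and grouped into fixed-length sequences that form the recurrent
network's input — a five-dimensional ``(N, T, C, H, W)`` batch.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
import SimpleITK as sitk
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Volume3D", "SliceSequence", "Batch",
    "load_volume", "save_volume", "split_and_filter", "resize_slice",
    "make_sequences", "batch_sequences", "preprocess_volume",
]


@dataclass
class Volume3D:
    """A 3-D grayscale image with an optional aligned binary mask.

    ``intensities`` is indexed (slice, row, col) with the scan axis given
    by ``scan_axis`` (default 0).  ``spacing`` is the per-axis voxel size
    in millimetres, when the source header provides one.
    """

    intensities: np.ndarray
    mask: np.ndarray | None = None
    spacing: tuple[float, float, float] | None = None
    scan_axis: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValidationError(
                f"intensities must be 3-D, got shape {self.intensities.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.intensities.shape:
                raise ValidationError(
                    f"mask shape {self.mask.shape} does not match "
                    f"intensities shape {self.intensities.shape}")
            vals = np.unique(self.mask)
            if not np.isin(vals, (0, 1, 255)).all():
                raise ValidationError(
                    f"mask must be coded 0/1 or 0/255, found values {vals}")
            self.mask = (self.mask > 0).astype(np.uint8)
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)
            if any(s <= 0 for s in self.spacing):
                raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if not 0 <= self.scan_axis <= 2:
            raise ValidationError("scan_axis must be 0, 1 or 2")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[self.scan_axis]


@dataclass
class SliceSequence:
    """An ordered run of T preprocessed slices forming one recurrent input.

    ``pad_count`` trailing positions are repeats of the last real slice;
    they are carried through the network but excluded from loss and
    metrics.
    """

    images: np.ndarray                  # (T, C, H, W) float
    masks: np.ndarray | None            # (T, H, W) uint8
    source_index: int = 0
    pad_count: int = 0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 4:
            raise ValidationError("images must be (T, C, H, W)")
        if self.masks is not None:
            self.masks = np.asarray(self.masks)
            if self.masks.shape != (self.images.shape[0],) + self.images.shape[2:]:
                raise ValidationError("masks must be (T, H, W) matching images")
        if not 0 <= self.pad_count < self.images.shape[0]:
            raise ValidationError("pad_count must be < sequence length")

    @property
    def seq_len(self) -> int:
        return self.images.shape[0]

    @property
    def valid(self) -> np.ndarray:
        """Boolean (T,) vector: True for real slices, False for padding."""
        t = self.seq_len
        return np.arange(t) < t - self.pad_count


@dataclass
class Batch:
    """A five-dimensional (N, T, C, H, W) network input with companions."""

    data: np.ndarray
    masks: np.ndarray | None = None     # (N, T, H, W)
    pad_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValidationError(f"batch must be (N, T, C, H, W), "
                                  f"got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValidationError("batch must contain at least one sequence")
        if self.masks is not None and self.masks.shape != (
                self.data.shape[0], self.data.shape[1]) + self.data.shape[3:]:
            raise ValidationError("batch masks must be (N, T, H, W)")

    @property
    def valid(self) -> np.ndarray:
        """Boolean (N, T) validity matrix derived from pad counts."""
        n, t = self.data.shape[:2]
        pads = self.pad_counts if len(self.pad_counts) == n else np.zeros(n, int)
        return np.arange(t)[None, :] < (t - pads)[:, None]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_any(path: Path) -> tuple[np.ndarray, tuple[float, ...] | None]:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        return data, tuple(float(z) for z in zooms)
    if name.endswith(".nrrd"):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)            # (z, y, x)
        return data, tuple(reversed(img.GetSpacing()))
    raise ValidationError(f"unsupported volume format: {path}")


def load_volume(path: str | os.PathLike,
                mask_path: str | os.PathLike | None = None,
                scan_axis: int = 0) -> Volume3D:
    """Load a NIfTI or NRRD volume (and optional label volume) from disk.

    Label values coded 0/255 are remapped to 0/1.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    data, spacing = _read_any(path)
    mask = None
    if mask_path is not None:
        mask_path = Path(mask_path)
        if not mask_path.exists():
            raise IOError(f"mask file not found: {mask_path}")
        mask, _ = _read_any(mask_path)
        mask = np.rint(mask).astype(np.int64)
    return Volume3D(intensities=data, mask=mask, spacing=spacing,
                    scan_axis=scan_axis)


def save_volume(path: str | os.PathLike, data: np.ndarray,
                spacing: tuple[float, float, float] | None = None) -> None:
    """Write a 3-D array as NIfTI, carrying spacing into the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sp = spacing if spacing is not None else (1.0, 1.0, 1.0)
    affine = np.diag(list(sp) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(sp)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# slicing / sequencing
# ---------------------------------------------------------------------------

def split_and_filter(vol: Volume3D, keep_empty: bool = False
                     ) -> list[tuple[np.ndarray, np.ndarray | None]]:
    """Split a volume into ordered 2-D (image, mask) slice pairs.

    With ``keep_empty=False`` (training) slices whose mask has no
    foreground pixel are excluded; with ``keep_empty=True`` (inference)
    every slice is retained.
    """
    if not keep_empty and vol.mask is None:
        raise ConfigurationError(
            "cannot filter empty slices without a mask; "
            "pass keep_empty=True for unlabelled volumes")
    imgs = np.moveaxis(vol.intensities, vol.scan_axis, 0)
    masks = (np.moveaxis(vol.mask, vol.scan_axis, 0)
             if vol.mask is not None else None)
    out: list[tuple[np.ndarray, np.ndarray | None]] = []
    for k in range(imgs.shape[0]):
        m = masks[k] if masks is not None else None
        if not keep_empty and int(m.sum()) == 0:
            continue
        out.append((imgs[k], m))
    if not out:
        logger.warning("split_and_filter: no slice contains foreground; "
                       "returning an empty list")
    return out


def resize_slice(img: np.ndarray, mask: np.ndarray | None,
                 target: tuple[int, int]
                 ) -> tuple[np.ndarray, np.ndarray | None]:
    """Resize one slice: smooth (bilinear) for intensities, nearest
    neighbour for the mask so it stays binary."""
    th, tw = int(target[0]), int(target[1])
    if th < 8 or tw < 8:
        raise ValidationError(f"target size must be at least 8x8, got {target}")
    if img.shape == (th, tw):
        out_img = img
    else:
        out_img = _sk_resize(img, (th, tw), order=1, preserve_range=True,
                             anti_aliasing=img.shape[0] > th)
        out_img = out_img.astype(img.dtype if np.issubdtype(img.dtype, np.floating)
                                 else np.float64)
    out_mask = None
    if mask is not None:
        if mask.shape == (th, tw):
            out_mask = mask
        else:
            out_mask = _sk_resize(mask.astype(np.uint8), (th, tw), order=0,
                                  preserve_range=True,
                                  anti_aliasing=False).astype(np.uint8)
    return out_img, out_mask


def make_sequences(slices: list[tuple[np.ndarray, np.ndarray | None]],
                   seq_len: int = 8) -> list[SliceSequence]:
    """Group ordered slices into consecutive non-overlapping sequences of
    length ``seq_len``; a final short group is padded by repeating its
    last slice, with the pad count recorded."""
    if seq_len < 1:
        raise ValidationError("sequence length must be >= 1")
    if not slices:
        raise ValidationError("cannot build sequences from an empty slice list")
    seqs: list[SliceSequence] = []
    for start in range(0, len(slices), seq_len):
        chunk = slices[start:start + seq_len]
        pad = seq_len - len(chunk)
        chunk = chunk + [chunk[-1]] * pad
        imgs = np.stack([np.asarray(c[0], dtype=np.float32)[None] for c in chunk])
        masks = None
        if chunk[0][1] is not None:
            masks = np.stack([np.asarray(c[1], dtype=np.uint8) for c in chunk])
        seqs.append(SliceSequence(images=imgs, masks=masks,
                                  source_index=start, pad_count=pad))
    return seqs


def batch_sequences(seqs: list[SliceSequence]) -> Batch:
    """Stack sequences of identical geometry into an (N, T, C, H, W) batch."""
    if not seqs:
        raise ValidationError("cannot batch an empty sequence list")
    shapes = {s.images.shape for s in seqs}
    if len(shapes) != 1:
        raise ValidationError(f"sequences have inconsistent shapes: {shapes}")
    masks = None
    if all(s.masks is not None for s in seqs):
        masks = np.stack([s.masks for s in seqs])
    return Batch(data=np.stack([s.images for s in seqs]), masks=masks,
                 pad_counts=np.array([s.pad_count for s in seqs]))


def normalize_intensities(vol_imgs: np.ndarray) -> np.ndarray:
    """Per-volume min–max scaling to [0, 1] (constant volumes map to 0)."""
    lo, hi = float(vol_imgs.min()), float(vol_imgs.max())
    if hi <= lo:
        return np.zeros_like(vol_imgs, dtype=np.float32)
    return ((vol_imgs - lo) / (hi - lo)).astype(np.float32)


def preprocess_volume(vol: Volume3D, size: tuple[int, int] | int,
                      seq_len: int = 8, keep_empty: bool = False
                      ) -> list[SliceSequence]:
    """Full input pipeline: normalise, split, filter, resize, sequence."""
    if isinstance(size, int):
        size = (size, size)
    vol = Volume3D(intensities=normalize_intensities(vol.intensities),
                   mask=vol.mask, spacing=vol.spacing, scan_axis=vol.scan_axis)
    pairs = split_and_filter(vol, keep_empty=keep_empty)
    if not pairs:
        return []
    pairs = [resize_slice(img, m, size) for img, m in pairs]
    return make_sequences(pairs, seq_len=seq_len)
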