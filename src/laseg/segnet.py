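"""The full sequence segmentation network.

Per slice, a U-shaped CNN runs a residual (bottleneck) encoder that emits
five skip feature maps at strides 2..32, passes each skip through the
multi-scale feature-fusion attention module, and decodes by repeated
upsample-and-concatenate back to input resolution — no cropping, so no
border information is lost.  The same CNN parameters are shared by every
slice.  Across the slice dimension, the per-slice feature maps are fed
to a bidirectional convolutional GRU whose concatenated states pass
through a 1x1 convolution and a softmax to give per-pixel class
probabilities.

A ``reduced`` configuration shrinks every width by a common factor and
uses one residual block per stage; it exists for desk-scale experiments
and tests and changes nothing structural.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, concat, stack
from .convgru import BiConvGRU
from .errors import ValidationError
from .msa import MSA
from .volume_io import Batch

__all__ = ["NetworkConfig", "Prediction", "SegSeqNet", "binarize",
           "strip_padding", "save_checkpoint", "load_checkpoint"]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``encoder_widths`` are the five skip channel counts (strides 2, 4, 8,
    16, 32).  ``msa_on_skips`` selects which skip levels get the
    attention module (all five by default).  ``head_width`` is the
    per-slice feature width entering the recurrence, whose hidden size
    matches it, so the bidirectional output has ``2 * head_width``
    channels.
    """

    encoder_widths: tuple[int, ...] = (64, 256, 512, 1024, 2048)
    blocks: tuple[int, ...] = (3, 4, 6, 3)
    decoder_widths: tuple[int, ...] = (256, 128, 64, 64)
    head_width: int = 64
    input_channels: int = 1
    num_classes: int = 2
    seq_len: int = 8
    msa_on_skips: tuple[int, ...] = (0, 1, 2, 3, 4)
    msa_grids: tuple[int, ...] = (1, 2, 4, 6)
    msa_reduction: int = 4
    msa_proj_ratio: int = 8
    msa_max_grid: int = 32
    gru_kernel: int = 3
    use_recurrence: bool = True
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.encoder_widths) != 5:
            raise ValidationError("encoder_widths must list five skip levels")
        if len(self.blocks) != 4 or len(self.decoder_widths) != 4:
            raise ValidationError("blocks and decoder_widths must have 4 entries")
        if self.num_classes < 2:
            raise ValidationError("num_classes must be >= 2")
        if any(w < 4 for w in self.encoder_widths):
            raise ValidationError("encoder widths must be >= 4")
        if not all(0 <= i <= 4 for i in self.msa_on_skips):
            raise ValidationError("msa_on_skips indices must be in 0..4")

    @classmethod
    def reduced(cls, factor: int = 8, **overrides) -> "NetworkConfig":
        """Desk-scale preset: widths divided by ``factor``, one residual
        block per stage.  Attention defaults to the two shallowest skips
        only, because the deeper skips of a small test image are below
        the largest pyramid grid.
        """
        base = cls()
        kw = dict(
            encoder_widths=tuple(max(4, w // factor) for w in base.encoder_widths),
            blocks=(1, 1, 1, 1),
            decoder_widths=tuple(max(4, w // factor) for w in base.decoder_widths),
            head_width=max(4, base.head_width // factor),
            msa_on_skips=(0, 1),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class Prediction:
    """Per-pixel class probabilities and, after binarisation, masks."""

    probabilities: np.ndarray            # (N, T, K, H, W)
    binary_mask: np.ndarray | None = None  # (N, T, H, W)


class Bottleneck(nn.Module):
    """Residual bottleneck: 1x1 reduce, 3x3 (optionally strided), 1x1
    expand, plus a projection shortcut when shape changes."""

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 *, rng: np.random.Generator):
        mid = max(4, out_ch // 4)
        self.conv1 = nn.Conv2d(in_ch, mid, 1, rng=rng)
        self.norm1 = nn.GroupNorm(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=stride, rng=rng)
        self.norm2 = nn.GroupNorm(mid)
        self.conv3 = nn.Conv2d(mid, out_ch, 1, rng=rng)
        self.norm3 = nn.GroupNorm(out_ch)
        self.shortcut = None
        if in_ch != out_ch or stride != 1:
            self.shortcut = nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                      pad=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm1(self.conv1(x)).relu()
        y = self.norm2(self.conv2(y)).relu()
        y = self.norm3(self.conv3(y))
        s = x if self.shortcut is None else self.shortcut(x)
        return (y + s).relu()


class Encoder(nn.Module):
    """Residual encoder emitting five skip maps at strides 2..32."""

    def __init__(self, cfg: NetworkConfig, *, rng: np.random.Generator):
        w = cfg.encoder_widths
        self.stem = nn.Conv2d(cfg.input_channels, w[0], 7, stride=2, rng=rng)
        self.stem_norm = nn.GroupNorm(w[0])
        self.stages = []
        in_ch = w[0]
        for level in range(4):
            stride = 1 if level == 0 else 2   # the stem pool supplies stride 4
            blocks = []
            for b in range(cfg.blocks[level]):
                blocks.append(Bottleneck(in_ch, w[level + 1],
                                         stride if b == 0 else 1, rng=rng))
                in_ch = w[level + 1]
            self.stages.append(blocks)

    def forward(self, x: Tensor) -> list[Tensor]:
        h, w = x.shape[2:]
        if h % 32 or w % 32:
            raise ValidationError(
                f"input spatial size ({h}, {w}) must be divisible by 32")
        skips = []
        y = self.stem_norm(self.stem(x)).relu()
        skips.append(y)                                   # stride 2
        y = nn.max_pool2d(y, 3, 2, pad=1)                 # stride 4
        for blocks in self.stages:
            for blk in blocks:
                y = blk(y)
            skips.append(y)                               # strides 4..32
        return skips


class Decoder(nn.Module):
    """Upsample-and-concatenate decoder ending at input resolution."""

    def __init__(self, cfg: NetworkConfig, *, rng: np.random.Generator):
        w = cfg.encoder_widths
        d = cfg.decoder_widths
        self.convs = []
        self.norms = []
        in_ch = w[4]
        for i, skip_ch in enumerate((w[3], w[2], w[1], w[0])):
            self.convs.append(nn.Conv2d(in_ch + skip_ch, d[i], 3, rng=rng))
            self.norms.append(nn.GroupNorm(d[i]))
            in_ch = d[i]
        self.head_conv = nn.Conv2d(in_ch, cfg.head_width, 3, rng=rng)
        self.head_norm = nn.GroupNorm(cfg.head_width)

    def forward(self, skips: list[Tensor],
                out_size: tuple[int, int]) -> Tensor:
        y = skips[4]
        for i, skip in enumerate((skips[3], skips[2], skips[1], skips[0])):
            y = nn.upsample_bilinear(y, skip.shape[2:])
            y = self.norms[i](self.convs[i](concat([y, skip], axis=1))).relu()
        y = nn.upsample_bilinear(y, out_size)
        return self.head_norm(self.head_conv(y)).relu()


class SegSeqNet(nn.Module):
    """The assembled network; all slices share one CNN."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng=rng)
        self.msa = [
            MSA(cfg.encoder_widths[i], grids=cfg.msa_grids,
                reduction=cfg.msa_reduction, proj_ratio=cfg.msa_proj_ratio,
                max_grid=cfg.msa_max_grid, rng=rng)
            if i in cfg.msa_on_skips else None
            for i in range(5)
        ]
        self.decoder = Decoder(cfg, rng=rng)
        self.gru = BiConvGRU(cfg.head_width, cfg.head_width,
                             kernel=cfg.gru_kernel, rng=rng)
        self.seq_head = nn.Conv2d(2 * cfg.head_width, cfg.num_classes, 1,
                                  rng=rng)
        # temporary per-slice head for static (stage-1) training
        self.static_head = nn.Conv2d(cfg.head_width, cfg.num_classes, 1,
                                     rng=rng)

    # -- parameter groups ----------------------------------------------
    def cnn_modules(self) -> list[nn.Module]:
        return [self.encoder, self.decoder] + [m for m in self.msa if m]

    def cnn_parameters(self) -> list[Tensor]:
        return [p for m in self.cnn_modules() for p in m.parameters()]

    def recurrent_parameters(self) -> list[Tensor]:
        return self.gru.parameters() + [self.seq_head.weight,
                                        self.seq_head.bias]

    # -- forward passes -------------------------------------------------
    def slice_features(self, x: Tensor) -> Tensor:
        """Per-slice CNN: (M, C, H, W) -> (M, head_width, H, W)."""
        skips = self.encoder(x)
        skips = [m(s) if m is not None else s
                 for m, s in zip(self.msa, skips)]
        return self.decoder(skips, x.shape[2:])

    def forward(self, batch) -> Tensor:
        """Probabilities (N, T, K, H, W) for an (N, T, C, H, W) batch."""
        data = batch.data if isinstance(batch, Batch) else batch
        x = data if isinstance(data, Tensor) else Tensor(
            np.asarray(data, dtype=np.float32))
        if x.ndim != 5:
            raise ValidationError(
                f"expected a 5-D (N, T, C, H, W) batch, got shape {x.shape}")
        n, t, c, h, w = x.shape
        feats = self.slice_features(x.reshape(n * t, c, h, w))
        feats = feats.reshape(n, t, -1, h, w)
        if self.cfg.use_recurrence:
            seq = [feats[:, k] for k in range(t)]
            states = self.gru(seq)
            logits = stack([self.seq_head(s) for s in states], axis=1)
        else:
            flat = self.static_head(feats.reshape(n * t, -1, h, w))
            logits = flat.reshape(n, t, self.cfg.num_classes, h, w)
        return nn.softmax(logits, axis=2)

    def forward_static(self, batch) -> Tensor:
        """Per-slice probabilities through the static head (recurrence
        bypassed), used for stage-1 pretraining."""
        data = batch.data if isinstance(batch, Batch) else batch
        x = data if isinstance(data, Tensor) else Tensor(
            np.asarray(data, dtype=np.float32))
        n, t, c, h, w = x.shape
        feats = self.slice_features(x.reshape(n * t, c, h, w))
        logits = self.static_head(feats)
        return nn.softmax(logits, axis=1).reshape(
            n, t, self.cfg.num_classes, h, w)

    def predict(self, batch, threshold: float | None = None) -> Prediction:
        """Forward pass plus binarisation, as a plain-numpy result."""
        probs = self.forward(batch).data
        thr = self.cfg.threshold if threshold is None else threshold
        return Prediction(probabilities=probs,
                          binary_mask=binarize(probs, thr))


def binarize(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Foreground where the foreground-class probability strictly exceeds
    the threshold (ties go to background, for determinism)."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie strictly inside (0, 1)")
    probs = probabilities.data if isinstance(probabilities, Tensor) \
        else np.asarray(probabilities)
    fg = probs[..., 1, :, :] if probs.ndim >= 3 else probs
    return (fg > threshold).astype(np.uint8)


def strip_padding(masks: np.ndarray, pad_counts) -> list[np.ndarray]:
    """Drop padded trailing positions of each sequence in an (N, T, H, W)
    stack, returning per-sequence arrays of real slices."""
    out = []
    for i, pad in enumerate(pad_counts):
        t = masks.shape[1] - int(pad)
        out.append(masks[i, :t])
    return out


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegSeqNet, path: str | Path) -> None:
    """Single-file checkpoint: parameter arrays plus the configuration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __config__=json.dumps(asdict(model.cfg)),
             **model.state_dict())


def load_checkpoint(path: str | Path) -> SegSeqNet:
    with np.load(Path(path), allow_pickle=False) as data:
        raw = json.loads(str(data["__config__"]))
        for key in ("encoder_widths", "blocks", "decoder_widths",
                    "msa_on_skips", "msa_grids"):
            raw[key] = tuple(raw[key])
        cfg = NetworkConfig(**raw)
        model = SegSeqNet(cfg)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
    return model
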