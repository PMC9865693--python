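"""Convolutional GRU over slice sequences.

The cell replaces the dense products of a textbook GRU with same-padded
convolutions, so the hidden state is a feature map that stays spatially
aligned with the input:

    z_t = sigma(Wz * x_t + Uz * h_{t-1} + bz)        (update gate)
    r_t = sigma(Wr * x_t + Ur * h_{t-1} + br)        (reset gate)
    h~_t = tanh(W * x_t + U * (r_t . h_{t-1}) + b)   (candidate)
    h_t = (1 - z_t) . h_{t-1} + z_t . h~_t

with ``*`` convolution and ``.`` elementwise multiplication.  The
bidirectional wrapper runs one cell in each slice order and concatenates
the two states per step, doubling the channel count: both neighbours of
a slice inform its segmentation.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, concat, stack
from .errors import ValidationError

__all__ = ["ConvGRUCell", "run_direction", "BiConvGRU"]


class ConvGRUCell(nn.Module):
    """One convolutional GRU cell.  Hidden state starts at zeros and is
    spatially identical to the input."""

    def __init__(self, in_channels: int, hidden_channels: int,
                 kernel: int = 3, *, rng: np.random.Generator,
                 dtype=np.float32):
        k = dict(rng=rng, dtype=dtype)
        self.hidden_channels = hidden_channels
        # input-to-hidden convolutions carry the bias terms
        self.wz = nn.Conv2d(in_channels, hidden_channels, kernel, **k)
        self.wr = nn.Conv2d(in_channels, hidden_channels, kernel, **k)
        self.w = nn.Conv2d(in_channels, hidden_channels, kernel, **k)
        self.uz = nn.Conv2d(hidden_channels, hidden_channels, kernel,
                            bias=False, **k)
        self.ur = nn.Conv2d(hidden_channels, hidden_channels, kernel,
                            bias=False, **k)
        self.u = nn.Conv2d(hidden_channels, hidden_channels, kernel,
                           bias=False, **k)

    def init_state(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        return Tensor(np.zeros((n, self.hidden_channels, h, w),
                               dtype=x.data.dtype))

    def step(self, x_t: Tensor, h_prev: Tensor) -> Tensor:
        if x_t.shape[0] != h_prev.shape[0] or x_t.shape[2:] != h_prev.shape[2:]:
            raise ValidationError(
                f"input {x_t.shape} and hidden state {h_prev.shape} are not "
                "spatially aligned")
        z = (self.wz(x_t) + self.uz(h_prev)).sigmoid()
        r = (self.wr(x_t) + self.ur(h_prev)).sigmoid()
        h_cand = (self.w(x_t) + self.u(r * h_prev)).tanh()
        return (1.0 - z) * h_prev + z * h_cand

    forward = step


def run_direction(seq: list[Tensor], cell: ConvGRUCell,
                  reverse: bool = False) -> list[Tensor]:
    """Run a cell over a slice sequence; states are returned in the
    original slice order regardless of direction."""
    if len(seq) == 0:
        raise ValidationError("cannot run a recurrence over an empty sequence")
    order = range(len(seq) - 1, -1, -1) if reverse else range(len(seq))
    h = cell.init_state(seq[0])
    states: list[Tensor] = [None] * len(seq)  # type: ignore[list-item]
    for t in order:
        h = cell.step(seq[t], h)
        states[t] = h
    return states


class BiConvGRU(nn.Module):
    """Bidirectional ConvGRU: per-step concatenation of the forward and
    backward hidden states, yielding 2 * hidden channels."""

    def __init__(self, in_channels: int, hidden_channels: int,
                 kernel: int = 3, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.fwd = ConvGRUCell(in_channels, hidden_channels, kernel,
                               rng=rng, dtype=dtype)
        self.bwd = ConvGRUCell(in_channels, hidden_channels, kernel,
                               rng=rng, dtype=dtype)

    def forward(self, seq: list[Tensor]) -> list[Tensor]:
        f = run_direction(seq, self.fwd, reverse=False)
        b = run_direction(seq, self.bwd, reverse=True)
        return [concat([ft, bt], axis=1) for ft, bt in zip(f, b)]

    def forward_tensor(self, x: Tensor) -> Tensor:
        """Convenience: (N, T, C, H, W) in, (N, T, 2*hidden, H, W) out."""
        t = x.shape[1]
        seq = [x[:, k] for k in range(t)]
        return stack(self.forward(seq), axis=1)
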