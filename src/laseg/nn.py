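"""Neural-network building blocks on top of :mod:`laseg.autodiff`.

Convolution uses an im2col forward (one BLAS matmul per layer) and a
col2im backward that scatters window gradients with one slice-add per
kernel offset, so both directions stay vectorised.  Adaptive pooling
follows the usual variable-bin convention (``start = floor(i*H/g)``,
``end = ceil((i+1)*H/g)``) so any grid size up to the spatial extent is
valid.  Bilinear resampling is expressed as two fixed interpolation
matrices applied by ``einsum``; being linear, its backward pass is the
transposed einsum.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor

__all__ = [
    "Module", "Conv2d", "GroupNorm", "Sequential", "SGD",
    "conv2d", "max_pool2d", "adaptive_avg_pool2d", "adaptive_max_pool2d",
    "upsample_bilinear", "softmax",
]


class Module:
    """Minimal parameter container with recursive discovery."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Tensor):
                        out.append((f"{full}.{i}", item))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} "
                             f"unexpected={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(p.data.dtype, copy=True)

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (n, c, oh, ow, kh, kw) -> (n, oh, ow, c*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, oh, ow, c * kh * kw)
    return cols, oh, ow


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = xshape
    oh, ow = dcols.shape[1], dcols.shape[2]
    dcols = dcols.reshape(n, oh, ow, c, kh, kw)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def _conv1x1(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Pointwise convolution without the im2col detour."""
    o, c = weight.shape[:2]
    wmat = weight.data.reshape(o, c)
    out_val = np.einsum("oc,nchw->nohw", wmat, x.data, optimize=True)
    if bias is not None:
        out_val = out_val + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_val, parents=parents)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("nohw,nchw->oc", g, x.data, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            x._accum(np.einsum("oc,nohw->nchw", wmat, g, optimize=True))
    out._backward = backward
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation over an (N, C, H, W) input."""
    o, c, kh, kw = weight.shape
    if x.shape[1] != c:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, "
                         f"kernel expects {c}")
    if kh == 1 and kw == 1 and stride == 1 and pad == 0:
        return _conv1x1(x, weight, bias)
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(o, c * kh * kw)
    out_val = cols @ wmat.T                      # (n, oh, ow, o)
    if bias is not None:
        out_val = out_val + bias.data
    out_val = out_val.transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(np.ascontiguousarray(out_val), parents=parents)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1)           # (n, oh, ow, o)
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=(0, 1, 2)))
        if weight.requires_grad:
            gw = np.tensordot(gmat, cols, axes=([0, 1, 2], [0, 1, 2]))
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            dcols = gmat @ wmat                  # (n, oh, ow, c*kh*kw)
            x._accum(_col2im(dcols, x.shape, kh, kw, stride, pad))
    out._backward = backward
    return out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *,
                 stride: int = 1, pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator, dtype=np.float32):
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        std = math.sqrt(2.0 / fan_in)            # He initialisation
        self.weight = Tensor(rng.normal(0.0, std,
                                        (out_ch, in_ch, kernel, kernel)
                                        ).astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      pad=self.pad)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int, stride: int, pad: int = 0) -> Tensor:
    n, c, h, w = x.shape
    xv = x.data
    if pad:
        xv = np.pad(xv, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                    constant_values=-np.inf)
    oh = (h + 2 * pad - kernel) // stride + 1
    ow = (w + 2 * pad - kernel) // stride + 1
    win = sliding_window_view(xv, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    win = win.reshape(n, c, oh, ow, kernel * kernel)
    idx = win.argmax(axis=-1)
    out = Tensor(np.ascontiguousarray(np.take_along_axis(
        win, idx[..., None], axis=-1)[..., 0]), parents=(x,))

    def backward(g):
        dwin = np.zeros((n, c, oh, ow, kernel * kernel), dtype=g.dtype)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dwin = dwin.reshape(n, c, oh, ow, kernel, kernel)
        dcols = dwin.transpose(0, 2, 3, 1, 4, 5).reshape(
            n, oh, ow, c * kernel * kernel)
        x._accum(_col2im(dcols, x.shape, kernel, kernel, stride, pad))
    out._backward = backward
    return out


def _bin_edges(size: int, grid: int) -> list[tuple[int, int]]:
    return [(int(math.floor(i * size / grid)),
             int(math.ceil((i + 1) * size / grid))) for i in range(grid)]


def adaptive_avg_pool2d(x: Tensor, grid: int) -> Tensor:
    n, c, h, w = x.shape
    if grid > h or grid > w:
        raise ValueError(f"adaptive pool grid {grid} exceeds spatial size "
                         f"({h}, {w})")
    hb, wb = _bin_edges(h, grid), _bin_edges(w, grid)
    out_val = np.empty((n, c, grid, grid), dtype=x.dtype)
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out_val[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
    out = Tensor(out_val, parents=(x,))

    def backward(g):
        dx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += g[:, :, i:i + 1, j:j + 1] / area
        x._accum(dx)
    out._backward = backward
    return out


def adaptive_max_pool2d(x: Tensor, grid: int) -> Tensor:
    n, c, h, w = x.shape
    if grid > h or grid > w:
        raise ValueError(f"adaptive pool grid {grid} exceeds spatial size "
                         f"({h}, {w})")
    hb, wb = _bin_edges(h, grid), _bin_edges(w, grid)
    out_val = np.empty((n, c, grid, grid), dtype=x.dtype)
    argmaxes = {}
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            block = x.data[:, :, h0:h1, w0:w1].reshape(n, c, -1)
            am = block.argmax(axis=-1)
            argmaxes[(i, j)] = am
            out_val[:, :, i, j] = np.take_along_axis(block, am[..., None],
                                                     axis=-1)[..., 0]
    out = Tensor(out_val, parents=(x,))

    def backward(g):
        dx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                bw = w1 - w0
                am = argmaxes[(i, j)]
                rows, cols = np.divmod(am, bw)
                nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
                np.add.at(dx, (nn, cc, h0 + rows, w0 + cols), g[:, :, i, j])
        x._accum(dx)
    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _interp_matrix(src: int, dst: int, dtype) -> np.ndarray:
    """Row-stochastic linear interpolation matrix mapping src -> dst samples."""
    m = np.zeros((dst, src), dtype=dtype)
    if src == 1:
        m[:, 0] = 1.0
        return m
    pos = (np.arange(dst) + 0.5) * src / dst - 0.5
    pos = np.clip(pos, 0.0, src - 1.0)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, src - 1)
    frac = pos - lo
    m[np.arange(dst), lo] += 1.0 - frac
    m[np.arange(dst), hi] += frac
    return m


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of an (N, C, H, W) tensor to ``size`` (pixel-centre
    aligned, matching the half-pixel convention)."""
    h2, w2 = size
    n, c, h, w = x.shape
    if (h, w) == (h2, w2):
        return x
    a = _interp_matrix(h, h2, x.data.dtype)
    b = _interp_matrix(w, w2, x.data.dtype)
    out = Tensor(np.einsum("ph,nchw,qw->ncpq", a, x.data, b, optimize=True),
                 parents=(x,))
    out._backward = lambda g: x._accum(
        np.einsum("ph,ncpq,qw->nchw", a, g, b, optimize=True))
    return out


# ---------------------------------------------------------------------------
# normalisation / activations
# ---------------------------------------------------------------------------

class GroupNorm(Module):
    """Group normalisation: batch-size independent, so small desk-scale
    batches behave exactly like large ones and inference needs no running
    statistics."""

    def __init__(self, channels: int, groups: int | None = None,
                 eps: float = 1e-5, dtype=np.float32):
        if groups is None:
            groups = next(g for g in (8, 4, 2, 1) if channels % g == 0)
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.groups = groups
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        xn = xn.reshape(n, c, h, w)
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


def softmax(x: Tensor, axis: int) -> Tensor:
    shifted = x - x.max_detached(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with classical momentum.

    Parameters whose ``requires_grad`` flag is off are skipped entirely, so
    freezing a sub-network is just flipping that flag.
    """

    def __init__(self, params: Sequence[Tensor], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity: dict[int, np.ndarray] = {}

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v = self._velocity.get(id(p))
            v = self.momentum * v + g if v is not None else g
            self._velocity[id(p)] = v
            p.data = p.data - self.lr * v
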