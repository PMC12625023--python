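"""Neural-network layers and optimisation on top of :mod:`segresdeit.tensor`.

Layout convention is channels-first: activations are ``(N, C, H, W)`` and
token sequences are ``(N, T, D)``.  Convolutions are stride 1 ("same" padding
for 3x3); all spatial downsampling happens in 2x2 max pooling, which records
the argmax position of every window so the decoder can unpool losslessly.

Weight initialisation is He (Kaiming) normal for every convolutional and
linear weight; biases start at zero, norm scales at one.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, make_node, softmax


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------


class Module:
    """Base class with parameter traversal and train/eval switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            params.extend(_collect(value))
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in self.__dict__.items():
            out.extend(_collect_named(value, f"{prefix}{name}"))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for value in self.__dict__.values():
            for mod in _collect_modules(value):
                mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.array(value, dtype=np.float64)
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name!r}")
        return self

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = []
        for name, value in self.__dict__.items():
            out.extend(_collect_buffers(value, f"{prefix}{name}"))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_named(value, name: str) -> list[tuple[str, Tensor]]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [(name, value)]
    if isinstance(value, Module):
        return value.named_parameters(prefix=name + ".")
    if isinstance(value, (list, tuple)):
        out = []
        for i, v in enumerate(value):
            out.extend(_collect_named(v, f"{name}.{i}"))
        return out
    return []


def _collect_modules(value) -> list["Module"]:
    if isinstance(value, Module):
        mods = [value]
        for v in value.__dict__.values():
            mods.extend(_collect_modules(v))
        return mods
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    return []


def _collect_buffers(value, name: str) -> list[tuple[str, np.ndarray]]:
    if isinstance(value, Module):
        out = []
        for attr, v in value.__dict__.items():
            out.extend(_collect_buffers(v, f"{name}.{attr}"))
        # norm running stats live as plain arrays tagged by convention
        for attr in ("running_mean", "running_var"):
            if attr in value.__dict__ and isinstance(value.__dict__[attr], np.ndarray):
                out.append((f"{name}.{attr}", value.__dict__[attr]))
        return out
    if isinstance(value, (list, tuple)):
        out = []
        for i, v in enumerate(value):
            out.extend(_collect_buffers(v, f"{name}.{i}"))
        return out
    return []


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# convolution (stride 1) via im2col / col2im
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # n,c,ho,wo,kh,kw
    ho, wo = win.shape[2], win.shape[3]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(col), ho, wo


def _col2im(col: np.ndarray, x_shape: tuple, kh: int, kw: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = hp - kh + 1, wp - kw + 1
    col = col.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    out = np.zeros((n, c, hp, wp))
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + ho, j : j + wo] += col[:, :, i, j]
    if pad:
        out = out[:, :, pad : hp - pad, pad : wp - pad]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor], pad: int) -> Tensor:
    """Stride-1 2-D cross-correlation; `pad` is symmetric zero padding."""
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {ci}")
    col, ho, wo = _im2col(x.data, kh, kw, pad)
    wmat = weight.data.reshape(o, -1)
    out = col @ wmat.T
    if bias is not None:
        out = out + bias.data
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, o)
        grads = []
        if x.requires_grad:
            dcol = g2 @ wmat
            grads.append((x, _col2im(dcol, x.shape, kh, kw, pad)))
        if weight.requires_grad:
            grads.append((weight, (g2.T @ col).reshape(weight.shape)))
        if bias is not None and bias.requires_grad:
            grads.append((bias, g2.sum(axis=0)))
        return grads

    parents = (x, weight) if bias is None else (x, weight, bias)
    return make_node(out, parents, backward)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.pad = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(he_normal(rng, (in_dim, out_dim), in_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


# ---------------------------------------------------------------------------
# pooling with indices
# ---------------------------------------------------------------------------


def max_pool_with_indices(x: Tensor, window: int = 2) -> tuple[Tensor, np.ndarray]:
    """Non-overlapping ``window x window`` max pooling.

    Returns the pooled tensor and an integer index array of the pooled shape
    whose entries are the flattened row-major position of each window's
    argmax *within the window* (ties -> first occurrence, i.e. row-major
    scan order).
    """
    if window != 2:
        raise ValueError("only 2x2 pooling windows are supported")
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    win = x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h2, w2, 4)
    idx = win.argmax(axis=-1)  # first occurrence on ties (row-major)
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dwin = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return [(x, dx.reshape(n, c, h, w))]

    return make_node(pooled, (x,), backward), idx


def max_unpool(x: Tensor, indices: np.ndarray, output_dims: tuple[int, int]) -> Tensor:
    """Place each value of `x` at its recorded argmax position; zeros elsewhere."""
    n, c, h2, w2 = x.shape
    h, w = output_dims
    if (h, w) != (2 * h2, 2 * w2):
        raise ValueError(f"output dims {output_dims} do not match pooled input {h2}x{w2}")
    if indices.shape != x.shape:
        raise ValueError("indices shape must match pooled input shape")
    if indices.min() < 0 or indices.max() > 3:
        raise ValueError("pooling indices out of range for a 2x2 window")

    def scatter(values: np.ndarray) -> np.ndarray:
        win = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(win, indices[..., None], values[..., None], axis=-1)
        out = win.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)

    def backward(g):
        gw = g.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2, w2, 4
        )
        return [(x, np.take_along_axis(gw, indices[..., None], axis=-1)[..., 0])]

    return make_node(scatter(x.data), (x,), backward)


# ---------------------------------------------------------------------------
# normalisation / dropout
# ---------------------------------------------------------------------------


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
            out = xhat * self.gamma.data[None, :, None, None] + self.beta.data[None, :, None, None]
            m = n * h * w
            gamma, beta = self.gamma, self.beta

            def backward(g):
                grads = []
                dgamma = (g * xhat).sum(axis=(0, 2, 3))
                if gamma.requires_grad:
                    grads.append((gamma, dgamma))
                if beta.requires_grad:
                    grads.append((beta, g.sum(axis=(0, 2, 3))))
                if x.requires_grad:
                    gsum = g.sum(axis=(0, 2, 3))
                    dx = (
                        gamma.data[None, :, None, None]
                        * invstd[None, :, None, None]
                        / m
                        * (
                            m * g
                            - gsum[None, :, None, None]
                            - xhat * dgamma[None, :, None, None]
                        )
                    )
                    grads.append((x, dx))
                return grads

            return make_node(out, (x, gamma, beta), backward)
        # inference: affine transform with frozen statistics
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data * invstd
        shift = self.beta.data - self.running_mean * scale
        out = x.data * scale[None, :, None, None] + shift[None, :, None, None]
        gamma, beta = self.gamma, self.beta
        rm = self.running_mean

        def backward_eval(g):
            grads = []
            if x.requires_grad:
                grads.append((x, g * scale[None, :, None, None]))
            if gamma.requires_grad:
                xhat = (x.data - rm[None, :, None, None]) * invstd[None, :, None, None]
                grads.append((gamma, (g * xhat).sum(axis=(0, 2, 3))))
            if beta.requires_grad:
                grads.append((beta, g.sum(axis=(0, 2, 3))))
            return grads

        return make_node(out, (x, gamma, beta), backward_eval)


class LayerNorm(Module):
    """Normalisation over the last dimension (token feature axis)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean) * invstd
        out = xhat * self.gamma.data + self.beta.data
        d = x.shape[-1]
        gamma, beta = self.gamma, self.beta

        def backward(g):
            grads = []
            dxhat = g * gamma.data
            if x.requires_grad:
                dx = invstd / d * (
                    d * dxhat
                    - dxhat.sum(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
                )
                grads.append((x, dx))
            if gamma.requires_grad:
                grads.append((gamma, (g * xhat).reshape(-1, d).sum(axis=0)))
            if beta.requires_grad:
                grads.append((beta, g.reshape(-1, d).sum(axis=0)))
            return grads

        return make_node(out, (x, gamma, beta), backward)


class Dropout(Module):
    """Inverted dropout; active only in training mode.

    The mask stream comes from the generator assigned to ``self.rng``
    (set by the trainer from the run seed) so runs are reproducible.
    """

    def __init__(self, rate: float):
        super().__init__()
        self.rate = float(rate)
        self.rng: np.random.Generator = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError("embed dim must be divisible by number of heads")
        self.heads = heads
        self.dim = dim
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h = self.heads
        dh = d // h
        qkv = self.qkv(x)  # (n, t, 3d)
        qkv = qkv.reshape(n, t, 3, h, dh).transpose(2, 0, 3, 1, 4)  # 3,n,h,t,dh
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        att = softmax(att, axis=-1)
        out = att @ v  # n,h,t,dh
        out = out.transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm block: x + MHSA(LN(x)); x + MLP(LN(x)) with GELU."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------


class Adam:
    """Adam with decoupled-from-nothing L2 weight decay added to gradients."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
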