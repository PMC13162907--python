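"""Neural-network building blocks (NumPy autograd backend).

Layers follow the usual conventions: a ``Module`` owns named parameters and
submodules, has ``train()`` / ``eval()`` modes, and exposes a flat
``state_dict`` of NumPy arrays for checkpointing. Initialisation is driven
by an explicit ``numpy.random.Generator`` so runs are reproducible on a
single CPU thread.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Parameter", "Linear", "Conv2d", "BatchNorm2d", "LayerNorm",
    "Dropout", "MultiHeadSelfAttention", "depthwise_conv_time",
    "conv_along_features", "avg_pool_2x2", "sinusoidal_positions",
]


# training arithmetic runs in single precision; pass float64 tensors for
# double-precision functional evaluation (dtype is preserved end to end)
DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._buffers.items()}
        for name, m in self._modules.items():
            out.update(m.named_buffers(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters().items()}
        out.update({k: v.copy() for k, v in self.named_buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        for k, p in params.items():
            p.data = np.array(state[k], dtype=np.float64)
        # buffers must be written back onto their owning module
        def _load_buf(mod: Module, prefix: str):
            for k in list(mod._buffers):
                full = prefix + k
                if full in state:
                    mod._buffers[k] = np.array(state[full], dtype=np.float64)
                    object.__setattr__(mod, k, mod._buffers[k])
            for name, sub in mod._modules.items():
                _load_buf(sub, prefix + name + ".")
        _load_buf(self, "")

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


def _conv2d_same(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """2-D cross-correlation, stride 1, same padding (odd kernels).

    im2col + GEMM: one contiguous patch copy, then BLAS for forward,
    weight gradient, and the input gradient (col2im scatter-add).
    """
    co, ci, kh, kw = weight.shape
    ph, pw = kh // 2, kw // 2
    b, c, hh, ww = x.shape
    xp_data = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    patches = np.lib.stride_tricks.sliding_window_view(
        xp_data, (kh, kw), axis=(2, 3)
    )  # (B, C, H, W, kh, kw)
    cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b * hh * ww, ci * kh * kw
    )
    wmat = weight.data.reshape(co, ci * kh * kw)
    out_data = (cols @ wmat.T).reshape(b, hh, ww, co).transpose(0, 3, 1, 2)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(b * hh * ww, co)
        gw = (g2.T @ cols).reshape(co, ci, kh, kw)
        gcols = (g2 @ wmat).reshape(b, hh, ww, ci, kh, kw)
        gxp = np.zeros_like(xp_data)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + hh, j:j + ww] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        gx = gxp[:, :, ph:ph + hh, pw:pw + ww]
        return (x, gx), (weight, gw)

    out = Tensor._make(out_data, (x, weight), backward)
    if bias is not None:
        out = out + bias.reshape(1, co, 1, 1)
    return out


class Conv2d(Module):
    """Stride-1 same-padded 2-D convolution (square odd kernel)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return _conv2d_same(x, self.weight, self.bias)


def avg_pool_2x2(x: Tensor) -> Tensor:
    """2x2 average pooling on (B, C, H, W); trailing odd row/col dropped."""
    b, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    x = x[:, :, : h2 * 2, : w2 * 2]
    x = x.reshape(b, c, h2, 2, w2, 2)
    return x.mean(axis=(3, 5))


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
            self._buffers["running_mean"] = self.running_mean
            self._buffers["running_var"] = self.running_var
        else:
            mu = self.running_mean.astype(x.data.dtype)
            var = self.running_var.astype(x.data.dtype)
        return _batchnorm2d(x, self.gamma, self.beta, mu, var, self.eps,
                            batch_stats=self.training)


def _batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, mu, var, eps,
                 batch_stats: bool) -> Tensor:
    """Fused channel normalization on (B, C, H, W) with explicit backward."""
    c = x.shape[1]
    inv = (1.0 / np.sqrt(var + eps)).astype(x.data.dtype)
    mu = np.asarray(mu, dtype=x.data.dtype)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    out_data = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        axes = (0, 2, 3)
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        scale = (gamma.data * inv).reshape(1, c, 1, 1)
        if batch_stats:
            n = g.shape[0] * g.shape[2] * g.shape[3]
            gx = scale * (
                g
                - (dbeta / n).reshape(1, c, 1, 1)
                - xhat * (dgamma / n).reshape(1, c, 1, 1)
            )
        else:
            gx = scale * g
        return (x, gx), (gamma, dgamma), (beta, dbeta)

    return Tensor._make(out_data, (x, gamma, beta), backward)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.data.dtype)
        return x * Tensor(keep / (1.0 - self.p))


class MultiHeadSelfAttention(Module):
    """Self-attention over the time axis with optional key masking.

    Input (B, T, D); ``key_mask`` (B, T) with 1 = valid. Masked positions are
    excluded as attention keys, so their content cannot influence any other
    frame's output.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        b, t, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(v: Tensor) -> Tensor:
            return v.reshape(b, t, h, dh).transpose(0, 2, 1, 3)  # (B, h, T, dh)

        q, k, v = split(self.q_proj(x)), split(self.k_proj(x)), split(self.v_proj(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))  # (B,h,T,T)
        if key_mask is not None:
            bias = np.where(np.asarray(key_mask, dtype=bool), 0.0, -1e9).astype(
                scores.data.dtype
            )
            scores = scores + Tensor(bias[:, None, None, :])
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (B, h, T, dh)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.out_proj(out)


def depthwise_conv_time(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Per-channel 1-D convolution along the time axis.

    x: (B, T, D); weight: (D, k), same padding.
    """
    dch, k = weight.shape
    p = k // 2
    xp = x.pad(((0, 0), (p, p), (0, 0)))
    patches = np.lib.stride_tricks.sliding_window_view(xp.data, k, axis=1)  # (B,T,D,k)
    out_data = np.einsum("btdk,dk->btd", patches, weight.data, optimize=True)

    def backward(g):
        gw = np.einsum("btd,btdk->dk", g, patches, optimize=True)
        gp = np.pad(g, ((0, 0), (p, p), (0, 0)))
        gpatch = np.lib.stride_tricks.sliding_window_view(gp, k, axis=1)
        gx = np.einsum("btdk,dk->btd", gpatch, weight.data[:, ::-1], optimize=True)
        return (xp, None), (weight, gw), (x, gx)

    out = Tensor._make(out_data, (xp, weight, x), backward)
    if bias is not None:
        out = out + bias
    return out


def conv_along_features(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """1-D convolution along the feature (channel) axis within each frame.

    x: (B, T, D); weight: (k,), shared across positions; same padding.
    No cross-time mixing: frame t's output depends only on frame t.
    """
    k = weight.shape[0]
    p = k // 2
    xp = x.pad(((0, 0), (0, 0), (p, p)))
    patches = np.lib.stride_tricks.sliding_window_view(xp.data, k, axis=2)  # (B,T,D,k)
    out_data = np.einsum("btdk,k->btd", patches, weight.data, optimize=True)

    def backward(g):
        gw = np.einsum("btd,btdk->k", g, patches, optimize=True)
        gp = np.pad(g, ((0, 0), (0, 0), (p, p)))
        gpatch = np.lib.stride_tricks.sliding_window_view(gp, k, axis=2)
        gx = np.einsum("btdk,k->btd", gpatch, weight.data[::-1], optimize=True)
        return (xp, None), (weight, gw), (x, gx)

    out = Tensor._make(out_data, (xp, weight, x), backward)
    if bias is not None:
        out = out + bias
    return out


def sinusoidal_positions(t: int, dim: int) -> np.ndarray:
    """Standard absolute sinusoidal positional encoding, shape (t, dim)."""
    pos = np.arange(t)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / dim)
    pe = np.zeros((t, dim))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe.astype(DTYPE)
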