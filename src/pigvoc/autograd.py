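"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The classifier in this package is a small Conformer-style network trained
with Adam; this module supplies the tape-based gradient machinery it needs.
Only the primitives the model uses are implemented, each with an explicit
backward rule. Everything is float64 CPU NumPy; no graph optimisation, no
in-place mutation of tensors that require gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph plumbing -------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in node._backward(node.grad):
                if not parent.requires_grad or g is None:
                    continue
                g = _unbroadcast(np.asarray(g), parent.data.shape)
                g = g.astype(parent.data.dtype, copy=False)
                # grads are never mutated in place, so sharing is safe
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other
        return Tensor._make(
            a.data + b.data, (a, b), lambda g: ((a, g), (b, g))
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other
        return Tensor._make(
            a.data * b.data, (a, b),
            lambda g: ((a, g * b.data), (b, g * a.data)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other
        return Tensor._make(
            a.data / b.data, (a, b),
            lambda g: ((a, g / b.data), (b, -g * a.data / (b.data ** 2))),
        )

    def __rtruediv__(self, other):
        return _as_tensor(other, self.data.dtype) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._make(
            a.data ** p, (a,), lambda g: ((a, g * p * a.data ** (p - 1)),)
        )

    def __matmul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (a, ga), (b, gb)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * out_data),))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: ((a, g / a.data),))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * 0.5 / out_data),))

    def relu(self):
        a = self
        m = a.data > 0
        return Tensor._make(a.data * m, (a,), lambda g: ((a, g * m),))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(
            out_data, (a,), lambda g: ((a, g * out_data * (1 - out_data)),)
        )

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * (1 - out_data ** 2)),))

    def silu(self):
        """x * sigmoid(x) (the Conformer activation)."""
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        out_data = a.data * s
        return Tensor._make(
            out_data, (a,), lambda g: ((a, g * (s * (1 + a.data * (1 - s)))),)
        )

    def cos(self):
        a = self
        return Tensor._make(np.cos(a.data), (a,), lambda g: ((a, -g * np.sin(a.data)),))

    def arccos(self):
        a = self
        return Tensor._make(
            np.arccos(a.data), (a,),
            lambda g: ((a, -g / np.sqrt(1.0 - a.data ** 2)),),
        )

    def clip(self, lo: float, hi: float):
        """Clip with straight-through gradient inside [lo, hi], zero outside."""
        a = self
        m = (a.data >= lo) & (a.data <= hi)
        return Tensor._make(np.clip(a.data, lo, hi), (a,), lambda g: ((a, g * m),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                return ((a, np.broadcast_to(g, a.data.shape)),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return ((a, np.broadcast_to(gg, a.data.shape)),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        # gradient flows to the (first) argmax element per slice
        idx = np.expand_dims(np.argmax(a.data, axis=axis), axis)
        out_data = np.take_along_axis(a.data, idx, axis)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(a.data)
            np.put_along_axis(full, idx, gg, axis)
            return ((a, full),)

        return Tensor._make(
            out_data if keepdims else np.squeeze(out_data, axis=axis), (a,), backward
        )

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            a.data.reshape(shape), (a,),
            lambda g: ((a, g.reshape(a.data.shape)),),
        )

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,),
            lambda g: ((a, g.transpose(inv)),),
        )

    def __getitem__(self, idx):
        a = self
        items = idx if isinstance(idx, tuple) else (idx,)
        basic = all(
            isinstance(i, (int, slice, type(None))) or i is Ellipsis for i in items
        )

        def backward(g):
            full = np.zeros_like(a.data)
            if basic:  # no duplicate targets: plain assignment suffices
                full[idx] = g
            else:
                np.add.at(full, idx, g)
            return ((a, full),)

        return Tensor._make(a.data[idx], (a,), backward)

    def pad(self, pad_width):
        """Zero-pad; pad_width as for np.pad."""
        a = self
        pw = tuple(tuple(p) for p in pad_width)

        def backward(g):
            sl = tuple(slice(p[0], g.shape[i] - p[1]) for i, p in enumerate(pw))
            return ((a, g[sl]),)

        return Tensor._make(np.pad(a.data, pw), (a,), backward)

    # -- composed helpers -----------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def _as_tensor(x, like: np.dtype | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if like is not None and np.isscalar(x):
        return Tensor(np.asarray(x, dtype=like))
    return Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            outs.append((t, g[tuple(sl)]))
        return tuple(outs)

    return Tensor._make(np.concatenate(datas, axis=axis), tensors, backward)
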