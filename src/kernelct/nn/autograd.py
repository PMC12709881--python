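"""A small reverse-mode automatic differentiation engine on NumPy.

The segmentation network and its composite loss need gradients, so this
module provides a :class:`Tensor` that records a tape of operations and
back-propagates through it.  The op set is exactly what an attention
U-Net and a focal-Tversky + boundary loss require: broadcasting
arithmetic, matmul, 2D convolution (via im2col), 2×2 max pooling,
reductions (sum / mean / max), reshaping, slicing, concatenation,
padding, and the sigmoid / ReLU / exp / log / sqrt nonlinearities.

Everything is float32 and deterministic: identical inputs and
parameters give bit-identical forward and backward results.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction --------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        requires = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=requires)
        if requires:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros(self.data.shape, dtype=np.float32)
        self.grad += _unbroadcast(grad.astype(np.float32, copy=False), self.data.shape)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        # topological order of the reachable graph
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._coerce(other)
        def backward(g):
            self._accumulate(g)
            other._accumulate(g)
        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        def backward(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        def backward(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data ** 2))
        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent
        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))
        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ------------------------------------------------
    def relu(self):
        mask = self.data > 0
        def backward(g):
            self._accumulate(g * mask)
        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))
        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            self._accumulate(g * out_data)
        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)
        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        def backward(g):
            # subgradient 0 where the argument is exactly 0 keeps the
            # boundary-loss gradient finite on flat regions
            denom = 2.0 * out_data
            safe = np.where(denom > 0, denom, 1.0)
            self._accumulate(np.where(denom > 0, g / safe, 0.0))
        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                g_exp = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g_exp, self.data.shape))
        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient splits equally among tied maxima."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        counts = mask.sum(axis=axis, keepdims=True)
        def backward(g):
            g_exp = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(mask * (g_exp / counts))
        result = out_data if keepdims else out_data.squeeze(axis=axis)
        return Tensor._make(result, (self,), backward)

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        def backward(g):
            self._accumulate(g.reshape(orig))
        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        def backward(g):
            self._accumulate(g.transpose(inv))
        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]
        def backward(g):
            full = np.zeros(self.data.shape, dtype=np.float32)
            full[key] = g
            self._accumulate(full)
        return Tensor._make(out_data, (self,), backward)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for np.pad (constant mode)."""
        out_data = np.pad(self.data, pad_width)
        slices = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, self.data.shape))
        def backward(g):
            self._accumulate(g[slices])
        return Tensor._make(out_data, (self,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) → (N, H, W, C*k*k) patch matrix for stride-1 'same' conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, h, w, k, k),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
        writeable=False,
    )
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h, w, c * k * k)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 'same'-padded 2D convolution (cross-correlation).

    ``x``: (N, C_in, H, W); ``weight``: (C_out, C_in, k, k) with odd k;
    ``bias``: (C_out,) or None.  Output (N, C_out, H, W).
    """
    k = weight.data.shape[2]
    if k % 2 != 1 or weight.data.shape[3] != k:
        raise ValueError(f"conv2d needs odd square kernels, got {weight.data.shape[2:]}")
    pad = k // 2
    n, c_in, h, w = x.data.shape
    c_out = weight.data.shape[0]
    cols = _im2col(x.data, k, pad)                       # (N,H,W,C*k*k)
    w_mat = weight.data.reshape(c_out, -1)               # (C_out, C*k*k)
    out_data = cols @ w_mat.T                            # (N,H,W,C_out)
    out_data = out_data.transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)

    def backward(g):
        g_nhwc = g.transpose(0, 2, 3, 1)                 # (N,H,W,C_out)
        if weight.requires_grad:
            gw = np.tensordot(g_nhwc, cols, axes=([0, 1, 2], [0, 1, 2]))  # (C_out, C*k*k)
            weight._accumulate(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = g_nhwc @ w_mat                       # (N,H,W,C*k*k)
            gcols = gcols.reshape(n, h, w, c_in, k, k)
            gx_pad = np.zeros((n, c_in, h + 2 * pad, w + 2 * pad), dtype=np.float32)
            for di in range(k):
                for dj in range(k):
                    gx_pad[:, :, di:di + h, dj:dj + w] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
            x._accumulate(gx_pad[:, :, pad:pad + h, pad:pad + w])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data.astype(np.float32), parents, backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2×2 max pooling, stride 2; H and W must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d needs even spatial dims, got {h}x{w}")
    patches = x.reshape(n, c, h // 2, 2, w // 2, 2)
    return patches.max(axis=5).max(axis=3)


def upsample2x_conv(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed convolution with 2×2 kernel and stride 2 (exact 2× upsample).

    ``weight``: (C_in, C_out * 4) — each input pixel expands to a 2×2
    output block.  Non-overlapping, so it reduces to a matmul plus a
    block reshape.
    """
    n, c_in, h, w = x.shape
    c_out4 = weight.shape[1]
    c_out = c_out4 // 4
    flat = x.transpose(0, 2, 3, 1).reshape(n * h * w, c_in)
    expanded = flat @ weight                              # (N*H*W, C_out*4)
    blocks = expanded.reshape(n, h, w, c_out, 2, 2)
    out = blocks.transpose(0, 3, 1, 4, 2, 5).reshape(n, c_out, 2 * h, 2 * w)
    if bias is not None:
        out = out + bias.reshape(1, c_out, 1, 1)
    return out


def upsample2x_nearest(x: Tensor) -> Tensor:
    """Nearest-neighbour 2× upsampling (interpolation alternative)."""
    n, c, h, w = x.shape
    col = x.reshape(n, c, h, 1, w, 1)
    row = concat([col, col], axis=3)
    full = concat([row, row], axis=5)
    return full.reshape(n, c, 2 * h, 2 * w)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 of an (N, C, H, W) tensor, numerically shifted."""
    shift = Tensor(x.data.max(axis=1, keepdims=True))    # constant w.r.t. grad
    e = (x - shift).exp()
    return e / e.sum(axis=1, keepdims=True)
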