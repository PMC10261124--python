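"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` accumulates gradients by reverse topological
traversal.  The op set is exactly what a 3D encoder-decoder segmentation
network needs: broadcast arithmetic, log/sigmoid/leaky-ReLU, axis reductions,
channel concatenation, strided 3D convolution and its transpose.  Convolution
is implemented as im2col + BLAS matmul, which is the fastest portable route
for small kernels on a CPU.

Dispatch helpers (:func:`log`, :func:`clip`, :func:`asum`, :func:`amean`)
accept either a Tensor or a plain ndarray, so formulas (e.g. loss functions)
can be written once and evaluated with or without gradient tracking.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

ArrayLike = Union["Tensor", np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: Tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd engine ------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = grad.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _wrap(x: ArrayLike) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def __add__(self, other: ArrayLike) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out_data = self.data ** e

        def backward(g):
            self._accum(g * e * self.data ** (e - 1.0))

        return self._make(out_data, (self,), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def log(self) -> "Tensor":
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        x = self.data
        s = np.empty_like(x)
        pos = x >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        e = np.exp(x[~pos])
        s[~pos] = e / (1.0 + e)

        def backward(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def leaky_relu(self, alpha: float = 0.1) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accum(g * np.where(mask, 1.0, alpha).astype(np.float32))

        return self._make(np.where(mask, self.data, alpha * self.data), (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only through the interior."""
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accum(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions & reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out = Tensor(out_data)
    if any(t.requires_grad or t._parents for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


# -- 3D convolution primitives (channels-first, NCXYZ) ------------------------

def _pad_zeros(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)


def _conv3d_forward(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """x: (N, C, X, Y, Z); w: (F, C, k, k, k) -> (N, F, ox, oy, oz)."""
    k = w.shape[-1]
    xp = _pad_zeros(x, pad)
    v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::stride, ::stride, ::stride]
    n, c, ox, oy, oz = v.shape[:5]
    col = v.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * ox * oy * oz, c * k ** 3)
    out = col @ w.reshape(w.shape[0], c * k ** 3).T
    return out.reshape(n, ox, oy, oz, w.shape[0]).transpose(0, 4, 1, 2, 3)


def _conv3d_dw(dout: np.ndarray, x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Gradient w.r.t. weights: (F, C, k, k, k)."""
    xp = _pad_zeros(x, pad)
    v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::stride, ::stride, ::stride]
    n, c, ox, oy, oz = v.shape[:5]
    col = v.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * ox * oy * oz, c * k ** 3)
    dflat = dout.transpose(0, 2, 3, 4, 1).reshape(n * ox * oy * oz, dout.shape[1])
    dw = dflat.T @ col
    return dw.reshape(dout.shape[1], c, k, k, k)


def _conv3d_dx(dout: np.ndarray, w: np.ndarray, x_shape, stride: int, pad: int) -> np.ndarray:
    """Gradient w.r.t. input (also the forward pass of transpose conv)."""
    n, c = x_shape[0], x_shape[1]
    k = w.shape[-1]
    spatial = tuple(s + 2 * pad for s in x_shape[2:])
    dxp = np.zeros((n, c) + spatial, dtype=np.float32)
    _, f, ox, oy, oz = dout.shape
    dflat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, f)
    dcol = dflat @ w.reshape(f, c * k ** 3)
    dcol = dcol.reshape(n, ox, oy, oz, c, k, k, k)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                dxp[:, :, i : i + ox * stride : stride,
                    j : j + oy * stride : stride,
                    l : l + oz * stride : stride] += dcol[:, :, :, :, :, i, j, l].transpose(
                        0, 4, 1, 2, 3)
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad, pad:-pad]
    return dxp


def conv3d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, pad: int = 1) -> Tensor:
    """3D convolution (cross-correlation), zero padding, square kernel."""
    out_data = _conv3d_forward(x.data, w.data, stride, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)
    k = w.data.shape[-1]

    def backward(g):
        x._accum(_conv3d_dx(g, w.data, x.data.shape, stride, pad))
        w._accum(_conv3d_dw(g, x.data, k, stride, pad))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
                     stride: int = 2, pad: int = 1, out_pad: int = 1) -> Tensor:
    """Transpose (fractionally strided) 3D convolution.

    ``w`` has shape (C_in, C_out, k, k, k).  With the defaults (k=3, stride=2,
    pad=1, out_pad=1) the spatial size exactly doubles.  Implemented as the
    adjoint of :func:`conv3d`: the forward pass is conv's input-gradient and
    vice versa.
    """
    k = w.data.shape[-1]
    n, c_in = x.data.shape[:2]
    c_out = w.data.shape[1]
    out_spatial = tuple(
        (s - 1) * stride - 2 * pad + k + out_pad for s in x.data.shape[2:]
    )
    big_shape = (n, c_out) + out_spatial
    w_conv = np.ascontiguousarray(w.data)  # (C_in, C_out, k^3): conv C_out -> C_in
    out_data = _conv3d_dx(x.data, w_conv, big_shape, stride, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)

    def backward(g):
        x._accum(_conv3d_forward(g, w_conv, stride, pad))
        w._accum(_conv3d_dw(x.data, g, k, stride, pad))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# -- type-generic helpers -----------------------------------------------------

def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def clip(x, lo: float, hi: float):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def asum(x):
    return x.sum() if isinstance(x, Tensor) else np.sum(x)


def amean(x):
    return x.mean() if isinstance(x, Tensor) else np.mean(x)
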