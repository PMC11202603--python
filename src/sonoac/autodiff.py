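"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the attenuation-regression network: broadcasted
arithmetic, matmul, 1-D/2-D convolution (im2col), reductions with axes,
shape ops and the usual activations.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` via topological sort.

The engine is deliberately small and CPU-only; it is validated against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "relu", "sigmoid", "conv1d", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _prev=(self, other), _backward=back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, _prev=(self,), _backward=back)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _prev=(self, other), _backward=back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(self.data / other.data, _prev=(self, other), _backward=back)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def back(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor(self.data**p, _prev=(self,), _backward=back)

    def __matmul__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor(self.data @ other.data, _prev=(self, other), _backward=back)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      _prev=(self,), _backward=back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, _prev=(self,), _backward=back)

    def log(self):
        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), _prev=(self,), _backward=back)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor(out_data, _prev=(self,), _backward=back)

    def abs(self):
        def back(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        return Tensor(np.abs(self.data), _prev=(self,), _backward=back)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor(self.data.reshape(shape), _prev=(self,), _backward=back)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _prev=(self,), _backward=back)

    def __getitem__(self, key):
        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        return Tensor(self.data[key], _prev=(self,), _backward=back)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _prev=tuple(tensors), _backward=back)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def back(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor(x.data * mask, _prev=(x,), _backward=back)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def back(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return Tensor(s, _prev=(x,), _backward=back)


# -- convolution ------------------------------------------------------------

def _im2col1d(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(B, C, T) -> windows (B, C, k, T_out), zero-padded."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    B, C, T = x.shape
    t_out = (T - k) // stride + 1
    s0, s1, s2 = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(B, C, k, t_out), strides=(s0, s1, s2, s2 * stride), writeable=False
    )


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """x (B, C_in, T) * w (C_out, C_in, k) -> (B, C_out, T_out)."""
    B, C, T = x.shape
    co, ci, k = w.shape
    win = _im2col1d(x.data, k, stride, pad)  # (B, C, k, To)
    out = np.einsum("bckt,ock->bot", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None]
    t_out = out.shape[-1]

    def back(g):
        if w.requires_grad:
            w._accum(np.einsum("bot,bckt->ock", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = np.zeros((B, C, T + 2 * pad))
            for kk in range(k):
                gcol = np.einsum("bot,oc->bct", g, w.data[:, :, kk], optimize=True)
                gx[:, :, kk:kk + stride * t_out:stride] += gcol
            x._accum(gx[:, :, pad:pad + T] if pad else gx)

    prev = (x, w) if b is None else (x, w, b)
    return Tensor(out, _prev=prev, _backward=back)


def _im2col2d(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    B, C, H, W = x.shape
    ho = (H - kh) // stride + 1
    wo = (W - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(B, C, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride), writeable=False
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """x (B, C_in, H, W) * w (C_out, C_in, kh, kw) -> (B, C_out, Ho, Wo)."""
    B, C, H, W = x.shape
    co, ci, kh, kw = w.shape
    win = _im2col2d(x.data, kh, kw, stride, pad)
    out = np.einsum("bcklhw,ockl->bohw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]
    ho, wo = out.shape[-2:]

    def back(g):
        if w.requires_grad:
            w._accum(np.einsum("bohw,bcklhw->ockl", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
            for i in range(kh):
                for j in range(kw):
                    gcol = np.einsum("bohw,oc->bchw", g, w.data[:, :, i, j], optimize=True)
                    gx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += gcol
            x._accum(gx[:, :, pad:pad + H, pad:pad + W] if pad else gx)

    prev = (x, w) if b is None else (x, w, b)
    return Tensor(out, _prev=prev, _backward=back)
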