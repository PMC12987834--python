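"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides just enough of a tensor framework to express and train
the small convolutional architectures in :mod:`mvfuse.models`: broadcasting
arithmetic, matrix multiplication, 2-D convolution (im2col), the usual
pointwise nonlinearities, axis reductions, softmax, and an Adam optimizer.

Design notes
------------
* Arrays are ``float32`` throughout; gradients accumulate in the same dtype.
* The graph is built eagerly; ``Tensor.backward`` runs a topological sweep.
* There is no in-place mutation of tensors that participate in a graph;
  optimizers mutate ``Parameter.data`` directly between steps.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "conv2d",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g.astype(np.float32, copy=False)

    # -- autograd engine ------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * (other ** -1.0)

    def __pow__(self, k: float):
        k = float(k)
        out_data = self.data ** k

        def bwd(g):
            if self.requires_grad:
                self._accum(g * k * self.data ** (k - 1.0))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    # -- pointwise nonlinearities --------------------------------------------

    def relu(self, slope: float = 0.0) -> "Tensor":
        """ReLU; a small negative ``slope`` makes it leaky (no dead units)."""
        mask = self.data > 0
        scale = np.where(mask, np.float32(1.0), np.float32(slope))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * scale)

        return Tensor(self.data * scale, parents=(self,), backward=bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through the interior only."""
        mask = (self.data > lo) & (self.data < hi)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bwd)

    # -- reductions & shape ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; the gradient flows to the first arg-max."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        idx = np.expand_dims(self.data.argmax(axis=axis), axis)

        def bwd(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, idx, g, axis=axis)
            self._accum(full)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                inner = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - inner))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bwd)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bwd)


class Parameter(Tensor):
    """A trainable tensor (``requires_grad=True`` leaf)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum (value-commutative; ties route the gradient to a)."""
    mask = a.data >= b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.shape))

    return Tensor(np.where(mask, a.data, b.data), parents=(a, b), backward=bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(data, parents=tuple(tensors), backward=bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) via im2col.

    Parameters
    ----------
    x : Tensor, shape ``(N, C, H, W)``
    w : Tensor, shape ``(O, C, kh, kw)``
    b : Tensor, shape ``(O,)``
    """
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"conv2d: input has {C} channels, kernel expects {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, Ho, Wo, kh, kw) -> (N*Ho*Wo, C*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(O, -1)
    out = cols @ wmat.T
    out = out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2) + b.data.reshape(1, O, 1, 1)

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.shape))
        if b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros((N, C, Hp, Wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += dcols[:, :, :, :, i, j]
            x._accum(dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp)

    return Tensor(out, parents=(x, w, b), backward=bwd)


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            upd = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                upd = upd + self.lr * self.weight_decay * p.data  # decoupled decay
            p.data -= upd.astype(np.float32)
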