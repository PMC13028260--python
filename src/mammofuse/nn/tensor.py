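"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network components in this package (depthwise-convolution blocks,
shifted-window attention, cross-attention fusion, the prototype head) need
gradients for training and for Grad-CAM.  This module provides a small tape
based autodiff engine: a :class:`Tensor` wraps a ``numpy`` array, records the
operation that produced it, and :meth:`Tensor.backward` runs the reverse
sweep.  Only the operations the model needs are implemented; gradients are
validated against finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np
from scipy.special import erf

DEFAULT_DTYPE = np.float64

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference / EMA eval)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray):
        grad = np.asarray(grad, dtype=DEFAULT_DTYPE)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return self.data.item()

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accumulate(-g))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def pow(self, exponent: float):
        a, n = self, float(exponent)

        def bw(g):
            a._accumulate(g * n * np.power(a.data, n - 1.0))

        return Tensor._make(np.power(a.data, n), (a,), bw)

    __pow__ = pow

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accumulate(g * out_data))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accumulate(g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accumulate(g * 0.5 / out_data))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: a._accumulate(g * mask))

    def clamp_min(self, value: float):
        a = self
        mask = a.data >= value
        out = np.where(mask, a.data, value)
        return Tensor._make(out, (a,), lambda g: a._accumulate(g * mask))

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))

        def bw(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            a._accumulate(g * (cdf + x * pdf))

        return Tensor._make(x * cdf, (a,), bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.shape[i] for i in axis]))
        else:
            n = self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: a._accumulate(g.reshape(old))
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: a._accumulate(g.transpose(inv))
        )

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bw)

    def take(self, indices: np.ndarray, axis: int = 0):
        """Integer gather along one axis (used by the relative-position table)."""
        a = self
        indices = np.asarray(indices)

        def bw(g):
            full = np.zeros_like(a.data)
            sl = [slice(None)] * a.ndim
            # scatter-add via np.add.at on the chosen axis
            np.add.at(full, tuple(sl[:axis]) + (indices,), g)
            a._accumulate(full)

        return Tensor._make(np.take(a.data, indices, axis=axis), (a,), bw)

    def roll(self, shift, axis):
        a = self
        neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
        return Tensor._make(
            np.roll(a.data, shift, axis=axis),
            (a,),
            lambda g: a._accumulate(np.roll(g, neg, axis=axis)),
        )

    def pad2d(self, pad_h: tuple, pad_w: tuple):
        """Zero-pad the trailing two axes."""
        a = self
        width = [(0, 0)] * (a.ndim - 2) + [pad_h, pad_w]

        def bw(g):
            sl = [slice(None)] * (a.ndim - 2)
            sl += [
                slice(pad_h[0], g.shape[-2] - pad_h[1]),
                slice(pad_w[0], g.shape[-1] - pad_w[1]),
            ]
            a._accumulate(g[tuple(sl)])

        return Tensor._make(np.pad(a.data, width), (a,), bw)

    # --------------------------------------------------------------- contract
    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    # --------------------------------------------------------------- softmax
    def softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p.squeeze(axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bw)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """Grouped 2-D convolution (cross-correlation), NCHW layout.

    ``groups == in_channels`` gives the depthwise convolution used by the
    local-encoder blocks; ``groups == 1`` the ordinary pointwise/stem convs.
    """
    x = Tensor._wrap(x)
    n, c_in, h, w = x.shape
    c_out, c_in_g, kh, kw = weight.shape
    if c_in_g * groups != c_in or c_out % groups != 0:
        raise ValueError(
            f"channel mismatch: input {c_in}, weight {weight.shape}, groups {groups}"
        )
    c_out_g = c_out // groups
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    h_out = (xp.shape[2] - kh) // s + 1
    w_out = (xp.shape[3] - kw) // s + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::s, ::s]  # (n, c_in, h_out, w_out, kh, kw)
    xv = view.reshape(n, groups, c_in_g, h_out, w_out, kh, kw)
    wv = weight.data.reshape(groups, c_out_g, c_in_g, kh, kw)
    out = np.einsum("ngihwkl,goikl->ngohw", xv, wv, optimize=True)
    out = out.reshape(n, c_out, h_out, w_out)
    if bias is not None:
        out = out + bias.data.reshape(1, c_out, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        go = g.reshape(n, groups, c_out_g, h_out, w_out)
        if weight.requires_grad:
            gw = np.einsum("ngihwkl,ngohw->goikl", xv, go, optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx_pad = np.zeros_like(xp).reshape(n, groups, c_in_g, *xp.shape[2:])
            for k in range(kh):
                for l in range(kw):
                    contrib = np.einsum(
                        "ngohw,goi->ngihw", go, wv[:, :, :, k, l], optimize=True
                    )
                    gx_pad[:, :, :, k : k + s * h_out : s, l : l + s * w_out : s] += contrib
            gx_pad = gx_pad.reshape(xp.shape)
            if padding:
                gx_pad = gx_pad[:, :, padding:-padding or None, padding:-padding or None]
            x._accumulate(gx_pad)

    return Tensor._make(out, parents, bw)
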