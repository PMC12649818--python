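"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the spectrogram classifiers need:
broadcasting arithmetic, matmul, grouped/strided 2-D convolution, max and
global-average pooling, reductions for batch-norm statistics, the usual
pointwise nonlinearities, and a numerically stable binary cross-entropy on
logits.  Gradients flow through a dynamically recorded tape; `backward()`
walks the tape in reverse topological order.

Everything is float64.  The engine is deliberately small: no views with
shared storage, no in-place ops, 2-D matmul only.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "astensor",
    "relu",
    "sigmoid",
    "silu",
    "conv2d",
    "maxpool2d",
    "global_avg_pool",
    "binary_cross_entropy_with_logits",
]


def _pair(v) -> tuple[int, int]:
    if isinstance(v, (int, np.integer)):
        return int(v), int(v)
    a, b = v
    return int(a), int(b)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _add_grad(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._add_grad(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        a, b = self, other

        def bw(g):
            a._add_grad(_unbroadcast(g, a.data.shape))
            b._add_grad(_unbroadcast(g, b.data.shape))

        return _make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._add_grad(-g)

        return _make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        a, b = self, other

        def bw(g):
            a._add_grad(_unbroadcast(g * b.data, a.data.shape))
            b._add_grad(_unbroadcast(g * a.data, b.data.shape))

        return _make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        a, b = self, other

        def bw(g):
            a._add_grad(_unbroadcast(g / b.data, a.data.shape))
            b._add_grad(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return _make(a.data / b.data, (a, b), bw)

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bw(g):
            a._add_grad(g * p * a.data ** (p - 1.0))

        return _make(out_data, (a,), bw)

    def __matmul__(self, other):
        other = astensor(other)
        a, b = self, other
        if a.data.ndim != 2 or b.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def bw(g):
            a._add_grad(g @ b.data.T)
            b._add_grad(a.data.T @ g)

        return _make(a.data @ b.data, (a, b), bw)

    # -- shape / reduction --------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            a._add_grad(g.reshape(old))

        return _make(a.data.reshape(shape), (a,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)
        axes = _norm_axes(axis, a.data.ndim)

        def bw(g):
            if not keepdims and axes is not None:
                g = np.expand_dims(g, axes)
            a._add_grad(np.broadcast_to(g, a.data.shape))

        return _make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        axes = _norm_axes(axis, self.data.ndim)
        n = (
            self.data.size
            if axes is None
            else int(np.prod([self.data.shape[i] for i in axes]))
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


class Parameter(Tensor):
    """A Tensor that a Module registers as trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _norm_axes(axis, ndim):
    if axis is None:
        return None
    if isinstance(axis, (int, np.integer)):
        axis = (int(axis),)
    return tuple(a % ndim for a in axis)


def _make(data, parents: Sequence[Tensor], backward):
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- nonlinearities ----------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = astensor(x)
    mask = x.data > 0

    def bw(g):
        x._add_grad(g * mask)

    return _make(np.where(mask, x.data, 0.0), (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    x = astensor(x)
    s = _sigmoid(x.data)

    def bw(g):
        x._add_grad(g * s * (1.0 - s))

    return _make(s, (x,), bw)


def silu(x: Tensor) -> Tensor:
    """x * sigmoid(x) (a.k.a. swish)."""
    x = astensor(x)
    s = _sigmoid(x.data)

    def bw(g):
        x._add_grad(g * s * (1.0 + x.data * (1.0 - s)))

    return _make(x.data * s, (x,), bw)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# -- convolution / pooling ---------------------------------------------

def _im2col_view(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    B, C, Hp, Wp = xp.shape
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(
            f"input spatial size {Hp}x{Wp} too small for kernel {kh}x{kw} stride {sh}x{sw}"
        )
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (B, C, kh, kw, Ho, Wo), (s0, s1, s2, s3, s2 * sh, s3 * sw)
    )
    return view, Ho, Wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride=1, padding=0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, zero padding, optional groups."""
    x = astensor(x)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, C, H, W = x.data.shape
    Co, Cg, kh, kw = weight.data.shape
    if C != Cg * groups:
        raise ValueError(f"conv2d: {C} input channels, weight expects {Cg * groups}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    view, Ho, Wo = _im2col_view(xp, kh, kw, sh, sw)
    L = Ho * Wo
    K = Cg * kh * kw
    # (B, C*kh*kw, L) columns; copies out of the strided view
    cols = np.ascontiguousarray(view).reshape(B, C * kh * kw, L)
    if groups == 1:  # dense conv: plain BLAS matmul
        w2 = weight.data.reshape(Co, K)
        out = np.matmul(w2, cols)
    else:  # grouped / depthwise conv
        colsg = cols.reshape(B, groups, K, L)
        wg = weight.data.reshape(groups, Co // groups, K)
        out = np.einsum("gok,bgkl->bgol", wg, colsg)
    out = out.reshape(B, Co, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, Co, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        if bias is not None:
            bias._add_grad(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            gg = g.reshape(B, Co, L)
            if weight.requires_grad:
                dw = np.tensordot(gg, cols, axes=([0, 2], [0, 2]))
                weight._add_grad(dw.reshape(weight.data.shape))
            if x.requires_grad:
                dcols = np.matmul(weight.data.reshape(Co, K).T, gg)
        else:
            gg = g.reshape(B, groups, Co // groups, L)
            colsg = cols.reshape(B, groups, K, L)
            wg = weight.data.reshape(groups, Co // groups, K)
            if weight.requires_grad:
                dw = np.einsum("bgol,bgkl->gok", gg, colsg)
                weight._add_grad(dw.reshape(weight.data.shape))
            if x.requires_grad:
                dcols = np.einsum("gok,bgol->bgkl", wg, gg).reshape(B, C * kh * kw, L)
        if x.requires_grad:
            dcols = dcols.reshape(B, C, kh, kw, Ho, Wo)
            dxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[:, :, ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw] += dcols[:, :, ki, kj]
            x._add_grad(dxp[:, :, ph:ph + H, pw:pw + W])

    return _make(out, parents, bw)


def maxpool2d(x: Tensor, kernel, stride=None, padding=0) -> Tensor:
    x = astensor(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride) if stride is not None else (kh, kw)
    ph, pw = _pair(padding)
    B, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                constant_values=-np.inf)
    view, Ho, Wo = _im2col_view(xp, kh, kw, sh, sw)
    patches = np.ascontiguousarray(view).reshape(B, C, kh * kw, Ho, Wo)
    idx = patches.argmax(axis=2)
    out = np.take_along_axis(patches, idx[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        dxp = np.zeros_like(xp)
        for p in range(kh * kw):
            ki, kj = divmod(p, kw)
            dxp[:, :, ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw] += np.where(idx == p, g, 0.0)
        x._add_grad(dxp[:, :, ph:ph + H, pw:pw + W])

    return _make(out, (x,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C) spatial mean."""
    return x.mean(axis=(2, 3))


# -- loss --------------------------------------------------------------

def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray,
                                     pos_weight: float | None = None) -> Tensor:
    """Mean Bernoulli negative log-likelihood on raw logits.

    Numerically stable via log(1+e^z) = logaddexp(0, z).  `pos_weight`
    multiplies the positive-class term (optional imbalance correction).
    """
    logits = astensor(logits)
    y = np.asarray(targets, dtype=np.float64).reshape(logits.data.shape)
    z = logits.data
    p = 1.0 if pos_weight is None else float(pos_weight)
    log_s = -np.logaddexp(0.0, -z)       # log sigmoid(z)
    log_1ms = -np.logaddexp(0.0, z)      # log (1 - sigmoid(z))
    per = -(p * y * log_s + (1.0 - y) * log_1ms)
    n = per.size
    out_data = per.mean()

    def bw(g):
        s = _sigmoid(z)
        dz = (-(p * y) * (1.0 - s) + (1.0 - y) * s) / n
        logits._add_grad(g * dz)

    return _make(out_data, (logits,), bw)
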