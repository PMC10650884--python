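"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed for 1-D convolutional
time-series networks: pointwise and depthwise convolutions, batch
normalization, ReLU, max/average pooling, concatenation and the two
training losses (masked MSE, binary cross-entropy with logits).

Convolutions with k > 1 are evaluated through FFT-based correlation
(``scipy.signal.fftconvolve``) so no im2col buffer is ever
materialized; pointwise (k = 1) convolutions reduce to BLAS matmuls.
All arithmetic is float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

__all__ = [
    "Tensor",
    "add",
    "relu",
    "concat",
    "reshape",
    "pointwise_conv",
    "depthwise_conv",
    "batchnorm",
    "maxpool_same",
    "adaptive_avg_pool",
    "mean_over_time",
    "masked_mse",
    "bce_with_logits",
]


class Tensor:
    """A NumPy array plus gradient bookkeeping for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for long conv stacks
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
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


def _from_op(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _sum_to_shape(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reverse NumPy broadcasting: reduce gradient g to `shape`."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        return _sum_to_shape(g, a.data.shape), _sum_to_shape(g, b.data.shape)

    return _from_op(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        return (g * mask,)

    return _from_op(x.data * mask, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _from_op(data, tuple(tensors), backward)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    orig = x.data.shape

    def backward(g):
        return (g.reshape(orig),)

    return _from_op(x.data.reshape(shape), (x,), backward)


def pointwise_conv(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1x1 convolution: x (B,C,L), w (O,C), optional bias (O,)."""
    data = np.einsum("oc,bcl->bol", w.data, x.data, optimize=True)
    if b is not None:
        data = data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gx = np.einsum("oc,bol->bcl", w.data, g, optimize=True)
        gw = np.einsum("bol,bcl->oc", g, x.data, optimize=True)
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2))

    return _from_op(data, parents, backward)


def depthwise_conv(x: Tensor, w: Tensor) -> Tensor:
    """Per-channel ("depthwise") correlation with SAME padding.

    x: (B, C, L); w: (C, k) with k odd. out[b,c,t] = sum_j x'[b,c,t+j] w[c,j]
    where x' is x zero-padded by k//2 on both sides.
    """
    c, k = w.data.shape
    if k % 2 != 1:
        raise ValueError("depthwise kernel length must be odd")
    p = k // 2
    L = x.data.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    data = fftconvolve(xp, w.data[None, :, ::-1], mode="valid", axes=2)

    def backward(g):
        gxp = fftconvolve(g, w.data[None, :, :], mode="full", axes=2)
        gx = gxp[:, :, p : p + L]
        gw_full = fftconvolve(xp, g[:, :, ::-1], mode="full", axes=2)
        gw = gw_full[:, :, L - 1 : L - 1 + k].sum(axis=0)
        return gx, gw

    return _from_op(data, (x, w), backward)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (batch, time) per channel.

    `running_mean`/`running_var` are updated in place while training.
    """
    if training:
        mu = x.data.mean(axis=(0, 2))
        var = x.data.var(axis=(0, 2))
        m = x.data.shape[0] * x.data.shape[2]
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None]) * ivstd[None, :, None]
    data = gamma.data[None, :, None] * xhat + beta.data[None, :, None]

    def backward(g):
        ggamma = (g * xhat).sum(axis=(0, 2))
        gbeta = g.sum(axis=(0, 2))
        gxhat = g * gamma.data[None, :, None]
        if training:
            m = g.shape[0] * g.shape[2]
            s1 = gxhat.sum(axis=(0, 2))
            s2 = (gxhat * xhat).sum(axis=(0, 2))
            gx = (
                gxhat
                - s1[None, :, None] / m
                - xhat * s2[None, :, None] / m
            ) * ivstd[None, :, None]
        else:
            gx = gxhat * ivstd[None, :, None]
        return gx, ggamma, gbeta

    return _from_op(data, (x, gamma, beta), backward)


def maxpool_same(x: Tensor, k: int = 3) -> Tensor:
    """Max pooling with stride 1 and SAME padding (odd k)."""
    if k % 2 != 1:
        raise ValueError("pool size must be odd")
    p = k // 2
    B, C, L = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf)
    win = sliding_window_view(xp, k, axis=2)
    idx = win.argmax(axis=3)
    data = np.take_along_axis(win, idx[..., None], axis=3)[..., 0]

    def backward(g):
        gxp = np.zeros((B, C, L + 2 * p))
        bi, ci, ti = np.indices((B, C, L))
        np.add.at(gxp, (bi, ci, ti + idx), g)
        return (gxp[:, :, p : p + L],)

    return _from_op(data, (x,), backward)


def _pool_bins(L: int, T: int) -> list[tuple[int, int]]:
    return [(int(np.floor(b * L / T)), int(np.ceil((b + 1) * L / T))) for b in range(T)]


def adaptive_avg_pool(x: Tensor, T: int) -> Tensor:
    """Average pooling to a fixed output length T (PyTorch bin convention)."""
    B, C, L = x.data.shape
    if T >= L:
        return x
    bins = _pool_bins(L, T)
    data = np.empty((B, C, T))
    for b, (s, e) in enumerate(bins):
        data[:, :, b] = x.data[:, :, s:e].mean(axis=2)

    def backward(g):
        gx = np.zeros((B, C, L))
        for b, (s, e) in enumerate(bins):
            gx[:, :, s:e] += g[:, :, b : b + 1] / (e - s)
        return (gx,)

    return _from_op(data, (x,), backward)


def mean_over_time(x: Tensor) -> Tensor:
    L = x.data.shape[2]

    def backward(g):
        return (np.repeat(g[:, :, None], L, axis=2) / L,)

    return _from_op(x.data.mean(axis=2), (x,), backward)


def masked_mse(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean squared error over masked positions only.

    mask is boolean, True = masked (= scored). Raises if nothing is masked.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("masked_mse: mask selects no positions")
    diff = (pred.data - target) * mask
    data = np.array((diff**2).sum() / n)

    def backward(g):
        return (g * 2.0 * diff / n,)

    return _from_op(data, (pred,), backward)


def bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    z = logits.data
    y = np.asarray(y, dtype=np.float64)
    loss = np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
    data = np.array(loss.mean())
    p = 1.0 / (1.0 + np.exp(-z))

    def backward(g):
        return (g * (p - y) / y.size,)

    return _from_op(data, (logits,), backward)
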