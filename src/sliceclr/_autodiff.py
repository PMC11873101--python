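"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the slice pipeline needs: dense linear
layers, layer normalization, GELU, patchify and depthwise convolutions,
global average pooling, row-wise L2 normalization, log-sum-exp and
softmax cross-entropy — each with an analytic backward pass — plus an
AdamW optimizer. All arithmetic is float64.

The public surface is the :class:`Tensor` class (build a graph by calling
the module-level ops, then ``loss.backward()``) and :class:`AdamW`.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor",
    "AdamW",
    "add",
    "mul",
    "sub",
    "scale",
    "matmul",
    "transpose2d",
    "linear",
    "gelu",
    "layer_norm",
    "patch_conv",
    "depthwise_conv",
    "global_avg_pool",
    "l2_normalize_rows",
    "logsumexp_rows",
    "gather_pairs",
    "mean_all",
    "softmax_cross_entropy",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from a scalar tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _node(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None] | None) -> Tensor:
    out = Tensor(data)
    tracked = tuple(p for p in parents if p.requires_grad or p._parents)
    if tracked and backward is not None:
        out.requires_grad = True
        out._parents = tracked
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / linear algebra


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _node(y, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    y = a.data - b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _node(y, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    y = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(y, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    y = a.data * c

    def backward(g):
        _accum(a, g * c)

    return _node(y, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    y = a.data @ b.data

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _node(y, (a, b), backward)


def transpose2d(a: Tensor) -> Tensor:
    y = a.data.T.copy()

    def backward(g):
        _accum(a, g.T)

    return _node(y, (a,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map over the last axis: ``y[..., j] = sum_i x[..., i] w[i, j] + b[j]``."""
    y = x.data @ w.data
    if b is not None:
        y = y + b.data

    def backward(g):
        _accum(x, g @ w.data.T)
        _accum(w, x.data.reshape(-1, x.data.shape[-1]).T @ g.reshape(-1, g.shape[-1]))
        if b is not None:
            _accum(b, g.reshape(-1, g.shape[-1]).sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _node(y, parents, backward)


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit, exact (erf) form."""
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    y = x.data * cdf

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
        _accum(x, g * (cdf + x.data * pdf))

    return _node(y, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = xhat * gamma.data + beta.data

    def backward(g):
        n = x.data.shape[-1]
        gxhat = g * gamma.data
        # d xhat / d x folded analytically
        dx = inv * (gxhat
                    - gxhat.mean(axis=-1, keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True))
        _accum(x, dx)
        red = tuple(range(g.ndim - 1))
        _accum(gamma, (g * xhat).sum(axis=red))
        _accum(beta, g.sum(axis=red))

    return _node(y, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# convolutions (channels-last layout: B, H, W, C)


def patch_conv(x: Tensor, w: Tensor, b: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k convolution with stride k (patchify).

    ``w`` has shape (k*k*C_in, C_out). Spatial extents not divisible by k
    are cropped at the high-index edge, matching strided-conv flooring.
    """
    B, H, W, C = x.data.shape
    Ho, Wo = H // k, W // k
    xc = x.data[:, : Ho * k, : Wo * k, :]
    patches = xc.reshape(B, Ho, k, Wo, k, C).transpose(0, 1, 3, 2, 4, 5)
    flat = patches.reshape(B, Ho, Wo, k * k * C)
    y = flat @ w.data + b.data

    def backward(g):
        gflat = g.reshape(-1, g.shape[-1])
        _accum(w, flat.reshape(-1, k * k * C).T @ gflat)
        _accum(b, gflat.sum(axis=0))
        gp = (g @ w.data.T).reshape(B, Ho, Wo, k, k, C).transpose(0, 1, 3, 2, 4, 5)
        gx = np.zeros_like(x.data)
        gx[:, : Ho * k, : Wo * k, :] = gp.reshape(B, Ho * k, Wo * k, C)
        _accum(x, gx)

    return _node(y, (x, w, b), backward)


def depthwise_conv(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Depthwise 2D convolution, stride 1, 'same' zero padding.

    ``w`` has shape (kh, kw, C); each channel is filtered independently.
    """
    kh, kw, C = w.data.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # B,H,W,C,kh,kw
    y = np.einsum("bhwcij,ijc->bhwc", win, w.data, optimize=True) + b.data

    def backward(g):
        _accum(w, np.einsum("bhwcij,bhwc->ijc", win, g, optimize=True))
        _accum(b, g.sum(axis=(0, 1, 2)))
        # full correlation with the flipped kernel gives dL/dx
        gp = np.pad(g, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(1, 2))
        wf = w.data[::-1, ::-1, :]
        _accum(x, np.einsum("bhwcij,ijc->bhwc", gwin, wf, optimize=True))

    return _node(y, (x, w, b), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the two spatial axes of a (B, H, W, C) tensor."""
    B, H, W, C = x.data.shape
    y = x.data.mean(axis=(1, 2))

    def backward(g):
        _accum(x, np.broadcast_to(g[:, None, None, :] / (H * W), x.data.shape).copy())

    return _node(y, (x,), backward)


# ---------------------------------------------------------------------------
# contrastive-loss building blocks


def l2_normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    nrm = np.sqrt((x.data * x.data).sum(axis=1, keepdims=True)) + eps
    y = x.data / nrm

    def backward(g):
        dot = (g * y).sum(axis=1, keepdims=True)
        _accum(x, (g - y * dot) / nrm)

    return _node(y, (x,), backward)


def logsumexp_rows(x: Tensor) -> Tensor:
    m = x.data.max(axis=1, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=1, keepdims=True)
    y = (m + np.log(s)).ravel()

    def backward(g):
        _accum(x, (e / s) * g[:, None])

    return _node(y, (x,), backward)


def gather_pairs(x: Tensor, cols: np.ndarray) -> Tensor:
    """``y[i] = x[i, cols[i]]``."""
    rows = np.arange(x.data.shape[0])
    y = x.data[rows, cols]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[rows, cols] = g
        _accum(x, gx)

    return _node(y, (x,), backward)


def mean_all(x: Tensor) -> Tensor:
    y = np.asarray(x.data.mean())

    def backward(g):
        _accum(x, np.full_like(x.data, float(g) / x.data.size))

    return _node(y, (x,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row-wise softmax."""
    m = logits.data.max(axis=1, keepdims=True)
    e = np.exp(logits.data - m)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    rows = np.arange(n)
    y = np.asarray(-np.mean(np.log(p[rows, labels] + 1e-300)))

    def backward(g):
        gp = p.copy()
        gp[rows, labels] -= 1.0
        _accum(logits, gp * (float(g) / n))

    return _node(y, (logits,), backward)


# ---------------------------------------------------------------------------
# optimizer


class AdamW:
    """AdamW with decoupled weight decay over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_annealing_lr(base_lr: float, epoch: int, period: int) -> float:
    """Cosine-annealed learning rate with warm restarts every ``period`` epochs.

    At epoch 0, ``period``, ``2*period``, ... the rate restarts at ``base_lr``
    and decays toward zero within each period.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    phase = (epoch % period) / period
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * phase))
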