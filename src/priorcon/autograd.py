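"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's encoders and losses need:
dense/conv layers, ReLU, pooling, row-normalisation, concatenation and a
numerically stable log-sum-exp. Tensors carry float32 data by default;
gradients are accumulated into ``Tensor.grad`` by :func:`backward`.

The design is intentionally small: a ``Tensor`` records its parents and a
closure that maps the output gradient to parent gradients; ``backward``
walks the graph in reverse topological order. No in-place mutation of
tensor data is permitted after construction.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.parents = parents if self.requires_grad else ()
        self._backward = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor that always requires a gradient.

    Floating dtypes are preserved (float64 supports finite-difference
    checks); anything else is cast to float32, the training dtype.
    """

    def __init__(self, data: np.ndarray):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)
        super().__init__(data, requires_grad=True)


def constant(data: np.ndarray, dtype=np.float32) -> Tensor:
    return Tensor(np.asarray(data, dtype=dtype))


def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad:
                stack.append((p, False))
    return order


def backward(root: Tensor) -> None:
    """Accumulate d(root)/d(leaf) into every reachable leaf's ``.grad``."""
    if root.data.size != 1:
        raise ValueError("backward() expects a scalar loss tensor")
    root._accumulate(np.ones_like(root.data))
    for node in reversed(_topo_order(root)):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def zero_grads(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / linear algebra ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward_fn=bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward_fn=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward_fn=bwd)


def scale(a: Tensor, s: float) -> Tensor:
    out_data = a.data * s

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * s)

    return Tensor(out_data, parents=(a,), backward_fn=bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward_fn=bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(out_data, parents=(a,), backward_fn=bwd)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    out_data = a.data.reshape(shape)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return Tensor(out_data, parents=(a,), backward_fn=bwd)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(gp)

    return Tensor(out_data, parents=tuple(tensors), backward_fn=bwd)


def mean_all(a: Tensor) -> Tensor:
    out_data = np.asarray(a.data.mean(), dtype=a.data.dtype)
    n = a.data.size

    def bwd(g):
        if a.requires_grad:
            a._accumulate(np.full(a.data.shape, float(g) / n, dtype=a.data.dtype))

    return Tensor(out_data, parents=(a,), backward_fn=bwd)


def sum_axis(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if a.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

    return Tensor(out_data, parents=(a,), backward_fn=bwd)


def l2_normalize(a: Tensor, axis: int = 1, eps: float = 1e-12) -> Tensor:
    """Row-normalise to unit L2 norm along ``axis``."""
    norms = np.sqrt((a.data**2).sum(axis=axis, keepdims=True)) + eps
    out_data = a.data / norms

    def bwd(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate((g - out_data * dot) / norms)

    return Tensor(out_data, parents=(a,), backward_fn=bwd)


def layer_norm(a: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-row standardisation (zero mean, unit variance over features).

    Removes the common-mode component that pooled ReLU features carry,
    without which unit-normalised codes of unrelated inputs start out
    nearly parallel and contrastive gradients vanish.
    """
    mu = a.data.mean(axis=1, keepdims=True)
    xc = a.data - mu
    var = (xc**2).mean(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    out_data = xc * inv
    n = a.data.shape[1]

    def bwd(g):
        if a.requires_grad:
            gm = g.mean(axis=1, keepdims=True)
            gy = (g * out_data).mean(axis=1, keepdims=True)
            a._accumulate(inv * (g - gm - out_data * gy))

    return Tensor(out_data, parents=(a,), backward_fn=bwd)


def batch_norm_train(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Batch normalisation over all axes but the channel axis (axis 1).

    Returns ``(out, batch_mean, batch_var)``; the statistics are plain
    arrays for the caller's running-average update.
    """
    axes = (0,) + tuple(range(2, a.data.ndim))
    m = a.data.size // a.data.shape[1]
    mu = a.data.mean(axis=axes, keepdims=True)
    var = a.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    shape = [1] * a.data.ndim
    shape[1] = a.data.shape[1]
    gam = gamma.data.reshape(shape)
    out_data = gam * xhat + beta.data.reshape(shape)

    def bwd(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if a.requires_grad:
            sum_g = g.sum(axis=axes, keepdims=True)
            sum_gx = (g * xhat).sum(axis=axes, keepdims=True)
            a._accumulate(gam * inv / m * (m * g - sum_g - xhat * sum_gx))

    out = Tensor(out_data, parents=(a, gamma, beta), backward_fn=bwd)
    return out, mu.reshape(-1), var.reshape(-1)


def batch_norm_eval(a: Tensor, gamma: Tensor, beta: Tensor,
                    running_mean: np.ndarray, running_var: np.ndarray,
                    eps: float = 1e-5) -> Tensor:
    """Batch normalisation with frozen (running) statistics."""
    shape = [1] * a.data.ndim
    shape[1] = a.data.shape[1]
    inv = (1.0 / np.sqrt(running_var + eps)).reshape(shape).astype(a.data.dtype)
    rm = running_mean.reshape(shape).astype(a.data.dtype)
    gam = gamma.data.reshape(shape)
    xhat = (a.data - rm) * inv
    out_data = gam * xhat + beta.data.reshape(shape)
    axes = (0,) + tuple(range(2, a.data.ndim))

    def bwd(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if a.requires_grad:
            a._accumulate(g * gam * inv)

    return Tensor(out_data, parents=(a, gamma, beta), backward_fn=bwd)


def logsumexp(a: Tensor, axis: int = 1) -> Tensor:
    """Stable log-sum-exp; the max shift is treated as a constant."""
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out_data = (np.log(s) + m).squeeze(axis)
    softmax = e / s

    def bwd(g):
        if a.requires_grad:
            a._accumulate(np.expand_dims(g, axis) * softmax)

    return Tensor(out_data, parents=(a,), backward_fn=bwd)


def pair_scores(anchors: Tensor, negatives: np.ndarray) -> Tensor:
    """Per-anchor dot products against a constant (B, k, d) negative stack."""
    negs = np.asarray(negatives, dtype=anchors.data.dtype)
    out_data = np.einsum("bd,bkd->bk", anchors.data, negs)

    def bwd(g):
        if anchors.requires_grad:
            anchors._accumulate(np.einsum("bk,bkd->bd", g, negs))

    return Tensor(out_data, parents=(anchors,), backward_fn=bwd)


def rowwise_dot(a: Tensor, b: Tensor) -> Tensor:
    """Per-row dot product of two (B, d) tensors -> (B,)."""
    out_data = (a.data * b.data).sum(axis=1)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g[:, None] * b.data)
        if b.requires_grad:
            b._accumulate(g[:, None] * a.data)

    return Tensor(out_data, parents=(a, b), backward_fn=bwd)


def cross_scores(a: Tensor, b: Tensor) -> Tensor:
    """All-pairs scores a @ b.T for two (B, d)/(M, d) tensors -> (B, M)."""
    out_data = a.data @ b.data.T

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.data)
        if b.requires_grad:
            b._accumulate(g.T @ a.data)

    return Tensor(out_data, parents=(a, b), backward_fn=bwd)


# ---------------------------------------------------------------------------
# convolution (im2col) and pooling
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-d convolution, NCHW layout, weight (F, C, kh, kw)."""
    n, c, h, wdt = x.data.shape
    f, _, kh, kw = w.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    w_flat = w.data.reshape(f, -1)
    out = cols @ w_flat.T + b.data
    out_data = out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)

    def bwd(g):
        g_cols = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
        if b.requires_grad:
            b._accumulate(g_cols.sum(axis=0))
        if w.requires_grad:
            w._accumulate((g_cols.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            d_cols = (g_cols @ w_flat).reshape(n, ho, wo, c, kh, kw)
            hp, wp = h + 2 * pad, wdt + 2 * pad
            dxp = np.zeros((n, c, hp, wp), dtype=x.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                        d_cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            x._accumulate(dxp[:, :, pad : pad + h, pad : pad + wdt] if pad else dxp)

    return Tensor(out_data, parents=(x, w, b), backward_fn=bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy())

    return Tensor(out_data, parents=(x,), backward_fn=bwd)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map x @ w + b with weight (in, out)."""
    return add(matmul(x, w), b)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class SGD:
    """Mini-batch SGD with classical momentum and decoupled L2 weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        zero_grads(self.params)
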