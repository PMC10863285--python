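"""A compact reverse-mode automatic-differentiation core over NumPy float32 arrays.

Implements exactly the operations the sequence model needs: broadcast
arithmetic, (batched) matmul, same-padded 1-D convolution, average pooling,
ELU/sigmoid/softmax, concatenation, slicing and reductions.  Gradients are
accumulated by topological-order backpropagation from a scalar loss.  Inputs
may also carry gradients (``requires_grad=True``), which is what the
integrated-gradients attribution relies on.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    # dtype conversion only; views (e.g. lazy transposes) are kept as views
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """A float32 array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep residual stacks overflow recursion
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
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:  # free interior gradients; leaves keep theirs
                node.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -other)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = _lift(a), _lift(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = _lift(a), _lift(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def matmul(a, b) -> Tensor:
    """Matrix product with NumPy stack-broadcasting semantics."""
    a, b = _lift(a), _lift(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def reshape(x: Tensor, shape) -> Tensor:
    x = _lift(x)
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


def transpose(x: Tensor, axes) -> Tensor:
    x = _lift(x)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = x.data.transpose(axes)  # lazy view; consumers may copy if needed

    def backward(g):
        x._accumulate(np.ascontiguousarray(g.transpose(inv)))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [_lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def slice_axis(x: Tensor, axis: int, start: int, stop: int) -> Tensor:
    x = _lift(x)
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, stop)
    sl = tuple(sl)
    out_data = np.ascontiguousarray(x.data[sl])

    def backward(g):
        full = np.zeros_like(x.data)
        full[sl] = g
        x._accumulate(full)

    return Tensor(out_data, parents=(x,), backward=backward)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    x = _lift(x)
    neg = alpha * np.expm1(np.minimum(x.data, 0.0))
    out_data = np.where(x.data > 0, x.data, neg).astype(DTYPE)

    def backward(g):
        x._accumulate(np.where(x.data > 0, g, g * (neg + alpha)))

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _lift(x)
    # overflow-safe: exponentiate only negative magnitudes
    e = np.exp(-np.abs(x.data))
    out_data = np.where(x.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e)).astype(DTYPE)

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=backward)


def log(x: Tensor) -> Tensor:
    x = _lift(x)
    out_data = np.log(x.data)

    def backward(g):
        x._accumulate(g / x.data)

    return Tensor(out_data, parents=(x,), backward=backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is zero outside [lo, hi]."""
    x = _lift(x)
    out_data = np.clip(x.data, lo, hi)
    inside = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        x._accumulate(g * inside)

    return Tensor(out_data, parents=(x,), backward=backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _lift(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accumulate(out_data * (g - dot))

    return Tensor(out_data, parents=(x,), backward=backward)


def mean(x: Tensor) -> Tensor:
    x = _lift(x)
    n = x.data.size
    out_data = np.asarray(x.data.mean(), dtype=DTYPE)

    def backward(g):
        x._accumulate(np.full_like(x.data, g / n))

    return Tensor(out_data, parents=(x,), backward=backward)


def sum_axis(x: Tensor, axis: int) -> Tensor:
    x = _lift(x)
    out_data = x.data.sum(axis=axis)

    def backward(g):
        x._accumulate(np.broadcast_to(np.expand_dims(g, axis), x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


def sum_all(x: Tensor) -> Tensor:
    x = _lift(x)
    out_data = np.asarray(x.data.sum(), dtype=DTYPE)

    def backward(g):
        x._accumulate(np.full_like(x.data, g))

    return Tensor(out_data, parents=(x,), backward=backward)


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    Uses max(l, 0) - l y + log(1 + exp(-|l|)); the gradient is
    (sigmoid(l) - y) / n, which never vanishes from clamping.
    """
    logits = _lift(logits)
    y = np.asarray(labels, dtype=DTYPE)
    l = logits.data
    per = np.maximum(l, 0) - l * y + np.log1p(np.exp(-np.abs(l)))
    out_data = np.asarray(per.mean(), dtype=DTYPE)
    n = l.size

    def backward(g):
        e = np.exp(-np.abs(l))
        p = np.where(l >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        logits._accumulate(g * (p - y) / n)

    return Tensor(out_data, parents=(logits,), backward=backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1-D convolution (cross-correlation).

    ``x``: (B, C_in, L); ``w``: (C_out, C_in, k) with odd k; ``b``: (C_out,).
    Output: (B, C_out, L).  Implemented as im2col + one GEMM.
    """
    x, w, b = _lift(x), _lift(w), _lift(b)
    B, C_in, L = x.data.shape
    C_out, C_in_w, k = w.data.shape
    if C_in != C_in_w:
        raise ValueError(f"channel mismatch: input has {C_in}, kernel expects {C_in_w}")
    if k % 2 != 1:
        raise ValueError("kernel width must be odd for same padding")
    pad = (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    # (B, C_in, L, k) view -> (B*L, C_in*k) copy for GEMM
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * L, C_in * k)
    w_flat = w.data.reshape(C_out, C_in * k)
    y = cols2 @ w_flat.T + b.data
    out_data = y.reshape(B, L, C_out).transpose(0, 2, 1)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * L, C_out)
        if w.requires_grad:
            w._accumulate((g2.T @ cols2).reshape(C_out, C_in, k))
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ w_flat).reshape(B, L, C_in, k).transpose(0, 2, 1, 3)
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j : j + L] += dcols[:, :, :, j]
            x._accumulate(dxp[:, :, pad : pad + L])

    return Tensor(out_data, parents=(x, w, b), backward=backward)


def avg_pool1d(x: Tensor, width: int) -> Tensor:
    """Average pooling with stride = width; trailing remainder is dropped."""
    x = _lift(x)
    B, C, L = x.data.shape
    L_out = L // width
    trimmed = x.data[:, :, : L_out * width]
    out_data = trimmed.reshape(B, C, L_out, width).mean(axis=3)

    def backward(g):
        dx = np.zeros_like(x.data)
        dx[:, :, : L_out * width] = np.repeat(g / width, width, axis=2)
        x._accumulate(dx)

    return Tensor(out_data, parents=(x,), backward=backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout (training mode only; call sites skip it in eval mode)."""
    x = _lift(x)
    if p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(DTYPE) / (1.0 - p)
    out_data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)
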