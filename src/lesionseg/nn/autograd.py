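"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations a U-Net with metadata fusion needs:
dense/conv/transposed-conv/pooling layers, ReLU/sigmoid, channel
concatenation, dropout, embedding lookup, and the elementwise arithmetic
required by cross-entropy and soft-Jaccard losses.  Everything runs in
float64 for bit-reproducible training on CPU.

Gradients are accumulated by a topological-sort backward pass over the
recorded operation tape; correctness is verified against central finite
differences in the test suite.

The default dtype is float32 (standard for CNN training and twice the BLAS
throughput of float64 on CPU); ``set_default_dtype`` switches the engine,
e.g. to float64 for finite-difference gradient verification.  Runs remain
bit-reproducible for a fixed seed in either precision.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "set_default_dtype",
    "default_dtype",
    "using_dtype",
    "relu",
    "sigmoid",
    "log",
    "clip",
    "concat",
    "reshape",
    "tsum",
    "tmean",
    "matmul",
    "conv2d",
    "conv_transpose2d",
    "maxpool2x",
    "upsample2x",
    "dropout",
    "embedding",
]

_FLOAT = np.float32


def set_default_dtype(dtype) -> None:
    """Set the engine dtype (np.float32 or np.float64) for new tensors."""
    global _FLOAT
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _FLOAT = np.dtype(dtype).type


def default_dtype():
    return _FLOAT


@contextlib.contextmanager
def using_dtype(dtype):
    previous = _FLOAT
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(previous)


class Tensor:
    """An ndarray plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_FLOAT)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debug helper
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed gradient: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=_FLOAT)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- arithmetic dunders --------------------------------------------
    def __add__(self, other):
        return _add(self, astensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, astensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return _add(self, -astensor(other))

    def __rsub__(self, other):
        return _add(astensor(other), -self)

    def __truediv__(self, other):
        return _div(self, astensor(other))

    def __rtruediv__(self, other):
        return _div(astensor(other), self)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


# ---------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------

def _add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def _div(a: Tensor, b: Tensor) -> Tensor:
    data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = astensor(x)
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0)

    def backward(g):
        x._accumulate(g * mask)

    return _make(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = astensor(x)
    # numerically stable logistic
    data = np.empty_like(x.data)
    pos = x.data >= 0
    data[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    data[~pos] = ex / (1.0 + ex)

    def backward(g):
        x._accumulate(g * data * (1.0 - data))

    return _make(data, (x,), backward)


def log(x: Tensor) -> Tensor:
    x = astensor(x)
    data = np.log(x.data)

    def backward(g):
        x._accumulate(g / x.data)

    return _make(data, (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip by value; gradient is passed only through unclipped entries."""
    x = astensor(x)
    data = np.clip(x.data, lo, hi)
    mask = (x.data > lo) & (x.data < hi)

    def backward(g):
        x._accumulate(g * mask)

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------
# reductions / shape ops
# ---------------------------------------------------------------------

def tsum(x: Tensor) -> Tensor:
    x = astensor(x)
    data = x.data.sum()

    def backward(g):
        x._accumulate(np.broadcast_to(g, x.shape).astype(_FLOAT))

    return _make(data, (x,), backward)


def tmean(x: Tensor) -> Tensor:
    x = astensor(x)
    n = x.data.size
    data = x.data.mean()

    def backward(g):
        x._accumulate(np.broadcast_to(g / n, x.shape).astype(_FLOAT))

    return _make(data, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    x = astensor(x)
    data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.shape))

    return _make(data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(data, tuple(tensors), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


# ---------------------------------------------------------------------
# convolution & friends (NCHW layout)
# ---------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    ho, wo = view.shape[2], view.shape[3]
    # flattened patch matrix (n*ho*wo, c*k*k)
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return cols, ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int = 1) -> Tensor:
    """Stride-1 2-D convolution with 'same' padding (pad = (k-1)//2).

    ``w`` has shape (C_out, C_in, k, k).  With symmetric same-padding the
    input gradient is again a same convolution — with the transposed,
    180°-rotated kernel — so forward and backward share one im2col+GEMM path.
    """
    x, w, b = astensor(x), astensor(w), astensor(b)
    cout, cin, k, _ = w.shape
    if pad != (k - 1) // 2:
        raise ValueError("conv2d supports same-padding only (pad=(k-1)//2)")
    cols, ho, wo = _im2col(x.data, k, pad)  # (n*ho*wo, cin*k*k)
    n = x.shape[0]
    wmat = w.data.reshape(cout, cin * k * k)
    out = cols @ wmat.T + b.data  # (n*hw, cout)
    data = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(w.shape))
        if b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            w2 = np.ascontiguousarray(wflip).reshape(cin, cout * k * k)
            gcols, _, _ = _im2col(np.ascontiguousarray(g), k, pad)
            dx = (gcols @ w2.T).reshape(n, ho, wo, cin).transpose(0, 3, 1, 2)
            x._accumulate(dx)

    return _make(data, (x, w, b), backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2×2 stride-2 transposed convolution; ``w``: (C_in, C_out, 2, 2)."""
    x, w, b = astensor(x), astensor(w), astensor(b)
    n, cin, h, ww_ = x.shape
    cout = w.shape[1]
    # output pixels partition exactly (kernel == stride): pure reshuffle
    tmp = np.tensordot(x.data, w.data, axes=([1], [0]))  # (n,h,w,cout,2,2)
    data = tmp.transpose(0, 3, 1, 4, 2, 5).reshape(n, cout, 2 * h, 2 * ww_)
    data = data + b.data[None, :, None, None]

    def backward(g):
        dtmp = g.reshape(n, cout, h, 2, ww_, 2).transpose(0, 2, 4, 1, 3, 5)
        if x.requires_grad:
            dx = np.tensordot(dtmp, w.data, axes=([3, 4, 5], [1, 2, 3]))
            x._accumulate(dx.transpose(0, 3, 1, 2))
        if w.requires_grad:
            dw = np.tensordot(x.data, dtmp, axes=([0, 2, 3], [0, 1, 2]))
            w._accumulate(dw)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(data, (x, w, b), backward)


def maxpool2x(x: Tensor) -> Tensor:
    """2×2 stride-2 max pooling (spatial dims must be even)."""
    x = astensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x needs even spatial dims, got {h}x{w}")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    data = r.max(axis=(3, 5))

    def backward(g):
        mask = r == data[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gr = mask * (g[:, :, :, None, :, None] / counts)
        x._accumulate(gr.reshape(n, c, h, w))

    return _make(data, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Parameter-free nearest-neighbour 2× upsampling."""
    x = astensor(x)
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        x._accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _make(data, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when ``rate`` is 0."""
    x = astensor(x)
    if rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _make(data, (x,), backward)


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``table[indices]`` with scatter-add gradient."""
    table = astensor(table)
    idx = np.asarray(indices, dtype=np.intp)
    data = table.data[idx]

    def backward(g):
        dt = np.zeros_like(table.data)
        np.add.at(dt, idx, g)
        table._accumulate(dt)

    return _make(data, (table,), backward)
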