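"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The embedding-loss suite and the U-Net are differentiated with this tape-based
engine.  It supports exactly the operations the network and losses need:
broadcasting arithmetic, elementwise transcendentals, reductions, slicing and
concatenation, 'same' 2D convolution, 2x2 max pooling, 2x2-stride-2 transposed
convolution, and group normalization.  Gradients of every primitive are
verified against central finite differences in the test suite.

Functions in this module accept either :class:`Tensor` or plain ndarray
inputs; ndarray-only expressions are computed eagerly with NumPy, so the loss
code can be written once and evaluated with or without gradient tracking.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "atan",
    "log",
    "relu",
    "maximum",
    "clip_min",
    "mean",
    "total_sum",
    "concat",
    "conv2d",
    "conv_transpose2d_2x2",
    "max_pool2d_2x2",
    "group_norm",
    "is_tensor",
]


class Tensor:
    """An ndarray plus the tape bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    # make `ndarray <op> Tensor` defer to the Tensor reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        # sequence of (parent Tensor, grad_fn: out_grad -> parent grad term)
        self._parents = tuple(parents)

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order topological sort
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, grad_fn in node._parents:
                term = grad_fn(g)
                key = id(parent)
                grads[key] = term if key not in grads else grads[key] + term

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def as_tensor(x, requires_grad: bool = False) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=requires_grad)


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _tracked(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that NumPy broadcasting expanded."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, extent in enumerate(shape):
        if extent == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _make(data, parents) -> Tensor:
    return Tensor(data, parents=parents)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    if not _tracked(a, b):
        return _data(a) + _data(b)
    da, db = _data(a), _data(b)
    parents = []
    if isinstance(a, Tensor):
        parents.append((a, lambda g, s=da.shape: _unbroadcast(g, s)))
    if isinstance(b, Tensor):
        parents.append((b, lambda g, s=db.shape: _unbroadcast(g, s)))
    return _make(da + db, parents)


def mul(a, b):
    if not _tracked(a, b):
        return _data(a) * _data(b)
    da, db = _data(a), _data(b)
    parents = []
    if isinstance(a, Tensor):
        parents.append((a, lambda g, o=db, s=da.shape: _unbroadcast(g * o, s)))
    if isinstance(b, Tensor):
        parents.append((b, lambda g, o=da, s=db.shape: _unbroadcast(g * o, s)))
    return _make(da * db, parents)


def div(a, b):
    if not _tracked(a, b):
        return _data(a) / _data(b)
    da, db = _data(a), _data(b)
    parents = []
    if isinstance(a, Tensor):
        parents.append((a, lambda g, o=db, s=da.shape: _unbroadcast(g / o, s)))
    if isinstance(b, Tensor):
        parents.append(
            (b, lambda g, n=da, o=db, s=db.shape: _unbroadcast(-g * n / (o * o), s))
        )
    return _make(da / db, parents)


def power(a, exponent: float):
    if not _tracked(a):
        return _data(a) ** exponent
    da = _data(a)
    out = da**exponent
    return _make(
        out, [(a, lambda g, x=da, p=exponent: g * p * x ** (p - 1))]
    )


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def atan(x):
    if not _tracked(x):
        return np.arctan(_data(x))
    d = _data(x)
    return _make(np.arctan(d), [(x, lambda g, v=d: g / (1.0 + v * v))])


def log(x):
    if not _tracked(x):
        return np.log(_data(x))
    d = _data(x)
    return _make(np.log(d), [(x, lambda g, v=d: g / v)])


def relu(x):
    if not _tracked(x):
        return np.maximum(_data(x), 0.0)
    d = _data(x)
    keep = d > 0
    return _make(np.where(keep, d, 0.0), [(x, lambda g, k=keep: g * k)])


def maximum(x, other):
    """Elementwise maximum; at ties the gradient flows to ``x``."""
    if not _tracked(x, other):
        return np.maximum(_data(x), _data(other))
    dx, do = _data(x), _data(other)
    out = np.maximum(dx, do)
    parents = []
    if isinstance(x, Tensor):
        keep = dx >= do
        parents.append((x, lambda g, k=keep, s=dx.shape: _unbroadcast(g * k, s)))
    if isinstance(other, Tensor):
        keep_o = do > dx
        parents.append(
            (other, lambda g, k=keep_o, s=do.shape: _unbroadcast(g * k, s))
        )
    return _make(out, parents)


def clip_min(x, floor: float):
    """max(x, floor) with zero gradient where the floor is active."""
    return maximum(x, float(floor))


# ---------------------------------------------------------------------------
# reductions / shaping
# ---------------------------------------------------------------------------

def mean(x, axis=None):
    if not _tracked(x):
        return np.mean(_data(x), axis=axis)
    d = _data(x)
    out = np.mean(d, axis=axis)
    count = d.size if axis is None else np.prod([d.shape[a] for a in np.atleast_1d(axis)])

    def grad_fn(g, shape=d.shape, axis=axis, count=count):
        if axis is None:
            return np.broadcast_to(g, shape) / count
        g = np.expand_dims(g, axis)
        return np.broadcast_to(g, shape) / count

    return _make(out, [(x, grad_fn)])


def total_sum(x, axis=None):
    if not _tracked(x):
        return np.sum(_data(x), axis=axis)
    d = _data(x)
    out = np.sum(d, axis=axis)

    def grad_fn(g, shape=d.shape, axis=axis):
        if axis is None:
            return np.broadcast_to(g, shape).copy()
        g = np.expand_dims(g, axis)
        return np.broadcast_to(g, shape).copy()

    return _make(out, [(x, grad_fn)])


def reshape(x, shape):
    if not _tracked(x):
        return _data(x).reshape(shape)
    d = _data(x)
    return _make(d.reshape(shape), [(x, lambda g, s=d.shape: g.reshape(s))])


def getitem(x, key):
    if not _tracked(x):
        return _data(x)[key]
    d = _data(x)

    def grad_fn(g, shape=d.shape, key=key):
        out = np.zeros(shape)
        np.add.at(out, key, g)
        return out

    return _make(d[key], [(x, grad_fn)])


def concat(xs, axis=0):
    if not _tracked(*xs):
        return np.concatenate([_data(x) for x in xs], axis=axis)
    datas = [_data(x) for x in xs]
    out = np.concatenate(datas, axis=axis)
    parents = []
    offset = 0
    for x, d in zip(xs, datas):
        extent = d.shape[axis]
        if isinstance(x, Tensor):
            sl = [slice(None)] * out.ndim
            sl[axis] = slice(offset, offset + extent)
            parents.append((x, lambda g, sl=tuple(sl): g[sl]))
        offset += extent
    return _make(out, parents)


# ---------------------------------------------------------------------------
# neural-network primitives (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> sliding windows (N, C, H, W, kh, kw), 'same' padded."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))


def conv2d(x, w, b):
    """'Same' 2D convolution (cross-correlation), stride 1, odd kernel.

    x: (N, C, H, W); w: (O, C, kh, kw); b: (O,).  Output (N, O, H, W).
    """
    dx, dw, dbias = _data(x), _data(w), _data(b)
    kh, kw = dw.shape[2:]
    pad = kh // 2
    cols = _im2col(dx, kh, kw, pad)
    out = np.einsum("nchwij,ocij->nohw", cols, dw, optimize=True)
    out += dbias[None, :, None, None]
    if not _tracked(x, w, b):
        return out
    parents = []
    if isinstance(x, Tensor):

        def grad_x(g, w_=dw, pad=pad, kh=kh, kw=kw):
            wf = w_[:, :, ::-1, ::-1]
            gcols = _im2col(g, kh, kw, kh - 1 - pad)
            return np.einsum("nohwij,ocij->nchw", gcols, wf, optimize=True)

        parents.append((x, grad_x))
    if isinstance(w, Tensor):
        parents.append(
            (w, lambda g, c=cols: np.einsum("nchwij,nohw->ocij", c, g, optimize=True))
        )
    if isinstance(b, Tensor):
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return _make(out, parents)


def max_pool2d_2x2(x):
    """2x2 max pooling, stride 2; ties share the gradient equally."""
    d = _data(x)
    n, c, h, w = d.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d_2x2 requires even H and W, got {h}x{w}")
    win = d.reshape(n, c, h // 2, 2, w // 2, 2)
    out = win.max(axis=(3, 5))
    if not _tracked(x):
        return out

    def grad_fn(g, win=win, out=out, shape=d.shape):
        is_max = win == out[:, :, :, None, :, None]
        counts = is_max.sum(axis=(3, 5), keepdims=True)
        spread = g[:, :, :, None, :, None] * is_max / counts
        return spread.reshape(shape)

    return _make(out, [(x, grad_fn)])


def conv_transpose2d_2x2(x, w, b):
    """Transposed convolution with a 2x2 kernel and stride 2 (up-convolution).

    x: (N, C, H, W); w: (C, O, 2, 2); b: (O,).  Output (N, O, 2H, 2W).
    Windows do not overlap at stride 2, so the op is a per-pixel outer product.
    """
    dx, dw, dbias = _data(x), _data(w), _data(b)
    n, c, h, wd = dx.shape
    o = dw.shape[1]
    out = np.einsum("nchw,coij->nohiwj", dx, dw, optimize=True).reshape(
        n, o, 2 * h, 2 * wd
    )
    out += dbias[None, :, None, None]
    if not _tracked(x, w, b):
        return out
    parents = []
    if isinstance(x, Tensor):

        def grad_x(g, w_=dw, n=n, o=o, h=h, wd=wd):
            gr = g.reshape(n, o, h, 2, wd, 2)
            return np.einsum("nohiwj,coij->nchw", gr, w_, optimize=True)

        parents.append((x, grad_x))
    if isinstance(w, Tensor):

        def grad_w(g, x_=dx, n=n, o=o, h=h, wd=wd):
            gr = g.reshape(n, o, h, 2, wd, 2)
            return np.einsum("nchw,nohiwj->coij", x_, gr, optimize=True)

        parents.append((w, grad_w))
    if isinstance(b, Tensor):
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return _make(out, parents)


def group_norm(x, gamma, beta, groups: int, eps: float = 1e-5):
    """Group normalization over (channels/groups, H, W) per sample."""
    dx, dgamma, dbeta = _data(x), _data(gamma), _data(beta)
    n, c, h, w = dx.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    xg = dx.reshape(n, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv_std).reshape(n, c, h, w)
    out = xhat * dgamma[None, :, None, None] + dbeta[None, :, None, None]
    if not _tracked(x, gamma, beta):
        return out
    parents = []
    if isinstance(x, Tensor):

        def grad_x(g, xhat=xhat, inv_std=inv_std, gamma_=dgamma, n=n, groups=groups):
            dxhat = (g * gamma_[None, :, None, None]).reshape(n, groups, -1)
            xh = xhat.reshape(n, groups, -1)
            term = (
                dxhat
                - dxhat.mean(axis=2, keepdims=True)
                - xh * (dxhat * xh).mean(axis=2, keepdims=True)
            )
            return (term * inv_std).reshape(g.shape)

        parents.append((x, grad_x))
    if isinstance(gamma, Tensor):
        parents.append((gamma, lambda g, xh=xhat: (g * xh).sum(axis=(0, 2, 3))))
    if isinstance(beta, Tensor):
        parents.append((beta, lambda g: g.sum(axis=(0, 2, 3))))
    return _make(out, parents)
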