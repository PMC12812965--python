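"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small volumetric and graph networks on CPU; this module
provides the tensor type and the differentiable primitives those networks
need (dense linear algebra, 3-D convolution/pooling, segment operations for
graph attention, and the entmax transform).  Gradients are accumulated by a
topological backward sweep.  All arithmetic is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "conv3d", "max_pool3d",
           "gather", "segment_sum", "entmax_transform", "no_grad"]


class _NoGrad:
    """Context manager that disables graph construction (eval-time speed)."""

    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._vjp = None  # callable: upstream grad -> tuple of parent grads

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, vjp) -> "Tensor":
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._vjp = vjp
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward engine ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor"):
            stack = [(node, False)]
            while stack:
                n, processed = stack.pop()
                if processed:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy() if g.base is not None else g
                else:
                    parent.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        return Tensor._make(out_data, (self, other), lambda g: (
            _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(self.data * other.data, (self, other), lambda g: (
            _unbroadcast(g * other.data, self.data.shape),
            _unbroadcast(g * self.data, other.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        inv = 1.0 / other.data
        return Tensor._make(self.data * inv, (self, other), lambda g: (
            _unbroadcast(g * inv, self.data.shape),
            _unbroadcast(-g * self.data * inv * inv, other.data.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = self.data ** e
        return Tensor._make(out, (self,), lambda g: (
            g * e * self.data ** (e - 1.0),))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        out = a @ b

        def vjp(g):
            if a.ndim == 1 and b.ndim == 1:
                return g * b, g * a
            if b.ndim == 1:       # out = a @ b : (..., n)
                ga = g[..., None] * b
                gb = (a * g[..., None]).sum(axis=tuple(range(a.ndim - 1)))
            elif a.ndim == 1:     # out = a @ b : (..., m)
                prod = b * g[..., None, :]
                ga = prod.sum(axis=(*range(b.ndim - 2), b.ndim - 1))
                gb = a[:, None] * g[..., None, :]
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(out, (self, other), vjp)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)
        return Tensor._make(self.data * scale, (self,), lambda g: (g * scale,))

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = np.where(self.data > 0, self.data, neg)
        dd = np.where(self.data > 0, 1.0, neg + alpha)
        return Tensor._make(out, (self,), lambda g: (g * dd,))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._make(t, (self,), lambda g: (g * (1.0 - t * t),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        s = np.sqrt(self.data)
        return Tensor._make(s, (self,), lambda g: (g * 0.5 / s,))

    def clamp_min(self, lo: float):
        mask = self.data >= lo
        return Tensor._make(np.maximum(self.data, lo), (self,),
                            lambda g: (g * mask,))

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor._make(out, (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    @property
    def T(self):
        return self.transpose(*reversed(range(self.data.ndim)))

    def __getitem__(self, idx):
        out = self.data[idx]

        def vjp(g):
            gi = np.zeros_like(self.data)
            np.add.at(gi, idx, g)
            return (gi,)

        return Tensor._make(out, (self,), vjp)

    # -- convenience ----------------------------------------------------------
    def softmax(self, axis: int = -1):
        z = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = z.exp()
        return e / e.sum(axis=axis, keepdims=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tuple(tensors), vjp)


def stack(tensors: list, axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = as_tensor(t)
        shape = list(t.data.shape)
        shape.insert(axis if axis >= 0 else len(shape) + 1 + axis, 1)
        expanded.append(t.reshape(tuple(shape)))
    return concat(expanded, axis=axis)


# -- gather / scatter (graph attention support) -------------------------------

def gather(x: Tensor, index: np.ndarray, axis: int = 0) -> Tensor:
    """Select rows `index` along `axis` (differentiable index_select)."""
    index = np.asarray(index, dtype=np.intp)
    out = np.take(x.data, index, axis=axis)

    def vjp(g):
        gi = np.zeros_like(x.data)
        sl = [slice(None)] * x.data.ndim
        sl[axis] = index
        np.add.at(gi, tuple(sl), g)
        return (gi,)

    return Tensor._make(out, (x,), vjp)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `x` into `num_segments` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_shape = (num_segments,) + x.data.shape[1:]
    out = np.zeros(out_shape, dtype=np.float64)
    np.add.at(out, segment_ids, x.data)

    def vjp(g):
        return (np.take(g, segment_ids, axis=0),)

    return Tensor._make(out, (x,), vjp)


# -- 3-D convolution and pooling ----------------------------------------------

def _im2col(xp: np.ndarray, kernel: tuple, stride: int):
    """(B,C,Dp,Hp,Wp) -> windows (B,Do,Ho,Wo,C,kd,kh,kw)."""
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    return win.transpose(0, 2, 3, 4, 1, 5, 6, 7)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3-D cross-correlation.  x: (B,C,D,H,W); w: (O,C,kd,kh,kw); b: (O,)."""
    B, C, D, H, W = x.data.shape
    O, Cw, kd, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"conv3d channel mismatch: input {C}, weight {Cw}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    Do = (D + 2 * p - kd) // s + 1
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    if Do < 1 or Ho < 1 or Wo < 1:
        raise ValueError(
            f"conv3d: spatial input {(D, H, W)} smaller than kernel "
            f"{(kd, kh, kw)} at stride {s}, padding {p}")
    cols = _im2col(xp, (kd, kh, kw), s).reshape(B * Do * Ho * Wo, C * kd * kh * kw)
    wmat = w.data.reshape(O, -1)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = out.reshape(B, Do, Ho, Wo, O).transpose(0, 4, 1, 2, 3)
    parents = (x, w) if b is None else (x, w, b)

    def vjp(g):
        g2 = g.transpose(0, 2, 3, 4, 1).reshape(B * Do * Ho * Wo, O)
        gw = (g2.T @ cols).reshape(w.data.shape)
        gcols = (g2 @ wmat).reshape(B, Do, Ho, Wo, C, kd, kh, kw)
        gcols = gcols.transpose(0, 4, 5, 6, 7, 1, 2, 3)  # (B,C,kd,kh,kw,Do,Ho,Wo)
        gxp = np.zeros((B, C, D + 2 * p, H + 2 * p, W + 2 * p))
        for a in range(kd):
            for bb in range(kh):
                for c in range(kw):
                    gxp[:, :, a:a + s * Do:s, bb:bb + s * Ho:s,
                        c:c + s * Wo:s] += gcols[:, :, a, bb, c]
        gx = gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp
        if b is None:
            return gx, gw
        return gx, gw, g2.sum(axis=0)

    return Tensor._make(out, parents, vjp)


def max_pool3d(x: Tensor, kernel: int, stride: int | None = None,
               padding: int = 0) -> Tensor:
    s = stride or kernel
    p = padding
    B, C, D, H, W = x.data.shape
    if p:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    Do = (D + 2 * p - kernel) // s + 1
    Ho = (H + 2 * p - kernel) // s + 1
    Wo = (W + 2 * p - kernel) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(
        xp, (kernel, kernel, kernel), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    flat = win.reshape(B, C, Do, Ho, Wo, -1)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def vjp(g):
        gxp = np.zeros_like(xp)
        kd, kh, kw = np.unravel_index(arg, (kernel, kernel, kernel))
        bi, ci, di, hi, wi = np.indices(arg.shape)
        np.add.at(gxp, (bi, ci, di * s + kd, hi * s + kh, wi * s + kw), g)
        gx = gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp
        return (gx,)

    return Tensor._make(out, (x,), vjp)


# -- entmax ------------------------------------------------------------------

def _entmax_numpy(z: np.ndarray, alpha: float, n_iter: int = 50) -> np.ndarray:
    """alpha-entmax along the last axis (bisection; exact branches at 1 and 2)."""
    from .classifier import entmax_probs  # local import avoids cycle at load
    return entmax_probs(z, alpha=alpha, bisect_iters=n_iter)


def entmax_transform(z: Tensor, alpha: float = 1.5, n_iter: int = 50) -> Tensor:
    """Differentiable alpha-entmax over the last axis.

    Jacobian-vector product uses the closed form J = diag(d) - d d^T / sum(d)
    with d_i = p_i^(2-alpha) on the support (reduces to the softmax and
    sparsemax Jacobians at alpha = 1 and 2).
    """
    p = _entmax_numpy(z.data, alpha, n_iter)

    def vjp(g):
        with np.errstate(divide="ignore"):
            d = np.where(p > 0, p ** (2.0 - alpha), 0.0)
        gd = g * d
        corr = gd.sum(axis=-1, keepdims=True) / d.sum(axis=-1, keepdims=True)
        return (gd - d * corr,)

    return Tensor._make(p, (z,), vjp)
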