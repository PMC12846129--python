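"""Reverse-mode automatic differentiation over numpy arrays.

This is the numerics core the package's neural components are built on: a
small dynamically-built tape of :class:`Tensor` nodes supporting the dense,
convolutional and attention operations the models need.  It is deliberately
minimal — float64 throughout, CPU only, no graph optimisation — which keeps
behaviour deterministic and easy to verify against finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "conv2d", "conv3d", "max_pool2d"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * np.sign(a.data))

        return Tensor._make(np.abs(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - o * o))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o * (1.0 - o))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if kd else np.expand_dims(g, ax)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, a=self, inv=inv):
            if a.requires_grad:
                a._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- softmax family -------------------------------------------------------
    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g, a=self, o=out_data, ax=axis):
            if a.requires_grad:
                dot = (g * o).sum(axis=ax, keepdims=True)
                a._accum(o * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    def log_softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        sm = np.exp(out_data)

        def backward(g, a=self, s=sm, ax=axis):
            if a.requires_grad:
                a._accum(g - s * g.sum(axis=ax, keepdims=True))

        return Tensor._make(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free interior grads/graph to bound memory
                node._backward = None
                node._parents = ()


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]

    def backward(g, ts=tensors, ax=axis):
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=ax))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, backward)


# ---------------------------------------------------------------------------
# Convolution primitives (im2col based, custom backward)
# ---------------------------------------------------------------------------

def _im2col2d(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
    )
    return view.reshape(n, c * kh * kw, ho * wo).copy(), ho, wo


def _col2im2d(cols, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    x = np.zeros((n, c, hp, wp))
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    return x[:, :, pad : pad + h, pad : pad + w] if pad else x


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution, NCHW layout, weight (C_out, C_in, kh, kw)."""
    co, ci, kh, kw = w.data.shape
    cols, ho, wo = _im2col2d(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(co, -1)
    out = np.einsum("ok,nkl->nol", wmat, cols)
    if b is not None:
        out = out + b.data.reshape(1, co, 1)
    out = out.reshape(x.data.shape[0], co, ho, wo)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g, x=x, w=w, b=b, cols=cols, wmat=wmat, stride=stride, pad=pad, kh=kh, kw=kw):
        gmat = g.reshape(g.shape[0], g.shape[1], -1)
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", gmat, cols)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.einsum("ok,nol->nkl", wmat, gmat)
            x._accum(_col2im2d(gcols, x.data.shape, kh, kw, stride, pad))

    return Tensor._make(out, parents, backward)


def _im2col3d(x: np.ndarray, kd: int, kh: int, kw: int, stride: int, pad: int):
    n, c, d, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    do = (x.shape[2] - kd) // stride + 1
    ho = (x.shape[3] - kh) // stride + 1
    wo = (x.shape[4] - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kd, kh, kw, do, ho, wo),
        strides=(s[0], s[1], s[2], s[3], s[4], s[2] * stride, s[3] * stride, s[4] * stride),
    )
    return view.reshape(n, c * kd * kh * kw, do * ho * wo).copy(), do, ho, wo


def _col2im3d(cols, x_shape, kd, kh, kw, stride, pad):
    n, c, d, h, w = x_shape
    dp, hp, wp = d + 2 * pad, h + 2 * pad, w + 2 * pad
    do = (dp - kd) // stride + 1
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    x = np.zeros((n, c, dp, hp, wp))
    cols = cols.reshape(n, c, kd, kh, kw, do, ho, wo)
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                x[
                    :,
                    :,
                    i : i + stride * do : stride,
                    j : j + stride * ho : stride,
                    k : k + stride * wo : stride,
                ] += cols[:, :, i, j, k]
    if pad:
        return x[:, :, pad : pad + d, pad : pad + h, pad : pad + w]
    return x


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """3D convolution, NCDHW layout, weight (C_out, C_in, kd, kh, kw)."""
    co, ci, kd, kh, kw = w.data.shape
    cols, do, ho, wo = _im2col3d(x.data, kd, kh, kw, stride, pad)
    wmat = w.data.reshape(co, -1)
    out = np.einsum("ok,nkl->nol", wmat, cols)
    if b is not None:
        out = out + b.data.reshape(1, co, 1)
    out = out.reshape(x.data.shape[0], co, do, ho, wo)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g, x=x, w=w, b=b, cols=cols, wmat=wmat, stride=stride, pad=pad, ks=(kd, kh, kw)):
        gmat = g.reshape(g.shape[0], g.shape[1], -1)
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", gmat, cols)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.einsum("ok,nol->nkl", wmat, gmat)
            x._accum(_col2im3d(gcols, x.data.shape, *ks, stride, pad))

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k×k stride-k max pooling with floor cropping of odd trailing rows/cols."""
    n, c, h, w = x.data.shape
    ho, wo = h // k, w // k
    xv = x.data[:, :, : ho * k, : wo * k].reshape(n, c, ho, k, wo, k)
    flat = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g, x=x, arg=arg, shape=(n, c, h, w), k=k, ho=ho, wo=wo):
        if not x.requires_grad:
            return
        gflat = np.zeros((shape[0], shape[1], ho, wo, k * k))
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = np.zeros(shape)
        gx[:, :, : ho * k, : wo * k] = (
            gflat.reshape(shape[0], shape[1], ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        ).reshape(shape[0], shape[1], ho * k, wo * k)
        x._accum(gx)

    return Tensor._make(out, (x,), backward)
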