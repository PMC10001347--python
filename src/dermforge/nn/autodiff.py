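"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the generative and transformer models in
this package need: broadcasted arithmetic, (batched) matmul, reshaping,
slicing, concatenation, reductions, the usual activations, 2-D convolution
and transposed convolution (im2col based), and embedding lookup.  Gradients
are accumulated in ``Tensor.grad`` after calling :meth:`Tensor.backward` on
a scalar loss.

Arrays are float64 throughout: the models here run at desk scale where
numerical robustness (finite-difference checkable gradients) is worth more
than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d", "embedding"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient and backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None
        self.name = name

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data)
        if self.requires_grad or other.requires_grad:
            out.requires_grad = True
            out._parents = tuple(p for p in (self, other) if p.requires_grad)

            def bwd():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.shape))

            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda: self._accumulate(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data)
        if self.requires_grad or other.requires_grad:
            out.requires_grad = True
            out._parents = tuple(p for p in (self, other) if p.requires_grad)

            def bwd():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out = Tensor(self.data ** exponent)
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda: self._accumulate(
                out.grad * exponent * self.data ** (exponent - 1.0)
            )
        return out

    def sqrt(self):
        return self.pow(0.5)

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data))
        if self.requires_grad or other.requires_grad:
            out.requires_grad = True
            out._parents = tuple(p for p in (self, other) if p.requires_grad)

            def bwd():
                g = out.grad
                if self.requires_grad:
                    if other.data.ndim == 1:
                        ga = np.multiply.outer(g, other.data) if g.ndim else g * other.data
                    else:
                        ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    if self.data.ndim == 1:
                        gb = np.multiply.outer(self.data, g)
                    else:
                        gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accumulate(_unbroadcast(gb, other.shape))

            out._backward = bwd
        return out

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda: self._accumulate(out.grad.reshape(old))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda: self._accumulate(out.grad.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def bwd():
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

            out._backward = bwd
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def bwd():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda: self._accumulate(out.grad * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda: self._accumulate(out.grad / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda: self._accumulate(out.grad * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda: self._accumulate(
                out.grad * out.data * (1.0 - out.data)
            )
        return out

    def leaky_relu(self, alpha: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda: self._accumulate(
                out.grad * np.where(self.data > 0, 1.0, alpha)
            )
        return out

    def relu(self):
        return self.leaky_relu(alpha=0.0)

    def gelu(self):
        # tanh approximation, composed from differentiable primitives
        c = np.sqrt(2.0 / np.pi)
        inner = (self + self.pow(3.0) * 0.044715) * c
        return self * 0.5 * (inner.tanh() + 1.0)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through only inside the range."""
        out = Tensor(np.clip(self.data, lo, hi))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda: self._accumulate(
                out.grad * ((self.data >= lo) & (self.data <= hi))
            )
        return out

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd():
            for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * out.ndim
                    idx[axis] = slice(start, stop)
                    t._accumulate(out.grad[tuple(idx)])

        out._backward = bwd
    return out


# -- convolution ------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride,
                                  j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(cols: np.ndarray, shape: tuple, k: int, stride: int, pad: int):
    n, c, h, w = shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    blocks = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride,
               j : j + stride * wo : stride] += blocks[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """NCHW convolution; ``w`` has shape (F, C, k, k), ``b`` shape (F,)."""
    n = x.shape[0]
    f, c, k, _ = w.shape
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    wmat = w.data.reshape(f, c * k * k)
    out_data = (wmat @ cols).reshape(n, f, ho, wo) + b.data.reshape(1, f, 1, 1)
    out = Tensor(out_data)
    if x.requires_grad or w.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = tuple(p for p in (x, w, b) if p.requires_grad)

        def bwd():
            g = out.grad.reshape(n, f, ho * wo)
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.einsum("nfl,ncl->fc", g, cols)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                gcols = np.einsum("fc,nfl->ncl", wmat, g)
                x._accumulate(_col2im(gcols, x.shape, k, stride, pad))

        out._backward = bwd
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2,
                     pad: int = 1) -> Tensor:
    """Transposed NCHW convolution (the adjoint of :func:`conv2d`).

    ``w`` has shape (C, F, k, k); the output spatial side is
    ``stride*(H-1) + k - 2*pad`` (2H for the DCGAN k=4, stride=2, pad=1 case).
    """
    n, c, h, wd = x.shape
    _, f, k, _ = w.shape
    ho = stride * (h - 1) + k - 2 * pad
    wo = stride * (wd - 1) + k - 2 * pad
    wmat = w.data.reshape(c, f * k * k)
    xflat = x.data.reshape(n, c, h * wd)
    dcols = np.einsum("cq,ncl->nql", wmat, xflat)
    out_data = _col2im(dcols, (n, f, ho, wo), k, stride, pad)
    out_data += b.data.reshape(1, f, 1, 1)
    out = Tensor(out_data)
    if x.requires_grad or w.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = tuple(p for p in (x, w, b) if p.requires_grad)

        def bwd():
            g = out.grad
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            gcols, _, _ = _im2col(g, k, stride, pad)
            if w.requires_grad:
                gw = np.einsum("ncl,nql->cq", xflat, gcols)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                gx = np.einsum("cq,nql->ncl", wmat, gcols)
                x._accumulate(gx.reshape(x.shape))

        out._backward = bwd
    return out


def embedding(idx: np.ndarray, w: Tensor) -> Tensor:
    """Row lookup ``w[idx]`` with scatter-add gradient into ``w``."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(w.data[idx])
    if w.requires_grad:
        out.requires_grad = True
        out._parents = (w,)

        def bwd():
            g = np.zeros_like(w.data)
            np.add.at(g, idx, out.grad)
            w._accumulate(g)

        out._backward = bwd
    return out
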