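"""Minimal reverse-mode autodiff on NumPy arrays.

Supports exactly the operator set needed by the audio CNNs in this package:
broadcasting elementwise arithmetic, (batched) matmul, reductions, slicing,
2-D convolution (dense and depthwise) via im2col, 2x2 max pooling and batch
normalization as fused primitives.  Gradients are accumulated into ``.grad``
by :meth:`Tensor.backward` after a topological sort of the recorded graph.

Arrays keep whatever float dtype they are given; layers default to float32
for speed while tests may run graphs in float64 for finite-difference
checks.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "where",
    "conv2d",
    "maxpool2x2",
    "batch_norm_train",
    "no_grad",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference-mode forwards)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev_state = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev_state
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


_NOOP = lambda: None  # noqa: E731


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward_fn", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: tuple["Tensor", ...] = (),
        _backward: Callable[[], None] | None = None,
    ):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        # graph recording is suppressed wholesale inside no_grad blocks
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward_fn = (_backward or _NOOP) if self.requires_grad else _NOOP
        self._prev = _prev if self.requires_grad else ()

    @property
    def _backward(self) -> Callable[[], None]:
        return self._backward_fn

    @_backward.setter
    def _backward(self, fn: Callable[[], None]) -> None:
        # ops assign their backward closure unconditionally; keep the graph
        # only when this node actually participates in differentiation
        if self.requires_grad:
            self._backward_fn = fn

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- autograd plumbing -------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad)  # own a copy; callers may pass shared views
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given).

        Interior-node gradients and recorded closures are released as soon
        as they have been consumed, so peak memory stays near the forward
        pass footprint even for large convolutional graphs.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node.grad is not None:
                node._backward()
            if node._prev:  # interior node: free its grad and graph closure
                node.grad = None
                node._backward = lambda: None
                node._prev = ()

    # -- elementwise arithmetic --------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def _backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def _backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data / other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def _backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-out.grad * self.data / (other.data**2), other.shape)
                )

        out._backward = _backward
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data**exponent, requires_grad=self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = _backward
        return out

    # -- transcendental ----------------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), requires_grad=self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * out.data)

        out._backward = _backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        out._backward = _backward
        return out

    def sqrt(self) -> "Tensor":
        out = Tensor(np.sqrt(self.data), requires_grad=self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * 0.5 / out.data)

        out._backward = _backward
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), requires_grad=self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * np.sign(self.data))

        out._backward = _backward
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0), requires_grad=self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * (self.data > 0))

        out._backward = _backward
        return out

    def sigmoid(self) -> "Tensor":
        with np.errstate(over="ignore", invalid="ignore"):
            s = np.where(
                self.data >= 0,
                1.0 / (1.0 + np.exp(-self.data)),
                np.exp(self.data) / (1.0 + np.exp(self.data)),
            )
        out = Tensor(s, requires_grad=self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * out.data * (1.0 - out.data))

        out._backward = _backward
        return out

    def softplus(self) -> "Tensor":
        """log(1 + exp(x)) in a numerically stable form; d/dx = sigmoid(x)."""
        x = self.data
        with np.errstate(over="ignore", invalid="ignore"):
            val = np.where(x > 0, x + np.log1p(np.exp(-np.abs(x))), np.log1p(np.exp(x)))
            sig = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
        out = Tensor(val, requires_grad=self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * sig)

        out._backward = _backward
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            _prev=(self,),
        )

        def _backward():
            if not self.requires_grad:
                return
            grad = out.grad
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                grad = np.expand_dims(grad, tuple(a % self.ndim for a in axes))
            self._accumulate(np.broadcast_to(grad, self.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.shape))

        out._backward = _backward
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad, _prev=(self,))
        inv = np.argsort(axes)

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(inv))

        out._backward = _backward
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, idx, out.grad)
                self._accumulate(gx)

        out._backward = _backward
        return out

    # -- matmul ------------------------------------------------------------
    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            np.matmul(self.data, other.data),
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def _backward():
            a, b, g = self.data, other.data, out.grad
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.expand_dims(g, -1) * b
                else:
                    ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.expand_dims(a, -1) * np.expand_dims(g, -2)
                else:
                    gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = _backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def where(cond: np.ndarray, a, b) -> Tensor:
    """Elementwise select with a constant (non-differentiable) condition."""
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond, dtype=bool)
    out = Tensor(
        np.where(cond, a.data, b.data),
        requires_grad=a.requires_grad or b.requires_grad,
        _prev=(a, b),
    )

    def _backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad * cond, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad * ~cond, b.shape))

    out._backward = _backward
    return out


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        _prev=tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])

    out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    """Return columns of shape (N, C, kh*kw, oh*ow)."""
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = np.empty((n, c, kh * kw, oh * ow), dtype=x.dtype)
    for ki in range(kh):
        for kj in range(kw):
            patch = x[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride]
            cols[:, :, ki * kw + kj, :] = patch.reshape(n, c, oh * ow)
    return cols, oh, ow


def _col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, ...],
    kh: int,
    kw: int,
    stride: int,
    padding: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for ki in range(kh):
        for kj in range(kw):
            dx[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride] += dcols[
                :, :, ki * kw + kj, :
            ].reshape(n, c, oh, ow)
    if padding:
        dx = dx[:, :, padding:-padding, padding:-padding]
    return dx


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input.

    ``groups`` must be 1 (dense) or equal to the input channel count
    (depthwise with channel multiplier 1).
    """
    n, c, h, w = x.shape
    o, cg, kh, kw = weight.shape
    if groups == 1:
        if cg != c:
            raise ValueError(f"weight expects {cg} input channels, got {c}")
    elif groups == c:
        if o != c or cg != 1:
            raise ValueError("depthwise conv requires weight shape (C, 1, kh, kw)")
    else:
        raise ValueError("only dense (groups=1) or depthwise (groups=C) convs supported")

    requires_grad = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad
    )

    if kh == 1 and kw == 1 and stride == 1 and padding == 0 and groups == 1:
        # pointwise fast path: plain batched matmul
        xm = x.data.reshape(n, c, h * w)
        wm = weight.data.reshape(o, c)
        y = np.matmul(wm[None], xm)  # (n, o, h*w)
        if bias is not None:
            y = y + bias.data.reshape(1, o, 1)
        prev = (x, weight) if bias is None else (x, weight, bias)
        out = Tensor(y.reshape(n, o, h, w), requires_grad=requires_grad, _prev=prev)

        def _backward_pw():
            g = out.grad.reshape(n, o, h * w)
            if x.requires_grad:
                x._accumulate(np.matmul(wm.T[None], g).reshape(x.shape))
            if weight.requires_grad:
                gw = np.matmul(g, xm.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(gw.reshape(weight.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2)))

        out._backward = _backward_pw
        return out

    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    if groups == 1:
        wm = weight.data.reshape(o, c * kh * kw)
        y = np.matmul(wm[None], cols.reshape(n, c * kh * kw, oh * ow))  # (n, o, oh*ow)
    else:  # depthwise
        wm = weight.data.reshape(c, kh * kw)
        y = np.einsum("nckl,ck->ncl", cols, wm)
    if bias is not None:
        y = y + bias.data.reshape(1, o, 1)
    del cols  # recomputed in backward; keeping it would pin ~GBs across the graph
    prev = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y.reshape(n, o, oh, ow), requires_grad=requires_grad, _prev=prev)

    def _backward():
        g = out.grad.reshape(n, o, oh * ow)
        cols, _, _ = _im2col(x.data, kh, kw, stride, padding)
        if groups == 1:
            cols_flat = cols.reshape(n, c * kh * kw, oh * ow)
            if weight.requires_grad:
                gw = np.matmul(g, cols_flat.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                dcols = np.matmul(wm.T[None], g).reshape(n, c, kh * kw, oh * ow)
                x._accumulate(_col2im(dcols, x.shape, kh, kw, stride, padding, oh, ow))
        else:
            if weight.requires_grad:
                gw = np.einsum("ncl,nckl->ck", g, cols)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                dcols = np.einsum("ncl,ck->nckl", g, wm)
                x._accumulate(_col2im(dcols, x.shape, kh, kw, stride, padding, oh, ow))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))

    out._backward = _backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; input H and W must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    arg = xr.argmax(axis=-1).astype(np.int8)  # values 0..3; keep the buffer small
    y = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    out = Tensor(y, requires_grad=x.requires_grad, _prev=(x,))

    def _backward():
        if not x.requires_grad:
            return
        gflat = np.zeros_like(xr)
        np.put_along_axis(gflat, arg[..., None], out.grad[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gx.reshape(x.shape))

    out._backward = _backward
    return out


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch norm over (N, H, W) per channel.

    Returns ``(out, batch_mean, batch_var)`` with the statistics as plain
    arrays for running-average bookkeeping.
    """
    axes = (0,) if x.ndim == 2 else (0, 2, 3)
    mu = x.data.mean(axis=axes)
    var = x.data.var(axis=axes)
    shape = (1, -1) if x.ndim == 2 else (1, -1, 1, 1)
    rstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * rstd.reshape(shape)
    y = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    del xhat  # recomputed in backward to keep the live graph lean
    out = Tensor(
        y,
        requires_grad=x.requires_grad or gamma.requires_grad or beta.requires_grad,
        _prev=(x, gamma, beta),
    )
    m = x.size // x.shape[1 if x.ndim == 4 else -1]

    def _backward():
        g = out.grad
        xhat = (x.data - mu.reshape(shape)) * rstd.reshape(shape)
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data.reshape(shape)
            s1 = dxhat.sum(axis=axes, keepdims=True)
            s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
            dx = (dxhat - s1 / m - xhat * s2 / m) * rstd.reshape(shape)
            x._accumulate(dx)

    out._backward = _backward
    return out, mu, var
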