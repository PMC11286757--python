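"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the operator set the network needs: broadcasted
arithmetic, matmul, the usual pointwise nonlinearities, axis reductions,
shape ops, 2-D convolution (with stride and dilation, im2col-based), 2x2 max
pooling, bilinear resizing and fancy indexing.  Gradients are accumulated on
:class:`Tensor` objects by :meth:`Tensor.backward`, which walks the recorded
graph in reverse topological order.

Convolution is the hot path: the forward gathers dilation-aware patches with
precomputed index arrays and reduces them with one BLAS matmul per batch;
the backward scatters patch gradients with ``bincount`` per sample, which is
far faster than ``np.add.at`` at these sizes.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import expit

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph recording (forward-only inference, no backward)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv2d",
    "maxpool2d",
    "bilinear_resize",
    "log_softmax",
    "cross_entropy",
]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


def _coerce(other, dtype) -> "Tensor":
    """Wrap ``other`` as a Tensor; scalar constants adopt ``dtype`` so they
    do not promote float32 graphs to float64."""
    if isinstance(other, Tensor):
        return other
    a = np.asarray(other)
    if a.ndim == 0:
        a = a.astype(dtype)
    return Tensor(a)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        if not _grad_enabled:
            requires_grad = False
            _prev = ()
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None, free_graph: bool = True) -> None:
        """Backpropagate from this tensor (default seed: ones).

        ``free_graph`` severs the recorded graph afterwards so large
        intermediate volumes are reclaimed immediately; pass False to
        backpropagate through the same graph again.
        """
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype).copy()
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        if free_graph:
            for node in topo:
                if node._backward is not None or node._prev:
                    node._backward = None
                    node._prev = ()

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _coerce(other, self.data.dtype)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _coerce(other, self.data.dtype)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = _coerce(other, self.data.dtype)
        return self + (-other)

    def __rsub__(self, other):
        return _coerce(other, self.data.dtype) + (-self)

    def __truediv__(self, other):
        other = _coerce(other, self.data.dtype)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _coerce(other, self.data.dtype) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = _bw if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = _coerce(other, self.data.dtype)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.data.shape))

        out._backward = _bw if out.requires_grad else None
        return out

    # -- pointwise --------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * out.data)

        out._backward = _bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = _bw if out.requires_grad else None
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = _bw if out.requires_grad else None
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out.data ** 2))

        out._backward = _bw if out.requires_grad else None
        return out

    def sigmoid(self):
        s = expit(self.data)
        out = Tensor(s, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * out.data * (1.0 - out.data))

        out._backward = _bw if out.requires_grad else None
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = _bw if out.requires_grad else None
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def _bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = _bw if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = _bw if out.requires_grad else None
        return out

    def max_along(self, axis: int):
        """Max over one axis with subgradient routed to the arg-max entry."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                      axis=axis).squeeze(axis)
        out = Tensor(out_data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis),
                                  np.expand_dims(g, axis), axis=axis)
                self._accum(full)

        out._backward = _bw if out.requires_grad else None
        return out


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = _bw if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _conv_indices(H, W, kh, kw, sh, sw, dh, dw, ph, pw):
    oh = (H + 2 * ph - (dh * (kh - 1) + 1)) // sh + 1
    ow = (W + 2 * pw - (dw * (kw - 1) + 1)) // sw + 1
    i0 = dh * np.repeat(np.arange(kh), kw)
    j0 = dw * np.tile(np.arange(kw), kh)
    i1 = sh * np.repeat(np.arange(oh), ow)
    j1 = sw * np.tile(np.arange(ow), oh)
    rows = i0[:, None] + i1[None, :]          # (K, L)
    cols = j0[:, None] + j1[None, :]
    return rows, cols, oh, ow


def _im2col(xdata: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            padding: int):
    """Patch matrix (N, C*kh*kw, L) plus output spatial dims."""
    N, C, H, W = xdata.shape
    if padding:
        xdata = np.pad(xdata, ((0, 0), (0, 0),
                               (padding, padding), (padding, padding)))
    span_h = dilation * (kh - 1) + 1
    span_w = dilation * (kw - 1) + 1
    win = np.lib.stride_tricks.sliding_window_view(xdata, (span_h, span_w),
                                                   axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    oh, ow = win.shape[2], win.shape[3]
    # single well-ordered copy into (N, C*K, L)
    col2 = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)
                                ).reshape(N, C * kh * kw, oh * ow)
    return col2, oh, ow


def _conv_raw(xdata: np.ndarray, wdata: np.ndarray, stride: int,
              dilation: int, padding: int):
    """Plain-NumPy cross-correlation; returns (out, col2) with col2 cached."""
    OC = wdata.shape[0]
    col2, oh, ow = _im2col(xdata, wdata.shape[2], wdata.shape[3],
                           stride, dilation, padding)
    w2 = wdata.reshape(OC, -1)
    out = np.matmul(w2[None], col2).reshape(xdata.shape[0], OC, oh, ow)
    return out, col2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, dilation: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout.

    ``x``: (N, C, H, W); ``w``: (OC, C, kh, kw); ``b``: (OC,) or None.
    The input gradient at stride 1 is computed as a convolution with the
    spatially flipped, channel-transposed kernel; strided convolutions fall
    back to an explicit column scatter.
    """
    N, C, H, W = x.data.shape
    OC, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input has {C}, kernel expects {Cw}")
    out_data, col2 = _conv_raw(x.data, w.data, stride, dilation, padding)
    if b is not None:
        out_data += b.data[None, :, None, None]
    oh, ow = out_data.shape[2], out_data.shape[3]
    K = kh * kw
    L = oh * ow

    prev = (x, w) if b is None else (x, w, b)
    req = any(t.requires_grad for t in prev)
    out = Tensor(out_data, req, prev)

    def _bw(g):
        g2 = np.ascontiguousarray(g.reshape(N, OC, L))
        if w.requires_grad:
            dw = np.matmul(g2, col2.swapaxes(1, 2)).sum(axis=0)
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=(0, 2)))
        if not x.requires_grad:
            return
        if stride == 1:
            w_rot = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            span = dilation * (kh - 1) + 1
            dx, _ = _conv_raw(g.reshape(N, OC, oh, ow), w_rot, 1, dilation,
                              span - 1 - padding)
            x._accum(dx)
        else:
            rows, cols, _, _ = _conv_indices(H, W, kh, kw, stride, stride,
                                             dilation, dilation,
                                             padding, padding)
            Hp, Wp = H + 2 * padding, W + 2 * padding
            flat = rows * Wp + cols
            idx1d = (np.arange(C)[:, None, None] * (Hp * Wp)
                     + flat[None]).ravel()
            w2 = w.data.reshape(OC, C * K)
            dcol = np.matmul(w2.T[None], g2)
            dxp = np.empty((N, C * Hp * Wp), dtype=x.data.dtype)
            for n in range(N):
                dxp[n] = np.bincount(idx1d, weights=dcol[n].ravel(),
                                     minlength=C * Hp * Wp)
            dxp = dxp.reshape(N, C, Hp, Wp)
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x._accum(dxp)

    out._backward = _bw if out.requires_grad else None
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max pooling with stride k; trailing rows/cols are dropped."""
    N, C, H, W = x.data.shape
    oh, ow = H // k, W // k
    xc = x.data[:, :, :oh * k, :ow * k]
    win = xc.reshape(N, C, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(N, C, oh, ow, k * k)
    idx = np.argmax(win, axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, x.requires_grad, (x,))

    def _bw(g):
        if not x.requires_grad:
            return
        dwin = np.zeros((N, C, oh, ow, k * k), dtype=x.data.dtype)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dxc = dwin.reshape(N, C, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
        dxc = dxc.reshape(N, C, oh * k, ow * k)
        if dxc.shape[2:] != (H, W):
            full = np.zeros_like(x.data)
            full[:, :, :oh * k, :ow * k] = dxc
            dxc = full
        x._accum(dxc)

    out._backward = _bw if out.requires_grad else None
    return out


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable bilinear resize of an NCHW tensor (half-pixel centers)."""
    N, C, H, W = x.data.shape
    if (H, W) == (out_h, out_w):
        return x
    ry = np.clip((np.arange(out_h) + 0.5) * H / out_h - 0.5, 0, H - 1)
    rx = np.clip((np.arange(out_w) + 0.5) * W / out_w - 0.5, 0, W - 1)
    y0 = np.floor(ry).astype(int)
    x0 = np.floor(rx).astype(int)
    y1 = np.minimum(y0 + 1, H - 1)
    x1 = np.minimum(x0 + 1, W - 1)
    wy = (ry - y0)[:, None]
    wx = (rx - x0)[None, :]
    w00 = (1 - wy) * (1 - wx)
    w01 = (1 - wy) * wx
    w10 = wy * (1 - wx)
    w11 = wy * wx
    d = x.data
    out_data = (d[:, :, y0[:, None], x0[None, :]] * w00 +
                d[:, :, y0[:, None], x1[None, :]] * w01 +
                d[:, :, y1[:, None], x0[None, :]] * w10 +
                d[:, :, y1[:, None], x1[None, :]] * w11)
    out = Tensor(out_data.astype(x.data.dtype), x.requires_grad, (x,))

    def _bw(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for wgt, yy, xx in ((w00, y0, x0), (w01, y0, x1),
                            (w10, y1, x0), (w11, y1, x1)):
            np.add.at(dx, (slice(None), slice(None), yy[:, None], xx[None, :]),
                      g * wgt)
        x._accum(dx)

    out._backward = _bw if out.requires_grad else None
    return out


def log_softmax(z: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax (max is subtracted as a constant)."""
    m = Tensor(z.data.max(axis=axis, keepdims=True))
    zs = z - m
    return zs - zs.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw logits and integer labels."""
    n, k = logits.data.shape
    onehot = np.zeros((n, k), dtype=logits.data.dtype)
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    logp = log_softmax(logits, axis=1)
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)
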