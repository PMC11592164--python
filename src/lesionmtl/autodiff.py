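"""Minimal tape-based reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the multi-task U-Net needs: strided 3x3 /
1x1 convolution (im2col + BLAS matmul), 2x2 stride-2 transpose convolution,
batch normalization with running statistics, dense layers, ReLU / sigmoid /
softmax, global and axis-wise pooling, differentiable bilinear resizing, and
broadcasting arithmetic. All computation is float32.

A :class:`Tensor` records its parents and a backward closure; calling
``backward()`` on a scalar loss topologically sorts the tape and accumulates
gradients into every tensor created with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph mechanics ---------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def item(self) -> float:
        return float(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts) -> bool:
    return any(t.requires_grad or t._backward is not None for t in ts)


def _unbroadcast(grad, shape):
    """Reduce a broadcast gradient back to ``shape``."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _binary(a, b, out, da, db):
    a, b = as_tensor(a), as_tensor(b)
    if not _needs(a, b):
        return Tensor(out)

    def backward(g):
        if a.requires_grad or a._backward is not None:
            a._accum(_unbroadcast(da(g), a.data.shape))
        if b.requires_grad or b._backward is not None:
            b._accum(_unbroadcast(db(g), b.data.shape))

    return Tensor(out, parents=(a, b), backward=backward)


# -- arithmetic ------------------------------------------------------------


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(
        a,
        b,
        a.data / b.data,
        lambda g: g / b.data,
        lambda g: -g * a.data / (b.data * b.data),
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data
    if not _needs(a, b):
        return Tensor(out)

    def backward(g):
        if a.requires_grad or a._backward is not None:
            a._accum(g @ b.data.T)
        if b.requires_grad or b._backward is not None:
            b._accum(a.data.T @ g)

    return Tensor(out, parents=(a, b), backward=backward)


# -- elementwise nonlinearities -------------------------------------------


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.maximum(x.data, 0.0)
    if not _needs(x):
        return Tensor(out)

    def backward(g):
        x._accum(g * (x.data > 0))

    return Tensor(out, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))
    if not _needs(x):
        return Tensor(out)

    def backward(g):
        x._accum(g * out * (1.0 - out))

    return Tensor(out, parents=(x,), backward=backward)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.log(x.data)
    if not _needs(x):
        return Tensor(out)

    def backward(g):
        x._accum(g / x.data)

    return Tensor(out, parents=(x,), backward=backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only where unclamped."""
    x = as_tensor(x)
    out = np.clip(x.data, lo, hi)
    if not _needs(x):
        return Tensor(out)
    mask = (x.data > lo) & (x.data < hi)

    def backward(g):
        x._accum(g * mask)

    return Tensor(out, parents=(x,), backward=backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)
    if not _needs(x):
        return Tensor(out)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accum(out * (g - dot))

    return Tensor(out, parents=(x,), backward=backward)


# -- reductions and shaping -----------------------------------------------


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)
    if not _needs(x):
        return Tensor(out)

    def backward(g):
        if axis is None:
            x._accum(np.broadcast_to(g, x.data.shape).astype(DTYPE))
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        x._accum(np.broadcast_to(gg, x.data.shape).astype(DTYPE))

    return Tensor(out, parents=(x,), backward=backward)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


def tmax(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; subgradient routed to the (first) argmax."""
    x = as_tensor(x)
    out = x.data.max(axis=axis, keepdims=keepdims)
    if not _needs(x):
        return Tensor(out)
    expanded = out if keepdims else np.expand_dims(out, axis)
    mask = x.data == expanded
    # split ties evenly so the gradient stays a subgradient
    mask = mask / mask.sum(axis=axis, keepdims=True)

    def backward(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        x._accum(mask * gg)

    return Tensor(out, parents=(x,), backward=backward)


def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    out = x.data.reshape(shape)
    if not _needs(x):
        return Tensor(out)

    def backward(g):
        x._accum(g.reshape(x.data.shape))

    return Tensor(out, parents=(x,), backward=backward)


def slice_channels(x: Tensor, lo: int, hi: int) -> Tensor:
    """Select channels [lo, hi) of an (N, C, ...) tensor."""
    x = as_tensor(x)
    out = x.data[:, lo:hi]
    if not _needs(x):
        return Tensor(out)

    def backward(g):
        gg = np.zeros_like(x.data)
        gg[:, lo:hi] = g
        x._accum(gg)

    return Tensor(out, parents=(x,), backward=backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    if not any(_needs(t) for t in tensors):
        return Tensor(out)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._backward is not None:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out, parents=tuple(tensors), backward=backward)


# -- convolution -----------------------------------------------------------


def _im2col(x, k, stride, pad):
    N, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    cols = np.empty((N, C, k, k, Ho, Wo), dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride]
    return cols.reshape(N, C * k * k, Ho * Wo), Ho, Wo


def _col2im(dcols, xshape, k, stride, pad, Ho, Wo):
    N, C, H, W = xshape
    dcols = dcols.reshape(N, C, k, k, Ho, Wo)
    dx = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad : pad + H, pad : pad + W]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int | None = None) -> Tensor:
    """2-D convolution; ``w`` has shape (out, in, k, k), ``b`` shape (out,)."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    F, C, k, _ = w.data.shape
    if pad is None:
        pad = k // 2
    cols, Ho, Wo = _im2col(x.data, k, stride, pad)
    wmat = w.data.reshape(F, C * k * k)
    out = np.matmul(wmat, cols) + b.data[:, None]
    N = x.data.shape[0]
    out = out.reshape(N, F, Ho, Wo)
    if not _needs(x, w, b):
        return Tensor(out)

    def backward(g):
        gflat = g.reshape(N, F, Ho * Wo)
        if w.requires_grad or w._backward is not None:
            dw = np.einsum("nfl,ncl->fc", gflat, cols, optimize=True)
            w._accum(dw.reshape(w.data.shape))
        if b.requires_grad or b._backward is not None:
            b._accum(gflat.sum(axis=(0, 2)))
        if x.requires_grad or x._backward is not None:
            dcols = np.matmul(wmat.T, gflat)
            x._accum(_col2im(dcols, x.data.shape, k, stride, pad, Ho, Wo))

    return Tensor(out, parents=(x, w, b), backward=backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 transpose convolution (exact x2 upsampling).

    ``w`` has shape (in, out, 2, 2), ``b`` shape (out,).
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    N, C, H, W = x.data.shape
    _, F, _, _ = w.data.shape
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N,H,W,F,2,2)
    out = t.transpose(0, 3, 1, 4, 2, 5).reshape(N, F, 2 * H, 2 * W)
    out = out + b.data[None, :, None, None]
    if not _needs(x, w, b):
        return Tensor(out)

    def backward(g):
        blocks = g.reshape(N, F, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)  # (N,H,W,F,2,2)
        if x.requires_grad or x._backward is not None:
            dx = np.tensordot(blocks, w.data, axes=([3, 4, 5], [1, 2, 3]))  # (N,H,W,C)
            x._accum(dx.transpose(0, 3, 1, 2).astype(DTYPE))
        if w.requires_grad or w._backward is not None:
            dw = np.tensordot(x.data, blocks, axes=([0, 2, 3], [0, 1, 2]))  # (C,F,2,2)
            w._accum(dw.astype(DTYPE))
        if b.requires_grad or b._backward is not None:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor(out, parents=(x, w, b), backward=backward)


# -- normalization ---------------------------------------------------------


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    ``running_mean``/``running_var`` are plain arrays mutated in place during
    training forward passes and consulted in eval mode.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    if not _needs(x, gamma, beta):
        return Tensor(out)

    def backward(g):
        if gamma.requires_grad or gamma._backward is not None:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad or beta._backward is not None:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._backward is not None:
            gx = g * gamma.data[None, :, None, None]
            if training:
                M = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                s1 = gx.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gx * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (inv_std[None, :, None, None] / M) * (M * gx - s1 - xhat * s2)
            else:
                dx = gx * inv_std[None, :, None, None]
            x._accum(dx.astype(DTYPE))

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


# -- pooling and resizing --------------------------------------------------


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C)."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    out = x.data.mean(axis=(2, 3))
    if not _needs(x):
        return Tensor(out)

    def backward(g):
        x._accum(np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape).astype(DTYPE))

    return Tensor(out, parents=(x,), backward=backward)


def global_max_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C); subgradient to the maxima."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    flat = x.data.reshape(N, C, H * W)
    out = flat.max(axis=2)
    if not _needs(x):
        return Tensor(out)
    mask = flat == out[:, :, None]
    mask = mask / mask.sum(axis=2, keepdims=True)

    def backward(g):
        x._accum((mask * g[:, :, None]).reshape(x.data.shape).astype(DTYPE))

    return Tensor(out, parents=(x,), backward=backward)


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers)."""
    R = np.zeros((n_out, n_in), dtype=DTYPE)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = (src - lo).astype(DTYPE)
    np.add.at(R, (np.arange(n_out), lo), 1.0 - w)
    np.add.at(R, (np.arange(n_out), hi), w)
    return R


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable bilinear resize of (N,C,H,W) to (N,C,out_h,out_w)."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    if (H, W) == (out_h, out_w):
        return x
    Ry = _resize_matrix(H, out_h)
    Rx = _resize_matrix(W, out_w)
    out = np.matmul(np.matmul(Ry, x.data), Rx.T)
    if not _needs(x):
        return Tensor(out)

    def backward(g):
        x._accum(np.matmul(np.matmul(Ry.T, g), Rx).astype(DTYPE))

    return Tensor(out, parents=(x,), backward=backward)


# -- layers ----------------------------------------------------------------


class Layer:
    def parameters(self):
        return []


class Conv2d(Layer):
    def __init__(self, c_in, c_out, k, stride, rng):
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, (c_out, c_in, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.k = k

    def __call__(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride)

    def parameters(self):
        return [self.w, self.b]


class ConvTranspose2d(Layer):
    def __init__(self, c_in, c_out, rng):
        std = np.sqrt(2.0 / (c_in * 4))
        self.w = Tensor(rng.normal(0.0, std, (c_in, c_out, 2, 2)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return conv_transpose2d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class BatchNorm2d(Layer):
    def __init__(self, c):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.training = True

    def __call__(self, x):
        return batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var, self.training
        )

    def parameters(self):
        return [self.gamma, self.beta]


class Linear(Layer):
    def __init__(self, n_in, n_out, rng):
        std = np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0.0, std, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x):
        return add(matmul(x, self.w), self.b)

    def parameters(self):
        return [self.w, self.b]


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
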