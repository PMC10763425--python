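"""Minimal deterministic neural-network engine on numpy.

Tensors are NCHW. Every layer implements ``forward`` (caching whatever its
backward pass needs), ``backward`` (returning the gradient w.r.t. its input
and accumulating parameter gradients), ``params`` and ``out_shape``. There is
no autodiff graph: gradients are written out explicitly so the whole engine
stays small, single-threaded-reproducible and inspectable.

Convolution is implemented once, as an im2col + GEMM primitive
(:func:`conv2d`); the input gradient and the transposed convolution are both
expressed through the same primitive via zero-dilation and kernel flipping,
so one well-tested code path serves forward and backward of both layer types.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Sequential",
    "AdamW",
    "softmax",
    "sigmoid",
]


class Param:
    """A trainable tensor with its gradient accumulator.

    ``no_decay`` marks parameters (biases, norm scales/shifts) excluded from
    decoupled weight decay.
    """

    __slots__ = ("data", "grad", "no_decay")

    def __init__(self, data: np.ndarray, no_decay: bool = False):
        self.data = data
        self.grad = np.zeros_like(data)
        self.no_decay = no_decay

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# convolution primitive
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, p: int, value: float = 0.0) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=value)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> tuple[np.ndarray, int, int]:
    """Return (N, C*kh*kw, L) patch matrix for a pre-padded input."""
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows).reshape(n, c * kh * kw, ho * wo)
    return cols, ho, wo


def conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0,
           _return_cols: bool = False):
    """Cross-correlation of NCHW input ``x`` with ``w`` of shape (Co, Ci, kh, kw)."""
    co, ci, kh, kw = w.shape
    xp = _pad_hw(x, pad)
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    y = np.matmul(w.reshape(co, -1), cols)  # (N, Co, L)
    y = y.reshape(x.shape[0], co, ho, wo)
    if _return_cols:
        return y, cols
    return y


def _dilate(x: np.ndarray, stride: int, out_h: int | None = None,
            out_w: int | None = None) -> np.ndarray:
    """Insert stride-1 zeros between spatial elements (adjoint of striding)."""
    n, c, h, w = x.shape
    th = (h - 1) * stride + 1 if out_h is None else out_h
    tw = (w - 1) * stride + 1 if out_w is None else out_w
    if stride == 1 and th == h and tw == w:
        return x
    out = np.zeros((n, c, th, tw), dtype=x.dtype)
    out[:, :, ::stride, ::stride][:, :, :h, :w] = x
    return out


def _flip_swap(w: np.ndarray) -> np.ndarray:
    """Spatially flip the kernel and swap in/out channel axes."""
    return np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))


def conv2d_input_grad(dy: np.ndarray, w: np.ndarray, stride: int, pad: int,
                      in_h: int, in_w: int) -> np.ndarray:
    """Gradient of conv2d w.r.t. its input (also the transposed-conv forward)."""
    co, ci, kh, kw = w.shape
    dyd = _dilate(dy, stride, in_h + 2 * pad - kh + 1, in_w + 2 * pad - kw + 1)
    dxp = conv2d(dyd, _flip_swap(w), stride=1, pad=kh - 1)
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d_weight_grad(cols: np.ndarray, dy: np.ndarray, w_shape) -> np.ndarray:
    n = dy.shape[0]
    co = w_shape[0]
    dy2 = dy.reshape(n, co, -1)
    dw = np.einsum("nol,nkl->ok", dy2, cols, optimize=True)
    return dw.reshape(w_shape)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def out_shape(self, shape: tuple[int, int, int]) -> tuple[int, int, int]:
        """Shape propagation on (C, H, W) without allocating activations."""
        return shape

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, ksize: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = ksize // 2 if pad is None else pad
        self.ksize = ksize
        self.w = Param(he_init(rng, (cout, cin, ksize, ksize), cin * ksize * ksize, dtype))
        self.b = Param(np.zeros(cout, dtype=dtype), no_decay=True) if bias else None
        self._cache = None

    def forward(self, x, training=False):
        y, cols = conv2d(x, self.w.data, self.stride, self.pad, _return_cols=True)
        if self.b is not None:
            y += self.b.data[None, :, None, None]
        self._cache = (x.shape, cols)
        return y

    def backward(self, dy):
        x_shape, cols = self._cache
        self.w.grad += conv2d_weight_grad(cols, dy, self.w.data.shape)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        return conv2d_input_grad(dy, self.w.data, self.stride, self.pad,
                                 x_shape[2], x_shape[3])

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def out_shape(self, shape):
        c, h, w = shape
        k, s, p = self.ksize, self.stride, self.pad
        return (self.w.data.shape[0], (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)


class ConvTranspose2d(Layer):
    """Transposed convolution; weight shape (Cin, Cout, k, k), torch convention."""

    def __init__(self, cin: int, cout: int, ksize: int, stride: int = 1,
                 pad: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = pad
        self.ksize = ksize
        self.w = Param(he_init(rng, (cin, cout, ksize, ksize), cin * ksize * ksize, dtype))
        self.b = Param(np.zeros(cout, dtype=dtype), no_decay=True) if bias else None
        self._cache = None

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.ksize, self.stride, self.pad
        return (h - 1) * s + k - 2 * p, (w - 1) * s + k - 2 * p

    def forward(self, x, training=False):
        oh, ow = self._out_hw(x.shape[2], x.shape[3])
        # adjoint of conv2d(·, w, stride, pad) mapping output grads back to inputs
        y = conv2d_input_grad(x, self.w.data, self.stride, self.pad, oh, ow)
        if self.b is not None:
            y += self.b.data[None, :, None, None]
        self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        # dX of the adjoint is the plain convolution of dy with w
        dyp = _pad_hw(dy, self.pad)
        cols, _, _ = _im2col(dyp, self.ksize, self.ksize, self.stride)
        dx = np.matmul(self.w.data.reshape(self.w.data.shape[0], -1), cols)
        dx = dx.reshape(x.shape)
        # dW: correlate dy (as conv input) against x (as conv output grad)
        self.w.grad += conv2d_weight_grad(cols, x, self.w.data.shape)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        return dx

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def out_shape(self, shape):
        c, h, w = shape
        oh, ow = self._out_hw(h, w)
        return (self.w.data.shape[1], oh, ow)


class BatchNorm2d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(c, dtype=dtype), no_decay=True)
        self.beta = Param(np.zeros(c, dtype=dtype), no_decay=True)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy):
        xhat, std = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        mean_dy = dy.sum(axis=(0, 2, 3))[None, :, None, None] / n
        mean_dyx = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None] / n
        return (g / std[None, :, None, None]) * (dy - mean_dy - xhat * mean_dyx)

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    def __init__(self, ksize: int = 3, stride: int = 2, pad: int = 1):
        self.ksize, self.stride, self.pad = ksize, stride, pad

    def forward(self, x, training=False):
        xp = _pad_hw(x, self.pad, value=-np.inf)
        n, c, h, w = xp.shape
        k, s = self.ksize, self.stride
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        s0, s1, s2, s3 = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, (n, c, ho, wo, k, k), (s0, s1, s2 * s, s3 * s, s2, s3), writeable=False)
        win = win.reshape(n, c, ho, wo, k * k)
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._in_shape
        k, s, p = self.ksize, self.stride, self.pad
        ho, wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        gi, gj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        ai = self._arg // k + gi[None, None] * s
        aj = self._arg % k + gj[None, None] * s
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, ai, aj), dy)
        return dxp[:, :, p:h + p, p:w + p] if p else dxp

    def out_shape(self, shape):
        c, h, w = shape
        k, s, p = self.ksize, self.stride, self.pad
        return (c, (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (N, C, H, W) -> (N, C)."""

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).astype(dy.dtype)

    def out_shape(self, shape):
        return (shape[0],)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)

    def out_shape(self, shape):
        return (int(np.prod(shape)),)


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.w = Param(he_init(rng, (nout, nin), nin, dtype))
        self.b = Param(np.zeros(nout, dtype=dtype), no_decay=True)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.data

    def params(self):
        return [self.w, self.b]

    def out_shape(self, shape):
        return (self.w.data.shape[0],)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def out_shape(self, shape):
        for layer in self.layers:
            shape = layer.out_shape(shape)
        return shape


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay.

    ``beta1`` is the first-moment coefficient (the recipe's "momentum");
    ``beta2`` stays at the conventional 0.999.
    """

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and not p.no_decay:
                p.data -= self.lr * self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
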