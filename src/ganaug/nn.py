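"""Minimal numpy neural-network layers with manual backpropagation.

All layers follow the same contract: ``forward(x, train)`` caches what the
backward pass needs, ``backward(dout)`` returns the gradient with respect to
the layer input and accumulates parameter gradients in ``grads``.  Tensors are
NCHW ``float64``.  Every source of randomness (initialisation, dropout masks)
comes from a ``numpy.random.Generator`` supplied by the caller, so identical
seeds give bit-identical training runs on a fixed platform.

The library covers exactly what the adversarial and classification networks
in this package need: dense, strided convolution, transposed convolution,
batch normalisation, max/average pooling, nearest-neighbour upsampling, the
usual activations, dropout, and Adam.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------


def _out_size(h: int, k: int, s: int, p: int) -> int:
    return (h + 2 * p - k) // s + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Unfold (N, C, H, W) into (N, C*k*k, OH*OW) patch columns."""
    n, c, h, w = x.shape
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back into an image."""
    n, c, h, w = x_shape
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    cols = cols.reshape(n, c, k, k, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Layer:
    """Base layer; stateless layers keep the default empty parameter lists."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0] += self._x.T @ dout
        self.grads[1] += dout.sum(axis=0)
        return dout @ self.w.T


class Conv2d(Layer):
    """Strided 2-D convolution (cross-correlation) on NCHW tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, zero_init: bool = False):
        super().__init__()
        if pad is None:
            pad = k // 2
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * k * k
        self.w = np.zeros((c_out, fan_in)) if zero_init else he_init(rng, (c_out, fan_in), fan_in)
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._xshape = x.shape
        self._cols = im2col(x, self.k, self.stride, self.pad)
        n = x.shape[0]
        oh = _out_size(x.shape[2], self.k, self.stride, self.pad)
        ow = _out_size(x.shape[3], self.k, self.stride, self.pad)
        y = np.einsum("of,nfl->nol", self.w, self._cols, optimize=True)
        return y.reshape(n, self.c_out, oh, ow) + self.b[None, :, None, None]

    def backward(self, dout):
        n, _, oh, ow = dout.shape
        dflat = dout.reshape(n, self.c_out, oh * ow)
        self.grads[0] += np.einsum("nol,nfl->of", dflat, self._cols, optimize=True)
        self.grads[1] += dflat.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", self.w, dflat, optimize=True)
        return col2im(dcols, self._xshape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed (fractionally strided) convolution: the adjoint of Conv2d."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 2, pad: int = 1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * k * k
        self.w = he_init(rng, (c_in, c_out * k * k), fan_in)
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h - 1) * self.stride - 2 * self.pad + self.k,
                (w - 1) * self.stride - 2 * self.pad + self.k)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        self._xflat = x.reshape(n, c, h * w)
        cols = np.einsum("cf,ncl->nfl", self.w, self._xflat, optimize=True)
        y = col2im(cols, (n, self.c_out, oh, ow), self.k, self.stride, self.pad)
        self._oshape = y.shape
        return y + self.b[None, :, None, None]

    def backward(self, dout):
        n = dout.shape[0]
        dcols = im2col(dout, self.k, self.stride, self.pad)
        self.grads[0] += np.einsum("ncl,nfl->cf", self._xflat, dcols, optimize=True)
        self.grads[1] += dout.sum(axis=(0, 2, 3))
        dx = np.einsum("cf,nfl->ncl", self.w, dcols, optimize=True)
        h = int(np.sqrt(dx.shape[2]))
        return dx.reshape(n, self.c_in, h, h)


class BatchNorm(Layer):
    """Batch normalisation over (N,) or (N, H, W) per channel."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    @staticmethod
    def _axes(x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    @staticmethod
    def _bc(v, x):
        return v if x.ndim == 2 else v[None, :, None, None]

    def forward(self, x, train=False):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - self._bc(mean, x)) / self._bc(self._std, x)
        self._m = x.size // x.shape[1]
        self._train = train
        return self._bc(self.gamma, x) * self._xhat + self._bc(self.beta, x)

    def backward(self, dout):
        axes = self._axes(dout)
        self.grads[0] += (dout * self._xhat).sum(axis=axes)
        self.grads[1] += dout.sum(axis=axes)
        dxhat = dout * self._bc(self.gamma, dout)
        if not self._train:
            return dxhat / self._bc(self._std, dout)
        m = self._m
        term = dxhat - dxhat.mean(axis=axes, keepdims=True) \
            - self._xhat * (dxhat * self._xhat).sum(axis=axes, keepdims=True) / m
        return term / self._bc(self._std, dout)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y ** 2)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; input sides must be even."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=4)
        self._xshape = x.shape
        return xr.max(axis=4)

    def backward(self, dout):
        n, c, oh, ow = dout.shape
        dxr = np.zeros((n, c, oh, ow, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=4)
        return dxr.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(self._xshape)


class AvgPool2(Layer):
    """2x2 average pooling with stride 2."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        self._xshape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    """Inverted dropout; identity when evaluating or when rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False):
        self._xshape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    @property
    def all_params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def all_grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()


def collect(*modules: Layer):
    """Flatten parameter/gradient lists of several layers or Sequentials."""
    params, grads = [], []
    for m in modules:
        if isinstance(m, Sequential):
            params += m.all_params
            grads += m.all_grads
        else:
            params += m.params
            grads += m.grads
    return params, grads


# ---------------------------------------------------------------------------
# Optimiser and losses
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0


def bce_with_logits(logits: np.ndarray, target: float | np.ndarray):
    """Binary cross-entropy on raw logits; returns (mean loss, dlogits)."""
    z = np.clip(logits, -60, 60)
    p = 1.0 / (1.0 + np.exp(-z))
    t = np.broadcast_to(np.asarray(target, dtype=float), logits.shape)
    loss = -(t * np.log(p + 1e-12) + (1 - t) * np.log(1 - p + 1e-12)).mean()
    return loss, (p - t) / logits.size


def mse_loss(pred: np.ndarray, target: float | np.ndarray):
    t = np.broadcast_to(np.asarray(target, dtype=float), pred.shape)
    diff = pred - t
    return float((diff ** 2).mean()), 2.0 * diff / pred.size


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy for integer labels; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), labels] + 1e-12).mean())
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, d / n
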