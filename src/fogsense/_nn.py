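"""A small numpy neural-network engine: layers, losses, optimizers.

Implements exactly what the package's classifiers need — 2-D convolution
("same" zero padding, stride 1) with max pooling and dropout, dense layers,
leaky-rectifier activations, stacked bidirectional LSTM layers with full
backpropagation through time, softmax cross-entropy, and RMSProp/Adam
optimizers.  Everything is deterministic given a seeded
``numpy.random.Generator``: weight initialization, minibatch shuffling and
dropout masks all draw from generators the caller controls.

Array conventions: images are (N, C, H, W); sequences are (N, T, D).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv2D",
    "MaxPool2",
    "LeakyReLU",
    "ReLU",
    "Dropout",
    "Flatten",
    "BiLSTM",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "RMSProp",
    "Adam",
    "make_optimizer",
]


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_uniform_fan_in(rng, n_in, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gout):
        self.W.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.W.value.T


class Conv2D(Layer):
    """Stride-1 convolution with "same" zero padding via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        self.W = Param(_uniform_fan_in(rng, fan_in, (fan_in, c_out)))
        self.b = Param(np.zeros(c_out))
        # even kernels pad asymmetrically: total padding = kernel - 1
        self.pad_lo = (kernel - 1) // 2
        self.pad_hi = kernel - 1 - self.pad_lo

    def params(self):
        return [self.W, self.b]

    def forward(self, x, *, train=False, rng=None):
        n, c, h, w = x.shape
        k = self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_lo, self.pad_hi), (self.pad_lo, self.pad_hi)))
        # (N, C, H, W, k, k) view -> columns (N*H*W, C*k*k)
        patches = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        self._cols, self._shape = cols, (n, c, h, w)
        out = cols @ self.W.value + self.b.value
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gout):
        n, c, h, w = self._shape
        k = self.kernel
        g = gout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.W.grad += self._cols.T @ g
        self.b.grad += g.sum(axis=0)
        gcols = (g @ self.W.value.T).reshape(n, h, w, c, k, k)
        gx = np.zeros((n, c, h + k - 1, w + k - 1))
        for di in range(k):
            for dj in range(k):
                gx[:, :, di:di + h, dj:dj + w] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return gx[:, :, self.pad_lo:self.pad_lo + h, self.pad_lo:self.pad_lo + w]


class MaxPool2(Layer):
    """2×2 max pooling; spatial dimensions must be even."""

    def forward(self, x, *, train=False, rng=None):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._arg = r.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gout):
        n, c, h, w = self._shape
        g4 = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(g4, self._arg[..., None], gout[..., None], axis=-1)
        g = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(n, c, h, w)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.3):
        self.alpha = alpha

    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, gout):
        return np.where(self._mask, gout, self.alpha * gout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Dropout(Layer):
    """Inverted dropout: active only when training with an rng supplied."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Flatten(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMDirection:
    """One directional LSTM pass over (N, T, D) with full BPTT."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.h = hidden
        self.Wx = Param(_uniform_fan_in(rng, n_in, (n_in, 4 * hidden)))
        self.Wh = Param(_uniform_fan_in(rng, hidden, (hidden, 4 * hidden)))
        self.b = Param(np.zeros(4 * hidden))

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x):
        n, t, d = x.shape
        hdim = self.h
        self._x = x
        h = np.zeros((n, hdim))
        c = np.zeros((n, hdim))
        self._cache = []
        hs = np.empty((n, t, hdim))
        for step in range(t):
            z = x[:, step] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim:2 * hdim])
            g = np.tanh(z[:, 2 * hdim:3 * hdim])
            o = _sigmoid(z[:, 3 * hdim:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, step] = h
        self._hs = hs
        return hs

    def backward(self, ghs):
        """ghs: gradient w.r.t. every hidden output (N, T, H)."""
        x = self._x
        n, t, d = x.shape
        hdim = self.h
        gx = np.zeros_like(x)
        gh_next = np.zeros((n, hdim))
        gc_next = np.zeros((n, hdim))
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            gh = ghs[:, step] + gh_next
            go = gh * tc
            gc = gh * o * (1 - tc * tc) + gc_next
            gi = gc * g
            gf = gc * c_prev
            gg = gc * i
            gz = np.concatenate(
                [gi * i * (1 - i), gf * f * (1 - f), gg * (1 - g * g), go * o * (1 - o)],
                axis=1,
            )
            self.Wx.grad += x[:, step].T @ gz
            self.Wh.grad += h_prev.T @ gz
            self.b.grad += gz.sum(axis=0)
            gx[:, step] = gz @ self.Wx.value.T
            gh_next = gz @ self.Wh.value.T
            gc_next = gc * f
        return gx


class BiLSTM(Layer):
    """Bidirectional LSTM layer with tanh cell activations.

    With ``return_sequences`` the forward and backward hidden tracks are
    concatenated per time step, giving (N, T, 2H); otherwise the two final
    states are concatenated into (N, 2H).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = True):
        self.fwd = _LSTMDirection(n_in, hidden, rng)
        self.bwd = _LSTMDirection(n_in, hidden, rng)
        self.return_sequences = return_sequences
        self.hidden = hidden

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, *, train=False, rng=None):
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        if self.return_sequences:
            return np.concatenate([hf, hb], axis=2)
        return np.concatenate([hf[:, -1], hb[:, 0]], axis=1)

    def backward(self, gout):
        n = gout.shape[0]
        hdim = self.hidden
        t = self.fwd._hs.shape[1]
        if self.return_sequences:
            gf, gb = gout[..., :hdim], gout[..., hdim:]
        else:
            gf = np.zeros((n, t, hdim))
            gb = np.zeros((n, t, hdim))
            gf[:, -1] = gout[:, :hdim]
            gb[:, 0] = gout[:, hdim:]
        gx_f = self.fwd.backward(gf)
        gx_b = self.bwd.backward(gb[:, ::-1])[:, ::-1]
        return gx_f + gx_b


class Sequential:
    """A feed-forward stack of layers producing class logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x, *, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class _Optimizer:
    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        raise NotImplementedError


class RMSProp(_Optimizer):
    def __init__(self, params, lr=1e-4, rho=0.9, eps=1e-8):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self.v):
            v *= self.rho
            v += (1 - self.rho) * p.grad ** 2
            p.value -= self.lr * p.grad / (np.sqrt(v) + self.eps)


class Adam(_Optimizer):
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def make_optimizer(name: str, params: list[Param], lr: float) -> _Optimizer:
    name = name.lower()
    if name == "rmsprop":
        return RMSProp(params, lr=lr)
    if name == "adam":
        return Adam(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
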