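"""Minimal neural-network engine: layers with explicit backprop, SGD+momentum.

Supports exactly what the artefact classifiers need — stride-1
shape-preserving 2D/3D convolution, 2x max pooling (odd trailing rows/columns
trimmed), ReLU, inverted dropout, dense layers, an LSTM read out at its final
step, and softmax cross-entropy with optional per-sample weights.  Everything
is plain numpy; convolutions use sliding-window views + tensordot, and every
layer's gradient is validated by finite differences in the test suite.

Initialisation is zero-mean Gaussian.  The default scale is He (sqrt(2 /
fan_in)), which keeps deep ReLU stacks numerically stable; ``init="unit"``
gives literal unit-standard-deviation draws.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d", "Conv3d", "MaxPool2d", "MaxPool3d", "ReLU", "Dropout",
    "Flatten", "Dense", "LSTMLast", "Sequential", "LRCNNet",
    "softmax", "softmax_cross_entropy", "SGD", "clip_global_norm",
]

_swv = np.lib.stride_tricks.sliding_window_view


def _init_std(init: str, fan_in: int) -> float:
    if init == "he":
        return float(np.sqrt(2.0 / fan_in))
    if init == "unit":
        return 1.0
    raise ValueError(f"unknown init {init!r}")


class Layer:
    """Base layer; parameter-free layers inherit the empty param lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 same-padding 2D convolution on (N, C, H, W)."""

    def __init__(self, cin: int, cout: int, k: int = 3, *,
                 rng: np.random.Generator, dtype=np.float32, init: str = "he"):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        std = _init_std(init, cin * k * k)
        self.k = k
        self.w = rng.normal(0.0, std, (cout, cin, k, k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, train=False, rng=None):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = _swv(xp, (self.k, self.k), axis=(2, 3))      # (N,C,H,W,k,k) view
        out = np.tensordot(win, self.w, axes=([1, 4, 5], [1, 2, 3]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        out += self.b[None, :, None, None]
        self._win = win if train else None
        return out

    def backward(self, dout):
        win = self._win
        self.gw[...] = np.tensordot(dout, win, axes=([0, 2, 3], [0, 2, 3]))
        self.gb[...] = dout.sum(axis=(0, 2, 3))
        # transpose of a stride-1 same-padded conv = conv with the kernel
        # flipped spatially and in/out channels swapped
        wr = np.ascontiguousarray(np.flip(self.w, axis=(2, 3)).swapaxes(0, 1))
        p = self.k // 2
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        wind = _swv(dp, (self.k, self.k), axis=(2, 3))
        dx = np.tensordot(wind, wr, axes=([1, 4, 5], [1, 2, 3]))
        self._win = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class Conv3d(Layer):
    """Stride-1 same-padding 3D convolution on (N, C, D, H, W)."""

    def __init__(self, cin: int, cout: int, k: int = 3, *,
                 rng: np.random.Generator, dtype=np.float32, init: str = "he"):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        std = _init_std(init, cin * k ** 3)
        self.k = k
        self.w = rng.normal(0.0, std, (cout, cin, k, k, k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, train=False, rng=None):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = _swv(xp, (self.k, self.k, self.k), axis=(2, 3, 4))  # (N,C,D,H,W,k,k,k)
        out = np.tensordot(win, self.w, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        out = np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))
        out += self.b[None, :, None, None, None]
        self._win = win if train else None
        return out

    def backward(self, dout):
        win = self._win
        self.gw[...] = np.tensordot(dout, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        self.gb[...] = dout.sum(axis=(0, 2, 3, 4))
        wr = np.ascontiguousarray(np.flip(self.w, axis=(2, 3, 4)).swapaxes(0, 1))
        p = self.k // 2
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        wind = _swv(dp, (self.k, self.k, self.k), axis=(2, 3, 4))
        dx = np.tensordot(wind, wr, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        self._win = None
        return np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3))


class MaxPool2d(Layer):
    """2x2 max pooling; trailing odd rows/columns are trimmed."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        if h2 == 0 or w2 == 0:
            raise ValueError(f"input {x.shape} too small to pool")
        xt = x[:, :, :h2 * 2, :w2 * 2]
        xr = xt.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxt = dxr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * 2, w2 * 2)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, :h2 * 2, :w2 * 2] = dxt
        return dx


class MaxPool3d(Layer):
    """2x2x2 max pooling on (N, C, D, H, W); odd remainders trimmed."""

    def forward(self, x, train=False, rng=None):
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        if d2 == 0 or h2 == 0 or w2 == 0:
            raise ValueError(f"input {x.shape} too small to pool")
        xt = x[:, :, :d2 * 2, :h2 * 2, :w2 * 2]
        xr = (xt.reshape(n, c, d2, 2, h2, 2, w2, 2)
                .transpose(0, 1, 2, 4, 6, 3, 5, 7)
                .reshape(n, c, d2, h2, w2, 8))
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, d, h, w = self._in_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dxr = np.zeros((n, c, d2, h2, w2, 8), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxt = (dxr.reshape(n, c, d2, h2, w2, 2, 2, 2)
                  .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                  .reshape(n, c, d2 * 2, h2 * 2, w2 * 2))
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, :d2 * 2, :h2 * 2, :w2 * 2] = dxt
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity otherwise."""

    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must lie in [0, 1); got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, fin: int, fout: int, *, rng: np.random.Generator,
                 dtype=np.float32, init: str = "he"):
        std = _init_std(init, fin)
        self.w = rng.normal(0.0, std, (fin, fout)).astype(dtype)
        self.b = np.zeros(fout, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, train=False, rng=None):
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, dout):
        self.gw[...] = self._x.T @ dout
        self.gb[...] = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx


def _sigmoid(x):
    # numerically stable logistic (no overflow for large |x|)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so their global L2 norm is <= max_norm.

    Standard guard against exploding recurrent gradients; returns the
    pre-clipping norm.
    """
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


class LSTMLast(Layer):
    """Single-layer LSTM over (N, T, F); returns the final hidden state.

    Gate order in the packed weight matrices is (input, forget, cell, output);
    the forget-gate bias starts at 1.  Backpropagation-through-time injects
    the incoming gradient at the last step only, which is all a
    classify-at-the-end readout needs.
    """

    def __init__(self, fin: int, hidden: int, *, rng: np.random.Generator,
                 dtype=np.float32, init: str = "he"):
        sx = _init_std(init, fin) if init == "unit" else float(np.sqrt(1.0 / fin))
        sh = 1.0 if init == "unit" else float(np.sqrt(1.0 / hidden))
        self.hidden = hidden
        self.wx = rng.normal(0.0, sx, (fin, 4 * hidden)).astype(dtype)
        self.wh = rng.normal(0.0, sh, (hidden, 4 * hidden)).astype(dtype)
        self.b = np.zeros(4 * hidden, dtype=dtype)
        self.b[hidden:2 * hidden] = 1.0
        self.gwx = np.zeros_like(self.wx)
        self.gwh = np.zeros_like(self.wh)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.wx, self.wh, self.b]

    def grads(self):
        return [self.gwx, self.gwh, self.gb]

    def forward(self, x, train=False, rng=None):
        n, t, _ = x.shape
        hdim = self.hidden
        h = np.zeros((n, hdim), dtype=x.dtype)
        c = np.zeros((n, hdim), dtype=x.dtype)
        cache = []
        for step in range(t):
            xt = x[:, step, :]
            a = xt @ self.wx + h @ self.wh + self.b
            i = _sigmoid(a[:, :hdim])
            f = _sigmoid(a[:, hdim:2 * hdim])
            g = np.tanh(a[:, 2 * hdim:3 * hdim])
            o = _sigmoid(a[:, 3 * hdim:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if train:
                cache.append((xt, h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        self._cache = cache if train else None
        self._x_shape = x.shape
        return h

    def backward(self, dout):
        n, t, fin = self._x_shape
        hdim = self.hidden
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        self.gwx[...] = 0.0
        self.gwh[...] = 0.0
        self.gb[...] = 0.0
        dh = dout
        dc = np.zeros_like(dout)
        for step in range(t - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tanh_c = self._cache[step]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            self.gwx += xt.T @ da
            self.gwh += h_prev.T @ da
            self.gb += da.sum(axis=0)
            dx[:, step, :] = da @ self.wx.T
            dh = da @ self.wh.T
            dc = dc * f
        self._cache = None
        return dx


class Sequential:
    """Plain layer stack used for the 3D CNN."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class LRCNNet:
    """Per-frame convolutional feature extractor + LSTM + dense readout.

    Input is (N, T, H, W) single-channel video; frames are folded into the
    batch axis for the 2D feature extractor, unfolded to (N, T, features)
    for the LSTM, and the classification is read from the final LSTM step.
    """

    def __init__(self, features: Sequential, lstm: LSTMLast, head: Dense):
        self.features = features
        self.lstm = lstm
        self.head = head

    def params(self):
        return self.features.params() + self.lstm.params() + self.head.params()

    def grads(self):
        return self.features.grads() + self.lstm.grads() + self.head.grads()

    def forward(self, x, train=False, rng=None):
        n, t, h, w = x.shape
        feat = self.features.forward(x.reshape(n * t, 1, h, w), train=train, rng=rng)
        self._feat_dim = feat.shape[1]
        hlast = self.lstm.forward(feat.reshape(n, t, -1), train=train, rng=rng)
        return self.head.forward(hlast, train=train, rng=rng)

    def backward(self, dout):
        dh = self.head.backward(dout)
        dfeat = self.lstm.backward(dh)
        n, t, f = dfeat.shape
        dflat = self.features.backward(dfeat.reshape(n * t, f))
        return dflat.reshape(n, t, *dflat.shape[1:])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray,
                          sample_weights: np.ndarray | None = None):
    """Mean (optionally weighted) cross-entropy and its gradient wrt logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    w = np.ones(n) if sample_weights is None else np.asarray(sample_weights, dtype=float)
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float(-(w * logp).sum() / n)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / n)[:, None]
    return loss, dlogits.astype(logits.dtype)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        if not (0.0 <= momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g, v in zip(params, grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v
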