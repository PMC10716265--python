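"""Minimal neural-network layers with explicit backpropagation.

Supports exactly what the risk models need: 1-D convolution (im2col),
average pooling, dense layers, ReLU, a bidirectional multi-layer LSTM with
full backpropagation through time, binary cross-entropy on logits, and
Adam. Everything is plain numpy, seeded and single-threaded-deterministic;
gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = [
    "Param", "Dense", "ReLU", "Conv1d", "AvgPool1d", "GlobalAvgPool",
    "Sequential", "BiLSTM", "Adam", "bce_with_logits", "sigmoid",
    "params_checksum",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = value
        self.grad = np.zeros_like(value)


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits, y):
    """Mean binary cross-entropy; returns (loss, dlogits)."""
    z = logits.ravel()
    y = y.ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.shape[0]
    return loss, dz.reshape(logits.shape)


class Layer:
    def params(self):
        return []


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, dtype=np.float64):
        lim = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-lim, lim, (n_in, n_out)).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype))

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv1d(Layer):
    """1-D convolution over (B, C, L) via im2col; 'valid' padding."""

    def __init__(self, c_in, c_out, kernel, stride=1, rng=None,
                 dtype=np.float32):
        lim = np.sqrt(6.0 / (c_in * kernel + c_out))
        self.W = Param(rng.uniform(-lim, lim, (c_in * kernel, c_out))
                       .astype(dtype))
        self.b = Param(np.zeros(c_out, dtype))
        self.k, self.stride, self.c_in = kernel, stride, c_in

    def forward(self, x):
        B, C, L = x.shape
        wins = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
        wins = wins[:, :, ::self.stride]                      # (B, C, Lo, k)
        cols = wins.transpose(0, 2, 1, 3).reshape(B, -1, C * self.k)
        self._cols, self._in_shape = cols, x.shape
        y = cols @ self.W.value + self.b.value                # (B, Lo, c_out)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy):
        B, C, L = self._in_shape
        dyt = dy.transpose(0, 2, 1)                           # (B, Lo, c_out)
        Lo = dyt.shape[1]
        self.W.grad += np.einsum("blc,blf->cf", self._cols, dyt,
                                 optimize=True)
        self.b.grad += dyt.sum(axis=(0, 1))
        dcols = dyt @ self.W.value.T                          # (B, Lo, C*k)
        dcols = dcols.reshape(B, Lo, C, self.k).transpose(0, 2, 1, 3)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        for j in range(self.k):
            dx[:, :, j:j + Lo * self.stride:self.stride] += dcols[:, :, :, j]
        return dx

    def params(self):
        return [self.W, self.b]


class AvgPool1d(Layer):
    def __init__(self, k):
        self.k = k

    def forward(self, x):
        B, C, L = x.shape
        Lo = L // self.k
        self._trim = L
        return x[:, :, :Lo * self.k].reshape(B, C, Lo, self.k).mean(axis=3)

    def backward(self, dy):
        B, C, Lo = dy.shape
        dx = np.zeros((B, C, self._trim), dtype=dy.dtype)
        dx[:, :, :Lo * self.k] = np.repeat(dy / self.k, self.k, axis=2)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None] / self._L, self._L, axis=2)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

def _tanh(x):
    return np.tanh(x)


class _LSTMDir(Layer):
    """Single-direction LSTM over (B, T, D) -> (B, T, H)."""

    def __init__(self, n_in, n_hidden, rng, reverse=False, dtype=np.float64):
        H = n_hidden
        lim = np.sqrt(6.0 / (n_in + 4 * H))
        self.Wx = Param(rng.uniform(-lim, lim, (n_in, 4 * H)).astype(dtype))
        limh = np.sqrt(6.0 / (H + 4 * H))
        self.Wh = Param(rng.uniform(-limh, limh, (H, 4 * H)).astype(dtype))
        b = np.zeros(4 * H, dtype)
        b[H:2 * H] = 1.0  # forget-gate bias
        self.b = Param(b)
        self.H, self.reverse = H, reverse

    def forward(self, x):
        if self.reverse:
            x = x[:, ::-1]
        B, T, D = x.shape
        H = self.H
        h = np.zeros((B, H), x.dtype)
        c = np.zeros((B, H), x.dtype)
        self._cache = []
        hs = np.empty((B, T, H), x.dtype)
        for t in range(T):
            xt = x[:, t]
            z = xt @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = _tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = _tanh(c_new)
            h_new = o * tc
            self._cache.append((xt, h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        self._last_h = h
        out = hs[:, ::-1] if self.reverse else hs
        return out

    def backward(self, dout, dlast=None):
        """dout: gradient wrt the (un-reversed) output sequence; dlast:
        extra gradient wrt the direction's final hidden state."""
        if self.reverse:
            dout = dout[:, ::-1]
        B, T, H = dout.shape
        dh_next = np.zeros((B, H), dout.dtype)
        if dlast is not None:
            dh_next = dh_next + dlast
        dc_next = np.zeros((B, H), dout.dtype)
        dx = np.empty((B, T, self.Wx.value.shape[0]), dout.dtype)
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.Wx.grad += xt.T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
        if self.reverse:
            dx = dx[:, ::-1]
        return np.ascontiguousarray(dx)

    def params(self):
        return [self.Wx, self.Wh, self.b]


class BiLSTM(Layer):
    """Stacked bidirectional LSTM.

    ``forward`` returns the final-state summary: the concatenated last
    hidden states of the top layer's two directions, shape (B, 2H).
    """

    def __init__(self, n_in, n_hidden, n_layers, rng, dtype=np.float64):
        self.pairs = []
        d = n_in
        for _ in range(n_layers):
            fwd = _LSTMDir(d, n_hidden, rng, reverse=False, dtype=dtype)
            bwd = _LSTMDir(d, n_hidden, rng, reverse=True, dtype=dtype)
            self.pairs.append((fwd, bwd))
            d = 2 * n_hidden
        self.H = n_hidden

    def forward(self, x):
        for fwd, bwd in self.pairs:
            x = np.concatenate([fwd.forward(x), bwd.forward(x)], axis=2)
        self._T = x.shape[1]
        top_f, top_b = self.pairs[-1]
        return np.concatenate([top_f._last_h, top_b._last_h], axis=1)

    def backward(self, dsummary):
        B = dsummary.shape[0]
        H = self.H
        dseq = np.zeros((B, self._T, 2 * H))
        dlast_f, dlast_b = dsummary[:, :H], dsummary[:, H:]
        for li in range(len(self.pairs) - 1, -1, -1):
            fwd, bwd = self.pairs[li]
            if li == len(self.pairs) - 1:
                dxf = fwd.backward(dseq[:, :, :H], dlast=dlast_f)
                dxb = bwd.backward(dseq[:, :, H:], dlast=dlast_b)
            else:
                dxf = fwd.backward(dseq[:, :, :H])
                dxb = bwd.backward(dseq[:, :, H:])
            dseq = dxf + dxb
        return dseq

    def params(self):
        return [p for fwd, bwd in self.pairs for p in (*fwd.params(),
                                                       *bwd.params())]


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def params_checksum(layer: Layer) -> str:
    """SHA-256 over all parameter bytes; detects any weight mutation."""
    h = hashlib.sha256()
    for p in layer.params():
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()
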