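"""Minimal seeded CNN framework on numpy: layers, manual backprop, Adam.

Everything downstream (the slice classifier and the tile U-Net) is built
from these pieces.  Arrays are NHWC float32; convolutions go through
im2col/col2im so the heavy lifting is BLAS matmuls.  Initialization is
Glorot-uniform, drawn from per-layer generators spawned off one seed, so a
rebuild with the same seed is bit-identical and single-threaded runs are
reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "MaxPool2D", "Flatten", "Dense", "ConvTranspose2D",
           "Sequential", "Adam", "sigmoid"]

_F = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F)


class Layer:
    """Base: trainable params live in .params/.grads (parallel lists)."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def num_params(self) -> int:
        return int(sum(p.size for p in self.params))


class _ReluMixin:
    def _act_forward(self, z, train):
        if self.activation == "relu":
            z = np.maximum(z, 0.0)
            if train:
                self._act_mask = z > 0
        return z

    def _act_backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._act_mask
        return dout


class Conv2D(Layer, _ReluMixin):
    """k×k convolution, stride 1, 'valid' or 'same' zero padding."""

    def __init__(self, cin, cout, k=3, padding="valid", activation="relu", rng=None):
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.cin, self.cout, self.k, self.padding = cin, cout, k, padding
        self.activation = activation
        fan_in, fan_out = k * k * cin, k * k * cout
        self.W = _glorot(rng, (k * k * cin, cout), fan_in, fan_out)
        self.b = np.zeros(cout, dtype=_F)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    # feature maps at or below this pixel count go through im2col (one big
    # matmul); larger maps use tap-wise shift-accumulate, which avoids
    # materializing the k²-fold patch matrix
    _IM2COL_MAX_PIXELS = 72 * 72

    def _w3(self):
        # (k*k*cin, cout) -> per-tap (k, k, cin, cout) view
        return self.W.reshape(self.k, self.k, self.cin, self.cout)

    def _pad(self, x):
        if self.padding == "same":
            p = self.k // 2
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        return x

    def _unpad_grad(self, dx):
        if self.padding == "same":
            p = self.k // 2
            dx = dx[:, p:-p or None, p:-p or None, :]
        return dx

    def _im2col(self, x, ho, wo):
        k = self.k
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # (N,Ho,Wo,C,k,k) -> (N·Ho·Wo, k·k·C)
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)
                                    ).reshape(-1, k * k * self.cin)

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=_F)
        x = self._pad(x)
        n, h, w, _ = x.shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        self._use_cols = h * w <= self._IM2COL_MAX_PIXELS
        if self._use_cols:
            cols = self._im2col(x, ho, wo)
            z = cols @ self.W + self.b
            if train:
                self._cols, self._xshape = cols, x.shape
        else:
            w3 = self._w3()
            z = np.zeros((n * ho * wo, self.cout), dtype=_F)
            tmp = np.empty_like(z)
            for di in range(k):
                for dj in range(k):
                    xv = np.ascontiguousarray(
                        x[:, di:di + ho, dj:dj + wo, :]).reshape(-1, self.cin)
                    np.matmul(xv, w3[di, dj], out=tmp)
                    z += tmp
            z += self.b
            if train:
                self._x = x
        z = z.reshape(n, ho, wo, self.cout)
        return self._act_forward(z, train)

    def backward(self, dout):
        dout = self._act_backward(dout)
        n, ho, wo, _ = dout.shape
        k = self.k
        dflat = np.ascontiguousarray(dout).reshape(-1, self.cout)
        self.grads[1][...] = dflat.sum(axis=0)
        if self._use_cols:
            self.grads[0][...] = self._cols.T @ dflat
            w3 = self._w3()
            dx = np.zeros(self._xshape, dtype=_F)
            for di in range(k):
                for dj in range(k):
                    dx[:, di:di + ho, dj:dj + wo, :] += (
                        dflat @ w3[di, dj].T).reshape(n, ho, wo, self.cin)
            self._cols = None
        else:
            x = self._x
            w3 = self._w3()
            dw3 = self.grads[0].reshape(k, k, self.cin, self.cout)
            dx = np.zeros(x.shape, dtype=_F)
            for di in range(k):
                for dj in range(k):
                    xv = np.ascontiguousarray(
                        x[:, di:di + ho, dj:dj + wo, :]).reshape(-1, self.cin)
                    dw3[di, dj] = xv.T @ dflat
                    dx[:, di:di + ho, dj:dj + wo, :] += (
                        dflat @ w3[di, dj].T).reshape(n, ho, wo, self.cin)
            self._x = None
        return self._unpad_grad(dx)


class MaxPool2D(Layer):
    """2×2 max pooling, stride 2; trailing odd row/col cropped (floor)."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :h2 * 2, :w2 * 2, :]
        win = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(n, h2, w2, 4, c)
        if train:
            self._arg = win.argmax(axis=3)
            self._xshape = x.shape
        return win.max(axis=3)

    def backward(self, dout):
        n, h2, w2, c = dout.shape
        dwin = np.zeros((n, h2, w2, 4, c), dtype=_F)
        np.put_along_axis(dwin, self._arg[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros(self._xshape, dtype=_F)
        dxc = dwin.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dx[:, :h2 * 2, :w2 * 2, :] = dxc.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        if train:
            self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer, _ReluMixin):
    def __init__(self, cin, cout, activation="relu", rng=None):
        super().__init__()
        self.activation = activation
        self.W = _glorot(rng, (cin, cout), cin, cout)
        self.b = np.zeros(cout, dtype=_F)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return self._act_forward(x @ self.W + self.b, train)

    def backward(self, dout):
        dout = self._act_backward(dout)
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T


class ConvTranspose2D(Layer):
    """2×2 transposed convolution with stride 2 (exact 2× upsampling)."""

    def __init__(self, cin, cout, rng=None, activation=None):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.activation = activation
        fan_in, fan_out = 4 * cin, 4 * cout
        self.W = _glorot(rng, (2, 2, cin, cout), fan_in, fan_out)
        self.b = np.zeros(cout, dtype=_F)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        if train:
            self._x = x
        n, h, w, _ = x.shape
        y6 = np.tensordot(x, self.W, axes=([3], [2]))      # (N,H,W,2,2,Cout)
        y = y6.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.cout)
        y = y + self.b
        if self.activation == "relu":
            y = np.maximum(y, 0.0)
            if train:
                self._act_mask = y > 0
        return y

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._act_mask
        n, h2, w2, _ = dout.shape
        h, w = h2 // 2, w2 // 2
        d6 = dout.reshape(n, h, 2, w, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        dW = np.tensordot(self._x, d6, axes=([0, 1, 2], [0, 1, 2]))  # (Cin,2,2,Cout)
        self.grads[0][...] = dW.transpose(1, 2, 0, 3)
        dx = np.tensordot(d6, self.W, axes=([3, 4, 5], [0, 1, 3]))
        self._x = None
        return dx


class Sequential:
    """A plain layer chain with shared parameter bookkeeping."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def num_params(self) -> int:
        return int(sum(l.num_params() for l in self.layers))


class Adam:
    """Adam with Keras defaults (β1=0.9, β2=0.999, ε=1e-7)."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2 ** self.t) / (1.0 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def save_params(path, params: list[np.ndarray]) -> None:
    np.savez(path, **{f"p{i}": p for i, p in enumerate(params)})


def load_params(path, params: list[np.ndarray]) -> None:
    with np.load(path) as npz:
        if len(npz.files) != len(params):
            raise ValueError("checkpoint does not match this architecture")
        for i, p in enumerate(params):
            arr = npz[f"p{i}"]
            if arr.shape != p.shape:
                raise ValueError("checkpoint does not match this architecture")
            p[...] = arr
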