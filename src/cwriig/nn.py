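"""Minimal NHWC convolutional network stack with manual backprop and Adam.

Sized for the six-channel 224 x 224 stacks and the small architecture used
here: convolutions are evaluated as one GEMM per kernel offset (BLAS does
the heavy lifting), float32 throughout.  Deterministic given the
construction seed and the training RNG.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2x2", "AvgPool2x2", "Flatten", "GlobalAvgPool",
           "Dense", "Sequential", "Adam"]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def out_shape(self, shape: tuple) -> tuple:  # (H, W, C)
        return shape


class Conv2d(Layer):
    """2-D convolution, NHWC, zero padding chosen at construction.

    Shallow inputs (small c_in * k^2) go through an explicit im2col GEMM --
    per-offset GEMMs with a tiny contraction axis are memory-bound --
    while deeper layers use one GEMM per kernel offset, which avoids the
    large im2col buffer.  ``need_input_grad=False`` (first layer) skips the
    input-gradient accumulation entirely.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, pad: int,
                 rng: np.random.Generator, need_input_grad: bool = True) -> None:
        super().__init__()
        self.k, self.s, self.p = kernel, stride, pad
        self.need_input_grad = need_input_grad
        self.use_im2col = c_in * kernel * kernel <= 384
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))  # He initialization
        w = rng.normal(0.0, scale, size=(kernel, kernel, c_in, c_out)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def out_shape(self, shape):
        h, w, _ = shape
        ho = (h + 2 * self.p - self.k) // self.s + 1
        wo = (w + 2 * self.p - self.k) // self.s + 1
        return (ho, wo, self.params[0].shape[3])

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        k, s = self.k, self.s
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # (B, ho, wo, C, k, k) -> (B*ho*wo, C*k*k)
        return np.ascontiguousarray(win[:, ::s, ::s]).reshape(-1, xp.shape[3] * k * k)

    def forward(self, x, train=False):
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        b_, hp, wp, c = xp.shape
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        w, bias = self.params
        if self.use_im2col:
            col = self._im2col(xp, ho, wo)
            wmat = np.ascontiguousarray(w.transpose(2, 0, 1, 3)).reshape(c * k * k, -1)
            out = (col.dot(wmat) + bias).reshape(b_, ho, wo, -1)
            if train:
                self._col, self._xp = col, (xp if self.need_input_grad else None)
        else:
            out = np.tile(bias.astype(np.float32), (b_, ho, wo, 1))
            for i in range(k):
                for j in range(k):
                    xs = xp[:, i:i + ho * s:s, j:j + wo * s:s, :]
                    out += xs.reshape(-1, c).dot(w[i, j]).reshape(b_, ho, wo, -1)
            if train:
                self._col, self._xp = None, xp
        if train:
            self._dims = (b_, hp, wp, c, ho, wo)
        return out

    def backward(self, dout):
        k, s, p = self.k, self.s, self.p
        b_, hp, wp, c, ho, wo = self._dims
        _, _, _, co = dout.shape
        w, _ = self.params
        dw, db = self.grads
        dflat = dout.reshape(-1, co)
        db[...] = dflat.sum(axis=0)
        if self.use_im2col:
            g = self._col.T.dot(dflat).reshape(c, k, k, co).transpose(1, 2, 0, 3)
            dw[...] = g
            self._col = None
            if not self.need_input_grad:
                self._xp = None
                return None
        xp = self._xp
        dxp = np.zeros((b_, hp, wp, c), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                if not self.use_im2col:
                    xs = xp[:, i:i + ho * s:s, j:j + wo * s:s, :]
                    dw[i, j] = xs.reshape(-1, c).T.dot(dflat)
                if self.need_input_grad:
                    dxp[:, i:i + ho * s:s, j:j + wo * s:s, :] += dflat.dot(w[i, j].T).reshape(b_, ho, wo, c)
        self._xp = None
        if not self.need_input_grad:
            return None
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2(Layer):
    """2 x 2 max pooling, stride 1, extent-preserving (pad right/bottom)."""

    def forward(self, x, train=False):
        xp = np.pad(x, ((0, 0), (0, 1), (0, 1), (0, 0)), constant_values=-np.inf)
        b, h, w, c = x.shape
        out = xp[:, :h, :w, :].copy()
        for di, dj in ((0, 1), (1, 0), (1, 1)):
            np.maximum(out, xp[:, di:di + h, dj:dj + w, :], out=out)
        if train:  # masks are recomputed in backward to keep memory flat
            self._xp, self._out, self._x_shape = xp, out, x.shape
        return out

    def backward(self, dout):
        b, h, w, c = self._x_shape
        xp, out = self._xp, self._out
        dxp = np.zeros((b, h + 1, w + 1, c), dtype=dout.dtype)
        claimed = np.zeros(dout.shape, dtype=bool)
        for di, dj in ((0, 0), (0, 1), (1, 0), (1, 1)):
            eq = xp[:, di:di + h, dj:dj + w, :] == out
            take = eq & ~claimed  # ties route to the first maximal entry
            claimed |= eq
            dxp[:, di:di + h, dj:dj + w, :] += np.where(take, dout, 0.0)
        self._xp = self._out = None
        return dxp[:, :h, :w, :]


class AvgPool2x2(Layer):
    """2 x 2 average pooling, stride 1, extent-preserving (edge-replicated)."""

    def forward(self, x, train=False):
        xp = np.pad(x, ((0, 0), (0, 1), (0, 1), (0, 0)), mode="edge")
        b, h, w, c = x.shape
        out = sum(xp[:, di:di + h, dj:dj + w, :] for di in (0, 1) for dj in (0, 1)) / 4.0
        if train:
            self._x_shape = x.shape
        return out.astype(x.dtype)

    def backward(self, dout):
        b, h, w, c = self._x_shape
        dxp = np.zeros((b, h + 1, w + 1, c), dtype=dout.dtype)
        for di in (0, 1):
            for dj in (0, 1):
                dxp[:, di:di + h, dj:dj + w, :] += dout
        dxp /= 4.0
        dxp[:, h - 1, :, :] += dxp[:, h, :, :]  # fold the replicated pad back
        dxp[:, :, w - 1, :] += dxp[:, :, w, :]
        return dxp[:, :h, :w, :]


class Flatten(Layer):
    def out_shape(self, shape):
        return (int(np.prod(shape)),)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Strict spatial global average: (H, W, C) -> (C,)."""

    def out_shape(self, shape):
        return (shape[2],)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        b, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).astype(dout.dtype)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        w = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        b = np.zeros(n_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def out_shape(self, shape):
        return (self.params[0].shape[1],)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x.dot(self.params[0]) + self.params[1]

    def backward(self, dout):
        w, _ = self.params
        self.grads[0][...] = self._x.T.dot(dout)
        self.grads[1][...] = dout.sum(axis=0)
        self._x = None
        return dout.dot(w.T)


class Sequential:
    def __init__(self, layers: list[Layer], input_shape: tuple) -> None:
        self.layers = layers
        self.input_shape = input_shape

    def forward(self, x: np.ndarray, train: bool = False,
                return_hidden: int | None = None) -> np.ndarray:
        """Run the stack; ``return_hidden=i`` stops after layer i (0-based)."""
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if return_hidden is not None and i == return_hidden:
                return x
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def shape_audit(self) -> list[tuple]:
        shapes = []
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.out_shape(shape)
            shapes.append(shape)
        return shapes


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
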