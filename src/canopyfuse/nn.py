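"""Minimal CPU neural-network layers with explicit backpropagation.

Just the pieces the canopy-height network needs: 3x3 convolution,
depthwise-separable 3x3 convolution, 1x1 convolution heads, ReLU and an
Adam optimizer. Arrays are (N, C, H, W); zero padding keeps spatial
dimensions, so output size always equals input size (no downsampling).

Written against NumPy directly because the method's training loop is the
package's own contribution and the dependency surface must stay small;
the implementation is validated by finite-difference gradient checks in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3x3", "SeparableConv3x3", "Conv1x1", "ReLU", "Adam"]


def _he_init(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Layer:
    """Base: parameters and gradients are parallel dicts of arrays."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3x3(Layer):
    """Standard 3x3 convolution, zero padding 1, stride 1."""

    def __init__(self, in_ch, out_ch, rng, dtype=np.float32):
        super().__init__()
        fan_in = in_ch * 9
        self.params["w"] = _he_init(rng, (out_ch, in_ch, 3, 3), fan_in, dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.zero_grad()

    def forward(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # (N, C, H, W, 3, 3) view -> (N*H*W, C*9)
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        wmat = self.params["w"].reshape(self.out_ch, c * 9)
        y = cols @ wmat.T + self.params["b"]
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, (n, c, h, w) = self._cache
        dy2 = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        wmat = self.params["w"].reshape(self.out_ch, c * 9)
        self.grads["w"] += (dy2.T @ cols).reshape(self.params["w"].shape)
        self.grads["b"] += dy2.sum(axis=0)
        dcols = (dy2 @ wmat).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=dy.dtype)
        for ki in range(3):
            for kj in range(3):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]


class Conv1x1(Layer):
    """Pointwise convolution (a per-pixel linear map over channels)."""

    def __init__(self, in_ch, out_ch, rng, dtype=np.float32, bias_init=0.0):
        super().__init__()
        self.params["w"] = _he_init(rng, (out_ch, in_ch), in_ch, dtype)
        self.params["b"] = np.full(out_ch, bias_init, dtype=dtype)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.zero_grad()

    def forward(self, x):
        self._x = x
        y = np.einsum("nchw,fc->nfhw", x, self.params["w"], optimize=True)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy):
        self.grads["w"] += np.einsum("nfhw,nchw->fc", dy, self._x, optimize=True)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        return np.einsum("nfhw,fc->nchw", dy, self.params["w"], optimize=True)


class _Depthwise3x3(Layer):
    """Per-channel 3x3 convolution, zero padding 1."""

    def __init__(self, ch, rng, dtype=np.float32):
        super().__init__()
        self.params["w"] = _he_init(rng, (ch, 3, 3), 9, dtype)
        self.ch = ch
        self.zero_grad()

    def forward(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._cache = (xp, x.shape)
        y = np.zeros_like(x)
        wgt = self.params["w"]
        for ki in range(3):
            for kj in range(3):
                y += wgt[:, ki, kj][None, :, None, None] * xp[:, :, ki:ki + h, kj:kj + w]
        return y

    def backward(self, dy):
        xp, (n, c, h, w) = self._cache
        wgt = self.params["w"]
        dxp = np.zeros_like(xp)
        for ki in range(3):
            for kj in range(3):
                self.grads["w"][:, ki, kj] += np.einsum(
                    "nchw,nchw->c", dy, xp[:, :, ki:ki + h, kj:kj + w], optimize=True)
                dxp[:, :, ki:ki + h, kj:kj + w] += wgt[:, ki, kj][None, :, None, None] * dy
        return dxp[:, :, 1:-1, 1:-1]


class SeparableConv3x3(Layer):
    """Depthwise 3x3 followed by pointwise 1x1 (bias on the pointwise)."""

    def __init__(self, in_ch, out_ch, rng, dtype=np.float32):
        super().__init__()
        self.depthwise = _Depthwise3x3(in_ch, rng, dtype)
        self.pointwise = Conv1x1(in_ch, out_ch, rng, dtype)

    @property
    def params(self):
        return {**{f"dw_{k}": v for k, v in self.depthwise.params.items()},
                **{f"pw_{k}": v for k, v in self.pointwise.params.items()}}

    @params.setter
    def params(self, value):  # set by Layer.__init__; children own storage
        pass

    @property
    def grads(self):
        return {**{f"dw_{k}": v for k, v in self.depthwise.grads.items()},
                **{f"pw_{k}": v for k, v in self.pointwise.grads.items()}}

    @grads.setter
    def grads(self, value):
        pass

    def zero_grad(self):
        self.depthwise.zero_grad()
        self.pointwise.zero_grad()

    def forward(self, x):
        return self.pointwise.forward(self.depthwise.forward(x))

    def backward(self, dy):
        return self.depthwise.backward(self.pointwise.backward(dy))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def zero_grad(self):
        pass


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr=1e-4, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
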