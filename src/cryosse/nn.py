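"""Minimal numpy building blocks for 3D convolutional networks.

Layers store their forward cache and implement an explicit backward
pass; parameters and gradients live in per-layer dicts so an optimizer
can iterate them generically.  Convolutions are evaluated as 27 shifted
channel-matrix multiplications (BLAS sgemm), which is the fastest pure
numpy formulation for 3^3 kernels at the volume sizes used here.

Tensors are channels-first ``(C, D, H, W)`` float32, batch size 1 (the
network consumes variable-size volumes).
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np


class Layer:
    """Base class: parameter/gradient registry plus forward/backward."""

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def _conv3_shift(x: np.ndarray, w: np.ndarray, out_channels: int) -> np.ndarray:
    """Same-padded 3^3 correlation: w has shape (Cout, Cin, 3, 3, 3)."""
    cin, d, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    y = np.zeros((out_channels, d * h * wd), dtype=np.float32)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                xs = np.ascontiguousarray(xp[:, i:i + d, j:j + h, k:k + wd]).reshape(cin, -1)
                y += w[:, :, i, j, k] @ xs
    return y.reshape(out_channels, d, h, wd)


class Conv3d(Layer):
    """3^3 (or 1^3) same-padded convolution, stride 1, He-initialised."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.cin, self.cout, self.kernel = cin, cout, kernel
        fan_in = cin * kernel ** 3
        std = np.sqrt(2.0 / fan_in)
        self.params["w"] = rng.normal(0.0, std, (cout, cin) + (kernel,) * 3).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w, b = self.params["w"], self.params["b"]
        if self.kernel == 1:
            y = (w.reshape(self.cout, self.cin) @ x.reshape(self.cin, -1)).reshape(
                (self.cout,) + x.shape[1:]
            )
        else:
            y = _conv3_shift(x, w, self.cout)
        return y + b[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, w = self._x, self.params["w"]
        self.grads["b"] += dy.sum(axis=(1, 2, 3))
        if self.kernel == 1:
            self.grads["w"] += (
                dy.reshape(self.cout, -1) @ x.reshape(self.cin, -1).T
            ).reshape(w.shape)
            return (
                w.reshape(self.cout, self.cin).T @ dy.reshape(self.cout, -1)
            ).reshape(x.shape)
        cin, d, h, wd = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        dyf = np.ascontiguousarray(dy).reshape(self.cout, -1)
        gw = self.grads["w"]
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = np.ascontiguousarray(xp[:, i:i + d, j:j + h, k:k + wd]).reshape(cin, -1)
                    gw[:, :, i, j, k] += dyf @ xs.T
        # input gradient: correlation of dy with the spatially flipped,
        # channel-transposed kernel (same padding)
        w_t = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        return _conv3_shift(dy, w_t, self.cin)


class InstanceNorm(Layer):
    """Per-channel normalisation over the spatial dims (batch size 1)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv
        g = self.params["gamma"][:, None, None, None]
        b = self.params["beta"][:, None, None, None]
        return (g * self._xhat + b).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        n = xhat[0].size
        self.grads["gamma"] += (dy * xhat).sum(axis=(1, 2, 3))
        self.grads["beta"] += dy.sum(axis=(1, 2, 3))
        g = self.params["gamma"][:, None, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(1, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
        ) * inv
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2^3 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dims")
        xr = (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8)
        )
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._in_shape
        dxr = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        return (
            dxr.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )


class TransposedConv2(Layer):
    """2^3 transposed convolution, stride 2 (doubles each spatial dim)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.params["w"] = rng.normal(0.0, std, (cin, cout, 2, 2, 2)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w = self.params["w"]
        c, d, h, wd = x.shape
        y = np.einsum("cdhw,coijk->odihjwk", x, w, optimize=True)
        y = y.reshape(self.cout, 2 * d, 2 * h, 2 * wd)
        return (y + self.params["b"][:, None, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, w = self._x, self.params["w"]
        c, d, h, wd = x.shape
        dyr = dy.reshape(self.cout, d, 2, h, 2, wd, 2)
        self.grads["b"] += dy.sum(axis=(1, 2, 3))
        self.grads["w"] += np.einsum("cdhw,odihjwk->coijk", x, dyr, optimize=True).astype(
            np.float32
        )
        return np.einsum("odihjwk,coijk->cdhw", dyr, w, optimize=True).astype(np.float32)


class Sequential(Layer):
    def __init__(self, layers: List[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def all_layers(self) -> List[Layer]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.all_layers())
            else:
                out.append(layer)
        return out


def conv_block(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    """conv3-norm-ReLU twice: the composite layer used at every U-Net level."""
    return Sequential([
        Conv3d(cin, cout, rng), InstanceNorm(cout), ReLU(),
        Conv3d(cout, cout, rng), InstanceNorm(cout), ReLU(),
    ])


class Adam:
    """Adam optimizer over a list of layers."""

    def __init__(self, layers: List[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** self.t)
                vhat = v[k] / (1 - b2 ** self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
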