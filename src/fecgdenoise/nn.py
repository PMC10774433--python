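"""Minimal 1-D neural-network layers with explicit backward passes.

Everything the denoiser needs — dilated/strided convolutions, transposed
convolutions, instance normalization, linear layers, pointwise activations
and a decoupled-weight-decay Adam optimizer — implemented on numpy arrays
of shape ``(batch, channels, time)`` (or ``(batch, features)`` for linear
layers).

Layers are *functional*: ``forward`` returns ``(output, cache)`` and
``backward`` consumes that cache, so one layer instance can take part in
several concurrent forward passes (the encoder runs on both the clean and
the noisy signal within a single training step). Parameter gradients are
accumulated into ``layer.grads`` unless backward is called with
``accumulate=False``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "ConvTranspose1d",
    "InstanceNorm1d",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Linear",
    "AdamW",
    "conv1d_output_length",
    "conv_transpose1d_output_length",
]


def conv1d_output_length(length: int, kernel: int, stride: int, dilation: int,
                         pad_left: int, pad_right: int) -> int:
    """Output length of a 1-D convolution with possibly asymmetric padding."""
    span = dilation * (kernel - 1) + 1
    return (length + pad_left + pad_right - span) // stride + 1


def conv_transpose1d_output_length(length: int, kernel: int, stride: int,
                                   dilation: int, padding: int,
                                   output_padding: int) -> int:
    return (length - 1) * stride - 2 * padding + dilation * (kernel - 1) + output_padding + 1


class Layer:
    """Base class: parameterless layers get empty param/grad dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy, cache, accumulate: bool = True):  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv1d(Layer):
    """1-D convolution (cross-correlation) with stride, dilation and
    asymmetric zero padding. Weight shape ``(out_ch, in_ch, kernel)``."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 8, stride: int = 1,
                 dilation: int = 1, padding=(0, 0), *, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.dilation = stride, dilation
        self.pad_left, self.pad_right = (padding, padding) if np.isscalar(padding) else padding
        fan_in = in_ch * kernel
        self.params = {
            "W": _fan_in_uniform(rng, (out_ch, in_ch, kernel), fan_in, dtype),
            "b": _fan_in_uniform(rng, (out_ch,), fan_in, dtype),
        }
        self.zero_grad()

    def output_length(self, length: int) -> int:
        return conv1d_output_length(length, self.kernel, self.stride,
                                    self.dilation, self.pad_left, self.pad_right)

    def forward(self, x: np.ndarray):
        W, b = self.params["W"], self.params["b"]
        n, _, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        L_out = self.output_length(L)
        s, d = self.stride, self.dilation
        y = np.broadcast_to(b[:, None], (self.out_ch, L_out)).copy()
        y = np.repeat(y[None], n, axis=0)
        hi = (L_out - 1) * s + 1
        for j in range(self.kernel):
            xs = xp[:, :, j * d: j * d + hi: s]
            y += np.matmul(W[:, :, j], xs)
        return y, (xp, L)

    def backward(self, gy: np.ndarray, cache, accumulate: bool = True):
        xp, L = cache
        W = self.params["W"]
        s, d = self.stride, self.dilation
        L_out = gy.shape[-1]
        hi = (L_out - 1) * s + 1
        gxp = np.zeros_like(xp)
        for j in range(self.kernel):
            xs = xp[:, :, j * d: j * d + hi: s]
            if accumulate:
                self.grads["W"][:, :, j] += np.einsum("nol,ncl->oc", gy, xs)
            gxp[:, :, j * d: j * d + hi: s] += np.matmul(W[:, :, j].T, gy)
        if accumulate:
            self.grads["b"] += gy.sum(axis=(0, 2))
        end = gxp.shape[-1] - self.pad_right
        return gxp[:, :, self.pad_left: end]


class ConvTranspose1d(Layer):
    """1-D transposed convolution, the adjoint of a strided/dilated
    convolution. Weight shape ``(in_ch, out_ch, kernel)``."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 8, stride: int = 1,
                 dilation: int = 1, padding: int = 0, output_padding: int = 0, *,
                 rng: np.random.Generator, dtype=np.float64) -> None:
        super().__init__()
        if output_padding > padding and output_padding >= stride:
            raise ValueError("output_padding must be smaller than stride")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.dilation = stride, dilation
        self.padding, self.output_padding = padding, output_padding
        fan_in = in_ch * kernel
        self.params = {
            "W": _fan_in_uniform(rng, (in_ch, out_ch, kernel), fan_in, dtype),
            "b": _fan_in_uniform(rng, (out_ch,), fan_in, dtype),
        }
        self.zero_grad()

    def output_length(self, length: int) -> int:
        return conv_transpose1d_output_length(length, self.kernel, self.stride,
                                              self.dilation, self.padding,
                                              self.output_padding)

    def _virtual_length(self, L: int) -> int:
        # full (unpadded-adjoint) output extent before cropping by `padding`
        return (L - 1) * self.stride + self.dilation * (self.kernel - 1) + 1

    def forward(self, x: np.ndarray):
        W, b = self.params["W"], self.params["b"]
        n, _, L = x.shape
        s, d, p = self.stride, self.dilation, self.padding
        Lv = self._virtual_length(L)
        L_out = self.output_length(L)
        yfull = np.zeros((n, self.out_ch, Lv), dtype=x.dtype)
        hi = (L - 1) * s + 1
        for j in range(self.kernel):
            yfull[:, :, j * d: j * d + hi: s] += np.matmul(W[:, :, j].T, x)
        y = yfull[:, :, p: p + L_out].copy()
        y += b[:, None]
        return y, (x, L, Lv)

    def backward(self, gy: np.ndarray, cache, accumulate: bool = True):
        x, L, Lv = cache
        W = self.params["W"]
        s, d, p = self.stride, self.dilation, self.padding
        gyfull = np.zeros((gy.shape[0], self.out_ch, Lv), dtype=gy.dtype)
        gyfull[:, :, p: p + gy.shape[-1]] = gy
        hi = (L - 1) * s + 1
        gx = np.zeros_like(x)
        for j in range(self.kernel):
            gys = gyfull[:, :, j * d: j * d + hi: s]
            gx += np.matmul(W[:, :, j], gys)
            if accumulate:
                self.grads["W"][:, :, j] += np.einsum("ncl,nol->co", x, gys)
        if accumulate:
            self.grads["b"] += gy.sum(axis=(0, 2))
        return gx


class InstanceNorm1d(Layer):
    """Per-sample per-channel normalization over time with learnable
    affine scale/shift; epsilon keeps zero-variance inputs finite."""

    def __init__(self, channels: int, eps: float = 1e-5, *, dtype=np.float64) -> None:
        super().__init__()
        self.channels, self.eps = channels, eps
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        y = self.params["gamma"][:, None] * xhat + self.params["beta"][:, None]
        return y, (xhat, inv_std)

    def backward(self, gy: np.ndarray, cache, accumulate: bool = True):
        xhat, inv_std = cache
        if accumulate:
            self.grads["gamma"] += (gy * xhat).sum(axis=(0, 2))
            self.grads["beta"] += gy.sum(axis=(0, 2))
        gxhat = gy * self.params["gamma"][:, None]
        m1 = gxhat.mean(axis=-1, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=-1, keepdims=True)
        return inv_std * (gxhat - m1 - xhat * m2)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x):
        y = np.where(x >= 0, x, self.slope * x)
        return y, x >= 0

    def backward(self, gy, cache, accumulate: bool = True):
        return np.where(cache, gy, self.slope * gy)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, gy, cache, accumulate: bool = True):
        return gy * cache


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return y, y

    def backward(self, gy, cache, accumulate: bool = True):
        return gy * cache * (1.0 - cache)


class Linear(Layer):
    """Affine map on ``(batch, in_features)``; weight ``(out, in)``."""

    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, dtype=np.float64) -> None:
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.params = {
            "W": _fan_in_uniform(rng, (out_features, in_features), in_features, dtype),
            "b": _fan_in_uniform(rng, (out_features,), in_features, dtype),
        }
        self.zero_grad()

    def forward(self, x):
        return x @ self.params["W"].T + self.params["b"], x

    def backward(self, gy, cache, accumulate: bool = True):
        if accumulate:
            self.grads["W"] += gy.T @ cache
            self.grads["b"] += gy.sum(axis=0)
        return gy @ self.params["W"]


class AdamW:
    """Adam with decoupled weight decay (the weight-decay step is applied
    directly to the parameter, not through the gradient moments)."""

    def __init__(self, layers, lr: float = 1e-5, weight_decay: float = 5e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.weight_decay = lr, weight_decay
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in self.layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                update = (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
                p -= self.lr * update + self.lr * self.weight_decay * p
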