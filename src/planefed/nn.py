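"""Minimal NumPy neural-network core: layers with manual backprop.

Provides the strided convolution / ReLU / global-average-pool / linear
layers that make up the small convolutional encoder, plus SGD with
momentum.  Parameters live in ordered ``{name: array}`` dictionaries, which
is also the unit exchanged by the federated-averaging stage.  Everything is
float64 and fully deterministic under a seeded ``numpy.random.Generator``,
which is what makes bit-for-bit reproducibility of federated runs possible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

ModelParameters = dict  # ordered {name: np.ndarray}


class Layer:
    """Forward caches whatever backward needs; params are name -> array."""

    params: dict

    def __init__(self):
        self.params = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray):
        """Return (grad_input, {name: grad_param})."""
        raise NotImplementedError  # pragma: no cover


class Conv2d(Layer):
    """3x3 (by default) strided convolution via im2col, no padding."""

    def __init__(self, in_ch, out_ch, ksize=3, stride=1, rng=None):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride = ksize, stride
        rng = rng or np.random.default_rng()
        fan_in = in_ch * ksize * ksize
        self.params = {
            "weight": rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in),
            "bias": np.zeros(out_ch),
        }

    def forward(self, x):
        b, c, h, w = x.shape
        k, s = self.k, self.stride
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (B, C, Ho, Wo, k, k) -> (B, Ho, Wo, C, k, k) -> (B*Ho*Wo, C*k*k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
        out = cols @ self.params["weight"].T + self.params["bias"]
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(b, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        x_shape, cols, ho, wo = self._cache
        b, c, h, w = x_shape
        k, s = self.k, self.stride
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        grads = {"weight": g.T @ cols, "bias": g.sum(axis=0)}
        dcols = (g @ self.params["weight"]).reshape(b, ho, wo, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (B, C, Ho, Wo, k, k)
        dx = np.zeros(x_shape)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[..., i, j]
        return dx, grads


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask, {}


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).copy(), {}


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params = {
            "weight": rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in),
            "bias": np.zeros(n_out),
        }

    def forward(self, x):
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, grad):
        grads = {"weight": grad.T @ self._x, "bias": grad.sum(axis=0)}
        return grad @ self.params["weight"], grads


class Sequential:
    """Named layer chain with flat ``prefix.param`` parameter access."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers

    def forward(self, x):
        for _, layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        """Backprop through the whole chain; returns flat param grads."""
        grads: dict = {}
        for name, layer in reversed(self.layers):
            grad, g = layer.backward(grad)
            for pname, arr in g.items():
                grads[f"{name}.{pname}"] = arr
        return grad, grads

    def get_params(self) -> ModelParameters:
        return {
            f"{name}.{p}": layer.params[p].copy()
            for name, layer in self.layers
            for p in layer.params
        }

    def set_params(self, params: ModelParameters) -> None:
        for name, layer in self.layers:
            for p in layer.params:
                layer.params[p] = params[f"{name}.{p}"].copy()


class SGD:
    """Plain SGD with momentum; the learning rate is set per step by the
    scheduler that drives it.

    Gradients are clipped to a global L2 norm of ``max_grad_norm`` before
    the update (disabled with None).  Without clipping, the first steps of
    supervised training on top of a contrastively pretrained backbone can
    be large enough to push every ReLU into the dead regime, after which
    the network cannot recover.
    """

    def __init__(self, net: Sequential, momentum: float = 0.9, max_grad_norm: float | None = 1.0):
        self.net = net
        self.momentum = momentum
        self.max_grad_norm = max_grad_norm
        self.velocity: dict = {}

    def step(self, grads: dict, lr: float) -> None:
        if self.max_grad_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        for name, layer in self.net.layers:
            for p in layer.params:
                key = f"{name}.{p}"
                v = self.velocity.get(key, 0.0)
                v = self.momentum * v - lr * grads[key]
                self.velocity[key] = v
                layer.params[p] = layer.params[p] + v


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy against (soft) target distributions.

    ``targets`` is (B, C) -- one-hot rows for plain labels, convex
    combinations of one-hot rows under mixup.  Returns (loss, dlogits).
    """
    p = softmax(logits)
    n = logits.shape[0]
    logp = logits - logits.max(axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    loss = -(targets * logp).sum() / n
    return loss, (p - targets) / n


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out
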