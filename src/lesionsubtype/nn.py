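"""Minimal CPU engine for small 3D convolutional networks.

Implements exactly the layer set the classifier needs -- 3x3x3 convolutions,
ReLU, ceil-mode 2x max pooling, flatten, fully connected layers, batch
normalization and inverted dropout -- with explicit forward and backward
passes in numpy.  Besides parameter gradients, the backward pass can return
the gradient at any intermediate layer output and at the network input, which
is what Grad-CAM++ and path-gradient attribution consume.

Convolutions are evaluated as 27 shifted channel-mixing contractions (one
per kernel offset); the backward pass reuses the same scheme, so no
scatter-adds or im2col copies are needed and everything stays vectorized.
"""

from __future__ import annotations

import numpy as np

from .errors import ArchitectureError


class Layer:
    """Base layer: forward caches what backward needs."""

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[dict]:
        """[{'value': array, 'grad': array, 'weight_decay': bool}, ...]"""
        return []


DTYPE = np.float32


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, zero padding 1 (shape-preserving).

    Implemented as 27 shifted channel-mixing einsums (one per kernel offset),
    which avoids materializing im2col patch matrices.
    """

    KS = 3

    def __init__(self, in_channels: int, out_channels: int, rng):
        self.cin, self.cout = in_channels, out_channels
        fan_in = in_channels * self.KS ** 3
        self.w = _he_init(rng, (out_channels, in_channels, self.KS, self.KS, self.KS),
                          fan_in)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp = None
        self._shape = None

    def forward(self, x, training=False, rng=None):
        n, c, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        self._xp, self._shape = xp, (n, c, d, h, w)
        y = np.empty((n, self.cout, d, h, w), dtype=DTYPE)
        y[:] = self.b[None, :, None, None, None]
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    y += np.einsum("ncdhw,oc->nodhw",
                                   xp[:, :, i:i + d, j:j + h, k:k + w],
                                   self.w[:, :, i, j, k], optimize=True)
        return y

    def backward(self, grad_out):
        n, c, d, h, w = self._shape
        self.gb += grad_out.sum(axis=(0, 2, 3, 4))
        gxp = np.zeros_like(self._xp)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = self._xp[:, :, i:i + d, j:j + h, k:k + w]
                    self.gw[:, :, i, j, k] += np.einsum(
                        "nodhw,ncdhw->oc", grad_out, xs, optimize=True)
                    gxp[:, :, i:i + d, j:j + h, k:k + w] += np.einsum(
                        "nodhw,oc->ncdhw", grad_out, self.w[:, :, i, j, k],
                        optimize=True)
        return gxp[:, :, 1:-1, 1:-1, 1:-1]

    def parameters(self):
        return [
            {"value": self.w, "grad": self.gw, "weight_decay": True},
            {"value": self.b, "grad": self.gb, "weight_decay": False},
        ]


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class MaxPool3d(Layer):
    """2x max pooling with ceil mode; axes already at size 1 are skipped."""

    def forward(self, x, training=False, rng=None):
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        k = tuple(2 if s > 1 else 1 for s in spatial)
        pad = tuple((-s) % kk for s, kk in zip(spatial, k))
        self._k, self._pad, self._inshape = k, pad, x.shape
        xp = np.pad(x, ((0, 0), (0, 0)) + tuple((0, p) for p in pad),
                    constant_values=-np.inf)
        do, ho, wo = (xp.shape[2] // k[0], xp.shape[3] // k[1], xp.shape[4] // k[2])
        r = xp.reshape(n, c, do, k[0], ho, k[1], wo, k[2])
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, do, ho, wo, -1)
        self._arg = r.argmax(axis=-1)
        self._rshape = r.shape
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad_out):
        n, c, do, ho, wo, kk = self._rshape
        g = np.zeros(self._rshape, dtype=grad_out.dtype)
        np.put_along_axis(g, self._arg[..., None], grad_out[..., None], axis=-1)
        k = self._k
        g = g.reshape(n, c, do, ho, wo, k[0], k[1], k[2])
        g = g.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(
            n, c, do * k[0], ho * k[1], wo * k[2])
        sl = tuple(slice(0, s) for s in self._inshape[2:])
        return g[(slice(None), slice(None)) + sl]


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng):
        self.w = _he_init(rng, (out_features, in_features), in_features)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad_out):
        self.gw += grad_out.T @ self._x
        self.gb += grad_out.sum(axis=0)
        return grad_out @ self.w

    def parameters(self):
        return [
            {"value": self.w, "grad": self.gw, "weight_decay": True},
            {"value": self.b, "grad": self.gb, "weight_decay": False},
        ]


class BatchNorm1d(Layer):
    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_features, dtype=DTYPE)
        self.beta = np.zeros(n_features, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training=False, rng=None):
        if training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training and x.shape[0] > 1
        return self.gamma * self._xhat + self.beta

    def backward(self, grad_out):
        self.ggamma += (grad_out * self._xhat).sum(axis=0)
        self.gbeta += grad_out.sum(axis=0)
        if not self._training:
            return grad_out * self.gamma / self._std
        n = grad_out.shape[0]
        gxhat = grad_out * self.gamma
        return (gxhat - gxhat.mean(axis=0)
                - self._xhat * (gxhat * self._xhat).mean(axis=0)) / self._std

    def parameters(self):
        # batch-norm scale/shift are exempt from weight decay
        return [
            {"value": self.gamma, "grad": self.ggamma, "weight_decay": False},
            {"value": self.beta, "grad": self.gbeta, "weight_decay": False},
        ]


class Dropout(Layer):
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Sequential:
    """Layer stack with capture of intermediate activations and gradients."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False, rng=None):
        self._acts = [x]
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
            self._acts.append(x)
        return x

    def activation(self, layer_index: int) -> np.ndarray:
        """Output of ``layers[layer_index]`` from the last forward pass."""
        return self._acts[layer_index + 1]

    def backward(self, grad_out, stop_at: int = 0) -> dict[int, np.ndarray]:
        """Backpropagate from the output; returns {layer_index: grad at its
        OUTPUT} for every layer down to ``stop_at`` plus key -1 for the grad
        at the network input."""
        grads = {len(self.layers) - 1: grad_out}
        g = grad_out
        for i in range(len(self.layers) - 1, stop_at - 1, -1):
            g = self.layers[i].backward(g)
            grads[i - 1] = g
        return grads

    def zero_grad(self):
        for layer in self.layers:
            for p in layer.parameters():
                p["grad"][...] = 0.0

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def state(self) -> list[np.ndarray]:
        arrays = [p["value"].copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                arrays.append(layer.running_mean.copy())
                arrays.append(layer.running_var.copy())
        return arrays

    def load_state(self, arrays: list[np.ndarray]):
        params = self.parameters()
        for p, a in zip(params, arrays[:len(params)]):
            p["value"][...] = a
        rest = arrays[len(params):]
        j = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = rest[j]
                layer.running_var[...] = rest[j + 1]
                j += 2


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean class-weighted cross entropy and its gradient wrt the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    w = class_weights[labels]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    loss = float(np.mean(w * nll))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad.astype(logits.dtype, copy=False)


def sgd_step(model: Sequential, lr: float, weight_decay: float = 0.0):
    """Plain SGD; L2 decay applied to weights only (not biases/batch-norm)."""
    for p in model.parameters():
        g = p["grad"]
        if weight_decay and p["weight_decay"]:
            g = g + weight_decay * p["value"]
        p["value"] -= lr * g


def spatial_after_pools(input_shape, n_blocks) -> list[tuple[int, int, int]]:
    """Spatial shape after each block's pool (ceil mode, skip at size 1)."""
    shapes = []
    s = tuple(int(v) for v in input_shape)
    for b in range(n_blocks):
        if any(v < 1 for v in s):
            raise ArchitectureError(f"spatial dimension collapsed before block {b + 1}")
        s = tuple(-(-v // 2) if v > 1 else 1 for v in s)
        shapes.append(s)
    return shapes
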