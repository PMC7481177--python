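"""Minimal 1-D convolutional neural-network layer on numpy.

Implements exactly the pieces the PPG models need — 1-D convolution
(same padding), max pooling, nearest-neighbour upsampling, dense layers,
batch normalization, dropout, ReLU family activations — with hand-written
backpropagation and an Adam optimizer.  All parameter initialization is
He-normal from an explicit ``numpy.random.Generator`` so two builds from
the same seed are bit-identical.

Conventions
-----------
* Sequence tensors are ``(N, L, C)`` — batch, length, channels.
* Dense tensors are ``(N, D)``.
* ``forward(x, training=...)`` caches whatever ``backward(grad)`` needs;
  ``backward`` returns the gradient w.r.t. the layer input and accumulates
  parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import json

import numpy as np

#: All network math runs in single precision: it halves memory traffic and
#: roughly doubles matmul throughput on one CPU core without affecting any
#: of the model's statistical behaviour.
DTYPE = np.float32

__all__ = [
    "Param", "Layer", "Conv1D", "MaxPool1D", "Upsample1D", "Dense",
    "Flatten", "ReLU", "LeakyReLU", "BatchNorm", "Dropout", "Sequential",
    "Adam", "softmax", "softmax_xent",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[Param]:
        return []


def he_normal(rng: np.random.Generator, shape: tuple[int, ...],
              fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv1D(Layer):
    """1-D convolution with 'same' zero padding, stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv",
                 input_grad: bool = True) -> None:
        if kernel < 1 or in_channels < 1 or out_channels < 1:
            raise ValueError("Conv1D sizes must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        # the first layer of a network never needs dL/dx; skipping it saves
        # the most expensive scatter-add of the whole backward pass
        self.input_grad = input_grad
        fan_in = kernel * in_channels
        self.W = Param(he_normal(rng, (kernel, in_channels, out_channels), fan_in),
                       f"{name}.W")
        self.b = Param(np.zeros(out_channels), f"{name}.b")
        self._cols: np.ndarray | None = None
        self._in_len = 0

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        n, length, cin = x.shape
        if cin != self.in_channels:
            raise ValueError(
                f"Conv1D expected {self.in_channels} channels, got {cin}")
        k = self.kernel
        pad_l = (k - 1) // 2
        pad_r = k - 1 - pad_l
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        # (N, L, C, K) -> (N, L, K, C) -> (N, L, K*C)
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(
            n, length, k * cin)
        self._cols = cols
        self._in_len = length
        wr = self.W.value.reshape(k * cin, self.out_channels)
        return cols @ wr + self.b.value

    def backward(self, grad):
        n, length, cout = grad.shape
        k, cin = self.kernel, self.in_channels
        cols2 = self._cols.reshape(-1, k * cin)
        g2 = grad.reshape(-1, cout)
        self.W.grad += (cols2.T @ g2).reshape(k, cin, cout)
        self.b.grad += g2.sum(axis=0)
        if not self.input_grad:
            return None
        wr = self.W.value.reshape(k * cin, cout)
        dcols = (grad @ wr.T).reshape(n, length, k, cin)
        pad_l = (k - 1) // 2
        dxp = np.zeros((n, length + k - 1, cin), dtype=DTYPE)
        for j in range(k):
            dxp[:, j:j + length] += dcols[:, :, j, :]
        return dxp[:, pad_l:pad_l + length]


class MaxPool1D(Layer):
    def __init__(self, factor: int) -> None:
        if factor < 2:
            raise ValueError("pool factor must be >= 2")
        self.factor = factor
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] = ()

    def forward(self, x, training=False, rng=None):
        n, length, c = x.shape
        f = self.factor
        if length % f:
            raise ValueError(f"length {length} not divisible by pool {f}")
        xr = x.reshape(n, length // f, f, c)
        self._idx = xr.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        n, length, c = self._shape
        f = self.factor
        dxr = np.zeros((n, length // f, f, c), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[:, :, None, :], grad[:, :, None, :], axis=2)
        return dxr.reshape(n, length, c)


class Upsample1D(Layer):
    """Nearest-neighbour repetition along the time axis."""

    def __init__(self, factor: int) -> None:
        if factor < 2:
            raise ValueError("upsample factor must be >= 2")
        self.factor = factor

    def forward(self, x, training=False, rng=None):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, grad):
        n, length, c = grad.shape
        f = self.factor
        return grad.reshape(n, length // f, f, c).sum(axis=2)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 name: str = "dense") -> None:
        self.in_dim, self.out_dim = in_dim, out_dim
        self.W = Param(he_normal(rng, (in_dim, out_dim), in_dim), f"{name}.W")
        self.b = Param(np.zeros(out_dim), f"{name}.b")
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.in_dim:
            raise ValueError(f"Dense expected {self.in_dim} features, got {x.shape[1]}")
        x = np.asarray(x, dtype=DTYPE)
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] = ()

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1) -> None:
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class BatchNorm(Layer):
    """Per-channel batch normalization for (N, L, C) or (N, D) tensors."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5, name: str = "bn") -> None:
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None
        self._inference = True

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0, 1) if x.ndim == 3 else (0,)

    def forward(self, x, training=False, rng=None):
        axes = self._axes(x)
        self._inference = not training
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, axes, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.value
        if self._inference:
            return grad * g * inv
        m = np.prod([shape[a] for a in axes])
        dxhat = grad * g
        return (inv / m) * (m * dxhat - dxhat.sum(axis=axes, keepdims=True)
                            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        self._mask = ((rng.random(x.shape) >= self.rate) / (1 - self.rate)).astype(DTYPE)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def forward_upto(self, x, stop: int, training=False, rng=None):
        """Run only ``layers[:stop]`` — used for activation probes."""
        for layer in self.layers[:stop]:
            x = layer.forward(x, training=training, rng=rng)
        return x

    # -- persistence -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                state[f"layer{i:03d}.p{j}"] = p.value
            if isinstance(layer, BatchNorm):
                state[f"layer{i:03d}.running_mean"] = layer.running_mean
                state[f"layer{i:03d}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                key = f"layer{i:03d}.p{j}"
                if state[key].shape != p.value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: expected {p.value.shape}, "
                        f"got {state[key].shape}")
                p.value = np.asarray(state[key], dtype=DTYPE)
                p.grad = np.zeros_like(p.value)
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(
                    state[f"layer{i:03d}.running_mean"], dtype=DTYPE)
                layer.running_var = np.asarray(
                    state[f"layer{i:03d}.running_var"], dtype=DTYPE)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray,
                 sample_weight: np.ndarray | None = None
                 ) -> tuple[float, np.ndarray]:
    """Softmax cross-entropy loss and its gradient w.r.t. the logits.

    ``labels`` are integer class indices; ``sample_weight`` rescales each
    example's contribution (used for inverse-frequency class weighting).
    Returns (mean weighted loss, dL/dlogits).
    """
    n = logits.shape[0]
    probs = softmax(np.asarray(logits, dtype=np.float64))
    if sample_weight is None:
        sample_weight = np.ones(n)
    logp = np.log(np.clip(probs[np.arange(n), labels], 1e-12, None))
    loss = float(-(sample_weight * logp).sum() / n)
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= sample_weight[:, None] / n
    return loss, grad.astype(DTYPE)


def save_npz(path, arrays: dict[str, np.ndarray], config: dict | None = None) -> None:
    """Checkpoint arrays to .npz with an optional JSON config sidecar."""
    np.savez(path, **arrays)
    if config is not None:
        sidecar = str(path) + ".json" if not str(path).endswith(".npz") \
            else str(path)[:-4] + ".json"
        with open(sidecar, "w") as fh:
            json.dump(config, fh, indent=2, sort_keys=True)


def load_npz(path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: np.array(v) for k, v in data.items()}
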