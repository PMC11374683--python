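"""Minimal NumPy neural-network engine for the convolutional potency model.

Implements exactly the layers the potency regressor needs — 1-D
convolution, batch normalization, max pooling, dropout and dense layers —
with reverse-mode gradients and an Adam optimizer. Everything is driven by
a single seeded ``numpy.random.Generator``, so training is bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np


class Layer:
    """Base layer: parameter dicts ``params``/``grads`` plus forward/backward."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator):
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def reg_loss(self) -> float:
        return 0.0


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float64)


class Conv1D(Layer):
    """Valid or shape-preserving 1-D convolution with optional ReLU and
    L2 penalties on kernel and/or bias."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        padding: str = "valid",
        relu: bool = True,
        l2_kernel: float = 0.0,
        l2_bias: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same', got {padding!r}")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.padding = padding
        self.relu = relu
        self.l2_kernel, self.l2_bias = l2_kernel, l2_bias
        rng = rng or np.random.default_rng()
        self.params = {
            "W": _glorot_uniform(rng, kernel * in_ch, out_ch, (kernel * in_ch, out_ch)),
            "b": np.zeros(out_ch),
        }

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "same":
            left = (self.kernel - 1) // 2
            right = self.kernel - 1 - left
            return np.pad(x, ((0, 0), (left, right), (0, 0)))
        return x

    def forward(self, x, training, rng):
        xp = self._pad(x)
        n, lp, cin = xp.shape
        lout = lp - self.kernel + 1
        patches = np.concatenate(
            [xp[:, j:j + lout, :] for j in range(self.kernel)], axis=2
        )
        z = patches @ self.params["W"] + self.params["b"]
        self._patches, self._z, self._xshape = patches, z, x.shape
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout):
        if self.relu:
            dout = dout * (self._z > 0)
        W = self.params["W"]
        n, lout, cout = dout.shape
        k, cin = self.kernel, self.in_ch
        flat_p = self._patches.reshape(-1, k * cin)
        flat_d = dout.reshape(-1, cout)
        self.grads["W"] = flat_p.T @ flat_d + 2.0 * self.l2_kernel * W
        self.grads["b"] = flat_d.sum(axis=0) + 2.0 * self.l2_bias * self.params["b"]
        dpatches = dout @ W.T
        lp = lout + k - 1
        dxp = np.zeros((n, lp, cin))
        for j in range(k):
            dxp[:, j:j + lout, :] += dpatches[:, :, j * cin:(j + 1) * cin]
        if self.padding == "same":
            left = (k - 1) // 2
            dxp = dxp[:, left:left + self._xshape[1], :]
        return dxp

    def reg_loss(self):
        return self.l2_kernel * float(np.sum(self.params["W"] ** 2)) + \
            self.l2_bias * float(np.sum(self.params["b"] ** 2))


class BatchNorm(Layer):
    """Channel-wise batch normalization over (batch, positions)."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training, rng):
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[1]
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        gamma = self.params["gamma"]
        xhat, inv, m = self._xhat, self._inv, self._m
        self.grads["gamma"] = np.sum(dout * xhat, axis=(0, 1))
        self.grads["beta"] = np.sum(dout, axis=(0, 1))
        dxhat = dout * gamma
        dx = inv / m * (
            m * dxhat
            - np.sum(dxhat, axis=(0, 1))
            - xhat * np.sum(dxhat * xhat, axis=(0, 1))
        )
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling (pool width == stride); the remainder
    of an odd-length input is dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training, rng):
        n, l, c = x.shape
        lout = l // self.pool
        xc = x[:, :lout * self.pool, :].reshape(n, lout, self.pool, c)
        self._arg = xc.argmax(axis=2)
        self._inshape = x.shape
        return np.take_along_axis(xc, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout):
        n, l, c = self._inshape
        lout = l // self.pool
        dxc = np.zeros((n, lout, self.pool, c))
        np.put_along_axis(dxc, self._arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros((n, l, c))
        dx[:, :lout * self.pool, :] = dxc.reshape(n, lout * self.pool, c)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._inshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._inshape)


class Dense(Layer):
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        relu: bool = True,
        l2_kernel: float = 0.0,
        l2_bias: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.relu = relu
        self.l2_kernel, self.l2_bias = l2_kernel, l2_bias
        rng = rng or np.random.default_rng()
        self.params = {
            "W": _glorot_uniform(rng, in_dim, out_dim, (in_dim, out_dim)),
            "b": np.zeros(out_dim),
        }

    def forward(self, x, training, rng):
        z = x @ self.params["W"] + self.params["b"]
        self._x, self._z = x, z
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout):
        if self.relu:
            dout = dout * (self._z > 0)
        self.grads["W"] = self._x.T @ dout + 2.0 * self.l2_kernel * self.params["W"]
        self.grads["b"] = dout.sum(axis=0) + 2.0 * self.l2_bias * self.params["b"]
        return dout @ self.params["W"].T

    def reg_loss(self):
        return self.l2_kernel * float(np.sum(self.params["W"] ** 2)) + \
            self.l2_bias * float(np.sum(self.params["b"] ** 2))


class Network:
    """A plain feed-forward stack of layers."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng()
        out = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def reg_loss(self) -> float:
        return sum(layer.reg_loss() for layer in self.layers)

    def parameters(self):
        """Yield (layer_index, name, array) triples."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield i, name, layer.params[name]

    def n_parameters(self) -> int:
        return sum(p.size for _, _, p in self.parameters())

    def get_state(self) -> dict:
        state = {
            f"{i}.{name}": p.copy() for i, name, p in self.parameters()
        }
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()


class Adam:
    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {f"{i}.{n}": np.zeros_like(p) for i, n, p in net.parameters()}
        self.v = {f"{i}.{n}": np.zeros_like(p) for i, n, p in net.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.net.layers):
            for name, p in layer.params.items():
                key = f"{i}.{name}"
                g = layer.grads[name]
                self.m[key] = b1 * self.m[key] + (1 - b1) * g
                self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
                mhat = self.m[key] / (1 - b1 ** self.t)
                vhat = self.v[key] / (1 - b2 ** self.t)
                layer.params[name] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def weighted_mse(y_true: np.ndarray, y_pred: np.ndarray,
                 alpha: Sequence[float]) -> float:
    """Weighted sum of per-task mean-squared errors."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.shape[1] != len(alpha):
        raise ValueError("alpha length must match the number of tasks")
    per_task = np.mean((y_true - y_pred) ** 2, axis=0)
    return float(np.dot(alpha, per_task))


def fit_network(
    net: Network,
    X: np.ndarray,
    Y: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    alpha: Sequence[float],
    batch_size: int,
    max_epochs: int,
    patience: int,
    lr: float,
    rng: np.random.Generator,
) -> tuple[dict, int]:
    """Mini-batch Adam training with validation-loss early stopping.

    Stops once the validation loss has failed to improve for more than
    ``patience`` consecutive epochs, and restores the best-validation
    weights. Returns (history, stopped_epoch)."""
    n = X.shape[0]
    if n == 0 or X_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    opt = Adam(net, lr=lr)
    alpha = np.asarray(alpha, dtype=float)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = net.get_state()
    wait = 0
    stopped_epoch = max_epochs
    for epoch in range(1, max_epochs + 1):
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            xb, yb = X[idx], Y[idx]
            pred = net.forward(xb, training=True, rng=rng)
            task_loss = weighted_mse(yb, pred, alpha)
            batch_losses.append(task_loss + net.reg_loss())
            dpred = 2.0 * alpha * (pred - yb) / xb.shape[0]
            net.backward(dpred)
            opt.step()
        val_pred = net.forward(X_val, training=False)
        val_loss = weighted_mse(Y_val, val_pred, alpha)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = net.get_state()
            wait = 0
        else:
            wait += 1
            if wait > patience:
                stopped_epoch = epoch
                break
    net.set_state(best_state)
    return history, min(stopped_epoch, len(history["val_loss"]))


def clone_network(net: Network) -> Network:
    return copy.deepcopy(net)
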