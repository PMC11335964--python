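"""Minimal numpy implementation of the epoch-classification CNN.

Architecture (time-axis 1-D convolutions, channels as input feature maps):

    BatchNorm -> 4 x (Conv1D -> GELU -> MaxPool) -> BatchNorm
              -> flatten -> 3 x (Dense -> ReLU) -> Dense -> softmax

Forward, backward (for both parameters and inputs), Adam, and L2
regularization are implemented directly so that the attribution stage can
query exact input gradients of the class probabilities.  All arithmetic is
float32; every source of randomness is an explicit Generator.
"""

from __future__ import annotations

import io
import json
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

_SQRT2 = np.float32(np.sqrt(2.0))
_INV_SQRT_2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


class Layer:
    """Base: parameterized layers fill ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BatchNorm(Layer):
    """Batch normalization over all axes except the feature axis.

    Accepts (B, C, T) with features on axis 1 or (B, D) with features on
    axis 1; running statistics are used in inference mode.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {
            "gamma": np.ones(n_features, dtype=np.float32),
            "beta": np.zeros(n_features, dtype=np.float32),
        }
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def _shape(self, x: np.ndarray) -> tuple[tuple[int, ...], tuple[int, ...]]:
        if x.ndim == 3:
            return (0, 2), (1, -1, 1)
        return (0,), (1, -1)

    def forward(self, x, training):
        axes, bshape = self._shape(x)
        gamma = self.params["gamma"].reshape(bshape)
        beta = self.params["beta"].reshape(bshape)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bshape)) * invstd.reshape(bshape)
        self._cache = (xhat.astype(np.float32), invstd.astype(np.float32), axes, bshape, training)
        return (gamma * xhat + beta).astype(np.float32)

    def backward(self, dout):
        xhat, invstd, axes, bshape, training = self._cache
        gamma = self.params["gamma"].reshape(bshape)
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        if not training:
            return (dout * gamma * invstd.reshape(bshape)).astype(np.float32)
        m = dout.size / gamma.size
        dxhat = dout * gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * invstd.reshape(bshape)
        return dx.astype(np.float32)


class Conv1D(Layer):
    """Same-padded 1-D convolution along the time axis: (B, Cin, T) -> (B, F, T)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 init: str = "glorot_uniform"):
        super().__init__()
        fan_in, fan_out = c_in * kernel, c_out * kernel
        if init == "glorot_normal":
            std = np.sqrt(2.0 / (fan_in + fan_out))
            W = rng.normal(0.0, std, (c_out, c_in, kernel))
        else:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            W = rng.uniform(-limit, limit, (c_out, c_in, kernel))
        self.params = {
            "W": W.astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.kernel = kernel
        self.pad = ((kernel - 1) // 2, kernel // 2)

    def forward(self, x, training):
        B, C, T = x.shape
        K = self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), self.pad))
        cols = sliding_window_view(xp, K, axis=2)  # (B, C, T, K)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B, T, C * K)
        Wm = self.params["W"].reshape(-1, C * K)  # (F, C*K)
        out = cols @ Wm.T + self.params["b"]
        self._cache = (cols, (B, C, T))
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, dout):
        cols, (B, C, T) = self._cache
        K = self.kernel
        F = dout.shape[1]
        do = np.ascontiguousarray(dout.transpose(0, 2, 1))  # (B, T, F)
        Wm = self.params["W"].reshape(F, C * K)
        self.grads["W"] = (
            do.reshape(-1, F).T @ cols.reshape(-1, C * K)
        ).reshape(F, C, K)
        self.grads["b"] = do.sum(axis=(0, 1))
        dcols = (do @ Wm).reshape(B, T, C, K)
        dxp = np.zeros((B, C, T + self.pad[0] + self.pad[1]), dtype=np.float32)
        for k in range(K):
            dxp[:, :, k : k + T] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dxp[:, :, self.pad[0] : self.pad[0] + T]


class GELU(Layer):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x, training):
        self._cache = x
        return (0.5 * x * (1.0 + erf(x / _SQRT2))).astype(np.float32)

    def backward(self, dout):
        x = self._cache
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return (dout * (cdf + x * pdf)).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training):
        self._cache = x > 0
        return np.where(self._cache, x, np.float32(0.0))

    def backward(self, dout):
        return np.where(self._cache, dout, np.float32(0.0))


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; a trailing remainder of the
    time axis shorter than the pool is dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training):
        B, C, T = x.shape
        p = self.pool
        Tp = (T // p) * p
        xr = x[:, :, :Tp].reshape(B, C, Tp // p, p)
        arg = xr.argmax(axis=3)
        self._cache = (arg, (B, C, T))
        return np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]

    def backward(self, dout):
        arg, (B, C, T) = self._cache
        p = self.pool
        dxr = np.zeros((B, C, T // p, p), dtype=np.float32)
        np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=3)
        dx = np.zeros((B, C, T), dtype=np.float32)
        dx[:, :, : (T // p) * p] = dxr.reshape(B, C, (T // p) * p)
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._cache)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.params = {
            "W": rng.uniform(-limit, limit, (d_in, d_out)).astype(np.float32),
            "b": np.zeros(d_out, dtype=np.float32),
        }

    def forward(self, x, training):
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._cache
        self.grads["W"] = x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet:
    """The assembled classifier; maps (B, n_channels, n_times) to logits."""

    def __init__(
        self,
        n_channels: int,
        n_times: int,
        n_classes: int,
        conv_filters: Sequence[int] = (16, 32, 64, 128),
        kernel_size: int = 50,
        pool_size: int = 2,
        dense_units: Sequence[int] = (128, 64, 32),
        l2: float = 1e-4,
        seed: int = 0,
    ):
        if n_times <= kernel_size:
            raise ValueError(
                f"n_times ({n_times}) must exceed kernel_size ({kernel_size})"
            )
        rng = np.random.default_rng(seed)
        self.n_channels, self.n_times, self.n_classes = n_channels, n_times, n_classes
        self.l2 = float(l2)
        self.spec = {
            "conv_filters": list(conv_filters),
            "kernel_size": int(kernel_size),
            "pool_size": int(pool_size),
            "dense_units": list(dense_units),
            "l2": self.l2,
        }
        layers: list[Layer] = [BatchNorm(n_channels)]
        c, t = n_channels, n_times
        for i, f in enumerate(conv_filters):
            init = "glorot_normal" if i == 0 else "glorot_uniform"
            layers += [Conv1D(c, f, kernel_size, rng, init), GELU(), MaxPool1D(pool_size)]
            c, t = f, t // pool_size
        if t < 1:
            raise ValueError("time axis fully consumed by pooling; reduce pool/depth")
        layers.append(BatchNorm(c))
        layers.append(Flatten())
        d = c * t
        for u in dense_units:
            layers += [Dense(d, u, rng), ReLU()]
            d = u
        layers.append(Dense(d, n_classes, rng))
        self.layers = layers
        self._kernel_layers = [l for l in layers if isinstance(l, (Conv1D, Dense))]

    # -- forward/backward ---------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def _backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [
            softmax(self.forward(x[i : i + batch_size], training=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    # -- training ------------------------------------------------------------
    def loss_and_param_grads(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        """Cross-entropy + L2; fills every layer's ``grads``."""
        logits = self.forward(x, training=True)
        logits64 = logits.astype(np.float64)
        logz = logits64 - logits64.max(axis=1, keepdims=True)
        logp = logz - np.log(np.exp(logz).sum(axis=1, keepdims=True))
        ce = -(y_onehot * logp).sum() / len(x)
        if not np.isfinite(ce):
            raise FloatingPointError("non-finite training loss; training diverged")
        p = np.exp(logp)
        self._backward(((p - y_onehot) / len(x)).astype(np.float32))
        reg = 0.0
        for layer in self._kernel_layers:
            W = layer.params["W"]
            reg += float((W.astype(np.float64) ** 2).sum())
            layer.grads["W"] = layer.grads["W"] + 2.0 * self.l2 * W
        return float(ce + self.l2 * reg)

    def evaluate_loss(self, x: np.ndarray, y_onehot: np.ndarray, batch_size: int = 256) -> tuple[float, float]:
        """(mean CE loss, accuracy) in inference mode."""
        tot, hits = 0.0, 0
        for i in range(0, len(x), batch_size):
            xb, yb = x[i : i + batch_size], y_onehot[i : i + batch_size]
            logits = self.forward(xb, training=False).astype(np.float64)
            logz = logits - logits.max(axis=1, keepdims=True)
            logp = logz - np.log(np.exp(logz).sum(axis=1, keepdims=True))
            tot += -(yb * logp).sum()
            hits += int((logp.argmax(axis=1) == yb.argmax(axis=1)).sum())
        return tot / len(x), hits / len(x)

    # -- input gradients (attribution support) -------------------------------
    def class_input_gradients(
        self, x: np.ndarray, class_indices: Sequence[int]
    ) -> np.ndarray:
        """d p_c / d x for each requested class, one shared inference-mode
        forward pass; returns (n_classes_requested, B, C, T)."""
        logits = self.forward(x, training=False)
        p = softmax(logits)
        grads = []
        for c in class_indices:
            dlogits = p * (-p[:, [c]])
            dlogits[:, c] += p[:, c]
            grads.append(self._backward(dlogits))
        return np.stack(grads, axis=0)

    def output_input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        return self.class_input_gradients(x, [class_index])[0]

    # -- (de)serialization ----------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            for k in sorted(layer.params):
                out.append(layer.params[k].copy())
            if isinstance(layer, BatchNorm):
                out += [layer.running_mean.copy(), layer.running_var.copy()]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for k in sorted(layer.params):
                layer.params[k] = next(it).copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    def save(self, path) -> None:
        meta = dict(
            self.spec,
            n_channels=self.n_channels,
            n_times=self.n_times,
            n_classes=self.n_classes,
        )
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        with open(path, "wb") as fh:
            buf = io.BytesIO()
            np.savez(buf, meta=json.dumps(meta), **arrays)
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "ConvNet":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            weights = [z[f"w{i}"] for i in range(len(z.files) - 1)]
        net = cls(
            n_channels=meta["n_channels"],
            n_times=meta["n_times"],
            n_classes=meta["n_classes"],
            conv_filters=meta["conv_filters"],
            kernel_size=meta["kernel_size"],
            pool_size=meta["pool_size"],
            dense_units=meta["dense_units"],
            l2=meta["l2"],
        )
        net.set_weights(weights)
        return net


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, layers: Sequence[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, g in layer.grads.items():
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                layer.params[k] = (
                    layer.params[k]
                    - self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
                ).astype(np.float32)
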