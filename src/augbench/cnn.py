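"""Reference 3D CNN binary classifier, implemented directly in NumPy.

The architecture: three 3x3x3 convolutional layers with ReLU (8, 8 and 16
filters), 2x2x2 max-pooling after the first and second convolutions, a
16-unit dense layer with ReLU, and a single sigmoid output node. With valid
padding on the standard 61 x 73 x 61 derivative grid this comes to 439,129
trainable parameters (approximately 450 k). The pooling/padding schedule is
pinned by that parameter count: three pools would give ~50 k, same-padding
with three pools ~118 k, both inconsistent with it.

Convolutions are evaluated as im2col matrix products; the backward pass is
the standard full correlation with spatially flipped kernels, verified
against numerical differentiation in the test suite. Everything is exact,
deterministic given the initialization seed, and fast enough on one CPU for
the scaled-down phantom volumes the package trains on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .volumes import BrainVolume


@dataclass
class CNNSpec:
    """Architecture hyperparameters of the reference classifier."""

    input_shape: tuple[int, int, int, int] = (61, 73, 61, 1)
    conv_filters: tuple[int, ...] = (8, 8, 16)
    kernel_size: int = 3
    pool_after: tuple[bool, ...] = (True, True, False)
    padding_mode: str = "valid"
    dense_units: int = 16

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        self.pool_after = tuple(bool(p) for p in self.pool_after)
        if len(self.input_shape) != 4:
            raise ValueError("input_shape must be (x, y, z, channels)")
        if len(self.conv_filters) != len(self.pool_after):
            raise ValueError("pool_after must match conv_filters in length")
        if self.padding_mode not in ("valid", "same"):
            raise ValueError("padding_mode must be 'valid' or 'same'")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        layer_output_shapes(self)  # raises on spatial collapse


def layer_output_shapes(spec: CNNSpec) -> list[tuple[int, ...]]:
    """Output shape after each conv/pool stage, then the flattened size.

    Raises ``ValueError`` if any spatial dimension collapses below 1.
    """
    d = list(spec.input_shape[:3])
    k = spec.kernel_size
    shapes: list[tuple[int, ...]] = []
    for i, (filters, pooled) in enumerate(zip(spec.conv_filters, spec.pool_after)):
        if spec.padding_mode == "valid":
            d = [x - (k - 1) for x in d]
        if any(x < 1 for x in d):
            raise ValueError(
                f"spatial collapse at conv layer {i + 1}: shape {tuple(d)}"
            )
        shapes.append(tuple(d) + (filters,))
        if pooled:
            d = [x // 2 for x in d]
            if any(x < 1 for x in d):
                raise ValueError(
                    f"spatial collapse at pool after conv {i + 1}: shape {tuple(d)}"
                )
            shapes.append(tuple(d) + (filters,))
    flat = int(np.prod(d)) * spec.conv_filters[-1]
    shapes.append((flat,))
    return shapes


def parameter_breakdown(spec: CNNSpec) -> dict[str, int]:
    """Exact trainable-parameter count per layer (weights + biases)."""
    k3 = spec.kernel_size**3
    counts: dict[str, int] = {}
    c_in = spec.input_shape[3]
    for i, f in enumerate(spec.conv_filters):
        counts[f"conv{i + 1}"] = k3 * c_in * f + f
        c_in = f
    flat = layer_output_shapes(spec)[-1][0]
    counts["dense"] = flat * spec.dense_units + spec.dense_units
    counts["output"] = spec.dense_units + 1
    return counts


def count_trainable_parameters(spec: CNNSpec) -> int:
    """Total number of trainable weights and biases."""
    return sum(parameter_breakdown(spec).values())


# ---------------------------------------------------------------------------
# layers


class _Conv3D:
    """3D convolution: im2col GEMM forward, offset-loop backward.

    The forward pass gathers the k^3 * c_in patch matrix once and runs a
    single GEMM (the patch matrix is also reused for the weight gradient).
    The input gradient instead accumulates one small GEMM per kernel offset
    into array slices, which avoids materializing the k^3-fold expansion of
    the upstream gradient — the memory bottleneck at these volume sizes.
    """

    def __init__(self, c_in: int, c_out: int, k: int, padding: str, rng, dtype):
        fan_in = k**3 * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, k, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k = k
        self.pad = (k - 1) // 2 if padding == "same" else 0
        self.params = {"W": self.W, "b": self.b}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.pad:
            p = self.pad
            x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        k = self.k
        n = x.shape[0]
        win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
        win = np.moveaxis(win, 4, 7)  # (n, do, ho, wo, k, k, k, c_in)
        do, ho, wo = win.shape[1:4]
        cols = win.reshape(n * do * ho * wo, -1)
        c_out = self.b.shape[0]
        out = cols @ self.params["W"].reshape(-1, c_out) + self.params["b"]
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return out.reshape(n, do, ho, wo, c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        do, ho, wo = dy.shape[1:4]
        c_out = dy.shape[4]
        W = self.params["W"]
        dyf = dy.reshape(-1, c_out)
        self.grads["b"] = dyf.sum(axis=0)
        self.grads["W"] = (self._cols.T @ dyf).reshape(W.shape)
        self._cols = None
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    dx[:, kd : kd + do, kh : kh + ho, kw : kw + wo, :] += dy @ W[kd, kh, kw].T
        if self.pad:
            p = self.pad
            dx = dx[:, p:-p, p:-p, p:-p, :]
        return dx


class _ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool3D:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, D, H, W, c = x.shape
        d, h, w = D // 2, H // 2, W // 2
        xr = (
            x[:, : 2 * d, : 2 * h, : 2 * w, :]
            .reshape(n, d, 2, h, 2, w, 2, c)
            .transpose(0, 1, 3, 5, 7, 2, 4, 6)
            .reshape(n, d, h, w, c, 8)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, D, H, W, c = self._in_shape
        d, h, w = D // 2, H // 2, W // 2
        g = np.zeros((n, d, h, w, c, 8), dtype=dy.dtype)
        np.put_along_axis(g, self._idx[..., None], dy[..., None], axis=-1)
        g = (
            g.reshape(n, d, h, w, c, 2, 2, 2)
            .transpose(0, 1, 5, 2, 6, 3, 7, 4)
            .reshape(n, 2 * d, 2 * h, 2 * w, c)
        )
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : 2 * d, : 2 * h, : 2 * w, :] = g
        return dx


class _Flatten:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng, dtype):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = {"W": self.W, "b": self.b}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# model


class CNN3D:
    """A built (possibly trained) instance of the reference classifier.

    ``history`` is populated by the training loop with per-epoch metrics.
    """

    def __init__(self, spec: CNNSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = int(seed)
        self.dtype = dtype
        self.history: Optional[dict[str, list]] = None
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in = spec.input_shape[3]
        for filters, pooled in zip(spec.conv_filters, spec.pool_after):
            layers.append(_Conv3D(c_in, filters, spec.kernel_size, spec.padding_mode, rng, dtype))
            layers.append(_ReLU())
            if pooled:
                layers.append(_MaxPool3D())
            c_in = filters
        layers.append(_Flatten())
        flat = layer_output_shapes(spec)[-1][0]
        layers.append(_Dense(flat, spec.dense_units, rng, dtype))
        layers.append(_ReLU())
        layers.append(_Dense(spec.dense_units, 1, rng, dtype))
        self.layers = layers

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[tuple[object, str]]:
        return [(layer, key) for layer in self.layers for key in layer.params]

    def n_parameters(self) -> int:
        return sum(layer.params[k].size for layer, k in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[k].copy() for layer, k in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for (layer, k), w in zip(self.parameters(), weights):
            layer.params[k][...] = w

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch shaped (n, x, y, z) or (n, x, y, z, 1)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 4:
            x = x[..., None]
        if x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec {self.spec.input_shape}"
            )
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dy = np.asarray(dlogits, dtype=self.dtype)[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)


class Adam:
    """Adam optimizer over a model's parameter list (Keras-style defaults)."""

    def __init__(self, model: CNN3D, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in model.parameters()]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for i, (layer, key) in enumerate(self.model.parameters()):
            g = layer.grads[key]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            layer.params[key] -= lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, (p - y) / z.size


def build_model(spec: CNNSpec, seed: int = 0, dtype=np.float32) -> CNN3D:
    """Build an untrained classifier with seed-deterministic initialization."""
    return CNN3D(spec, seed=seed, dtype=dtype)


def _volumes_to_batch(volumes, spec: CNNSpec) -> np.ndarray:
    if isinstance(volumes, np.ndarray):
        x = volumes
        if x.ndim == 3:
            x = x[None]
    else:
        x = np.stack(
            [v.data if isinstance(v, BrainVolume) else np.asarray(v) for v in volumes]
        )
    if x.shape[1:4] != spec.input_shape[:3]:
        raise ValueError(
            f"volume shape {x.shape[1:4]} does not match spec {spec.input_shape[:3]}"
        )
    return x


def predict_proba(model: CNN3D, volumes, batch_size: int = 16) -> np.ndarray:
    """Sigmoid class-1 probability for each volume; deterministic, order-stable."""
    x = _volumes_to_batch(volumes, model.spec)
    probs = []
    for start in range(0, x.shape[0], batch_size):
        z = model.forward_logits(x[start : start + batch_size], train=False)
        probs.append(1.0 / (1.0 + np.exp(-z.astype(np.float64))))
    return np.concatenate(probs)


def classify(model: CNN3D, volume, threshold: float = 0.5) -> int:
    """Binary label: 1 iff the predicted probability is >= threshold (boundary inclusive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    data = volume.data if isinstance(volume, BrainVolume) else np.asarray(volume)
    p = predict_proba(model, data[None])[0]
    return int(p >= threshold)
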