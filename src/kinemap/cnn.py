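"""A small convolutional network for 28×28 acceleration images.

Architecture (fixed by :class:`ModelSpec` defaults):

    input 28×28×1
    → conv 3×3, 8 filters, zero-padding 1 → batch-norm → ReLU → max-pool 2×2/2
    → conv 3×3, 16 filters, padding 1     → batch-norm → ReLU → max-pool 2×2/2
    → conv 3×3, 32 filters, padding 1     → batch-norm → ReLU
    → fully connected (7·7·32 = 1568 → 2) → softmax

Channel counts double per block while spatial extent halves, and the two-way
softmax head scores each image as ADHD-like vs control-like.  Class order is
fixed: index 0 = ADHD, index 1 = control.

Everything — im2col convolutions, batch normalisation, max-pooling, SGD with
momentum — is implemented directly on numpy arrays in float32.  The network
is small enough (≈20k parameters) that CPU training over tens of thousands of
28×28 binary images takes seconds per epoch, and keeping the numerics in one
place makes seeded runs bit-reproducible.

Training uses mini-batch SGD with momentum on the softmax cross-entropy; the
learning rate, momentum, epoch and batch-size defaults mirror common
framework defaults for this kind of model and live in :class:`TrainConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CLASSES",
    "ADHD",
    "CONTROL",
    "ModelSpec",
    "TrainConfig",
    "softmax",
    "AccelCNN",
    "build_model",
]

#: Fixed class order of the softmax head.
CLASSES = ("ADHD", "control")
ADHD, CONTROL = 0, 1


@dataclass(frozen=True)
class ModelSpec:
    """Layer hyper-parameters of the image classifier."""

    image_size: int = 28
    in_channels: int = 1
    conv_channels: tuple[int, ...] = (8, 16, 32)
    kernel: int = 3
    pool_after: tuple[bool, ...] = (True, True, False)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.pool_after) != len(self.conv_channels):
            raise ValueError("pool_after must match conv_channels in length")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd (same-padding convolution)")
        if self.flat_dim <= 0:
            raise ValueError("spatial size collapsed to zero; too many pools")

    @property
    def flat_dim(self) -> int:
        """Input dimension of the fully connected head."""
        size = self.image_size
        for pooled in self.pool_after:
            if pooled:
                size //= 2
        return size * size * self.conv_channels[-1]


@dataclass
class TrainConfig:
    """Optimisation settings for :meth:`AccelCNN.fit`."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 10
    batch_size: int = 128
    seed: int = 0
    class_weighting: bool = False
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis.

    ``p_i = exp(z_i) / Σ_j exp(z_j)`` with the row maximum subtracted first,
    so shifted logits give identical probabilities.
    """
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# layers — NHWC activations, float32

class _Conv3x3:
    """Same-padding k×k convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.k = k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        pad = k // 2
        b_, h, w_, c = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        # (b, h, w, c, k, k) -> (b*h*w, c*k*k); kernel dims minor, channel major
        cols = sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = cols.reshape(b_ * h * w_, c * k * k)
        out = cols @ self.w + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(b_, h, w_, -1)

    def backward(self, dy: np.ndarray):
        cols, x_shape = self._cache
        b_, h, w_, c = x_shape
        k = self.k
        pad = k // 2
        dyf = dy.reshape(-1, dy.shape[-1]).astype(np.float32)
        self.dw = cols.T @ dyf
        self.db = dyf.sum(axis=0)
        dcols = (dyf @ self.w.T).reshape(b_, h, w_, c, k, k)
        dxp = np.zeros((b_, h + 2 * pad, w_ + 2 * pad, c), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + h, kj : kj + w_, :] += dcols[:, :, :, :, ki, kj]
        return dxp[:, pad : pad + h, pad : pad + w_, :]

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _BatchNorm:
    """Per-channel batch normalisation over (batch, height, width)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            axes = tuple(range(x.ndim - 1))
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (xhat, inv_std, x.shape)
            return (self.gamma * xhat + self.beta).astype(np.float32)
        inv_std = 1.0 / np.sqrt(self.run_var + self.eps)
        return (self.gamma * (x - self.run_mean) * inv_std + self.beta).astype(np.float32)

    def backward(self, dy: np.ndarray):
        xhat, inv_std, shape = self._cache
        axes = tuple(range(dy.ndim - 1))
        m = dy.size // dy.shape[-1]
        self.dgamma = (dy * xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        # standard batch-norm gradient, vectorised per channel
        dxhat = dy * self.gamma
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) * inv_std
        return dx.astype(np.float32)

    def params(self):
        return [("gamma", self.gamma, "dgamma"), ("beta", self.beta, "dbeta")]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool2:
    """2×2 max-pooling with stride 2 (even spatial dims assumed)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(b, h // 2, w // 2, c, 4)
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg = arg
            self._shape = x.shape
        return out

    def backward(self, dy: np.ndarray):
        b, h, w, c = self._shape
        dxr = np.zeros((b, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(b, h, w, c)

    def params(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray):
        return dy.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


# ---------------------------------------------------------------------------


class AccelCNN:
    """The acceleration-image classifier, trainable with plain SGD+momentum.

    Implements the classifier interface used by the evaluation harnesses:
    :meth:`fit` and :meth:`predict_proba`.
    """

    def __init__(self, spec: ModelSpec | None = None, seed: int = 0):
        self.spec = spec or ModelSpec()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        s = self.spec
        layers: list = []
        c_in = s.in_channels
        for c_out, pooled in zip(s.conv_channels, s.pool_after):
            layers.append(_Conv3x3(c_in, c_out, s.kernel, rng))
            layers.append(_BatchNorm(c_out))
            layers.append(_ReLU())
            if pooled:
                layers.append(_MaxPool2())
            c_in = c_out
        layers.append(_Flatten())
        layers.append(_Dense(s.flat_dim, s.n_classes, rng))
        self.layers = layers
        self.train_log: list[dict] = []

    # -- parameter access -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        """Flat name → array view of every trainable and running parameter."""
        out = {}
        for li, layer in enumerate(self.layers):
            for name, arr, _ in layer.params():
                out[f"layer{li}.{name}"] = arr
            if isinstance(layer, _BatchNorm):
                out[f"layer{li}.run_mean"] = layer.run_mean
                out[f"layer{li}.run_var"] = layer.run_var
        return out

    def save(self, path) -> None:
        """Checkpoint: parameter arrays (.npz) + JSON architecture/seed manifest."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.parameters())
        manifest = {"seed": self.seed, "spec": asdict(self.spec),
                    "epochs_trained": len(self.train_log)}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    def load_parameters(self, arrays: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name, arr, _ in layer.params():
                arr[...] = arrays[f"layer{li}.{name}"]
            if isinstance(layer, _BatchNorm):
                layer.run_mean[...] = arrays[f"layer{li}.run_mean"]
                layer.run_var[...] = arrays[f"layer{li}.run_var"]

    # -- forward / loss ---------------------------------------------------

    @staticmethod
    def _prepare(images: np.ndarray, image_size: int) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4 or x.shape[1] != image_size or x.shape[2] != image_size:
            raise ValueError(
                f"images must be (k, {image_size}, {image_size}[, 1]), got {x.shape}"
            )
        return x

    def logits(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._prepare(images, self.spec.image_size)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, images: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Per-image class probabilities ``(p_ADHD, p_control)``, order preserved."""
        x = self._prepare(images, self.spec.image_size)
        probs = [softmax(self.logits(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(probs) if probs else np.empty((0, self.spec.n_classes))

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Hard labels; exact probability ties break toward control."""
        p = self.predict_proba(images)
        return np.where(p[:, ADHD] > p[:, CONTROL], ADHD, CONTROL)

    # -- training ---------------------------------------------------------

    def fit(self, images: np.ndarray, labels: np.ndarray,
            config: TrainConfig | None = None) -> "AccelCNN":
        """Mini-batch SGD with momentum on the softmax cross-entropy.

        ``labels`` are class indices (0 = ADHD, 1 = control).  Both classes
        must be present.  Per-epoch mean loss and training accuracy are
        appended to :attr:`train_log`.  Fully reproducible given
        ``config.seed`` (batch order is the only randomness).
        """
        config = config or TrainConfig()
        x = self._prepare(images, self.spec.image_size)
        y = np.asarray(labels, dtype=np.int64)
        if y.shape != (x.shape[0],):
            raise ValueError("labels must be one class index per image")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training stack must contain both classes")

        weights = np.ones(self.spec.n_classes, dtype=np.float32)
        if config.class_weighting:
            counts = np.bincount(y, minlength=self.spec.n_classes).astype(np.float64)
            w = counts.sum() / np.maximum(counts, 1) / self.spec.n_classes
            weights = w.astype(np.float32)

        rng = np.random.default_rng(config.seed)
        velocity = {}
        n = len(x)
        for epoch in range(config.epochs):
            order = rng.permutation(n) if config.shuffle else np.arange(n)
            total_loss = 0.0
            correct = 0
            for lo in range(0, n, config.batch_size):
                idx = order[lo : lo + config.batch_size]
                xb, yb = x[idx], y[idx]
                z = xb
                for layer in self.layers:
                    z = layer.forward(z, True)
                p = softmax(z)
                wb = weights[yb]
                eps = 1e-12
                total_loss += float(-(wb * np.log(p[np.arange(len(yb)), yb] + eps)).sum())
                correct += int((p.argmax(axis=1) == yb).sum())
                # softmax + cross-entropy gradient, per-sample weighted
                dz = p.astype(np.float32)
                dz[np.arange(len(yb)), yb] -= 1.0
                dz *= (wb / len(yb))[:, None]
                g = dz
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                for li, layer in enumerate(self.layers):
                    for name, arr, gname in layer.params():
                        key = (li, name)
                        grad = getattr(layer, gname)
                        v = velocity.get(key)
                        if v is None:
                            v = np.zeros_like(arr)
                            velocity[key] = v
                        v *= config.momentum
                        v -= config.learning_rate * grad
                        arr += v
            self.train_log.append(
                {"epoch": epoch, "loss": total_loss / n, "accuracy": correct / n}
            )
        return self


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> AccelCNN:
    """Construct an untrained classifier with seed-deterministic initial weights."""
    return AccelCNN(spec, seed)
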