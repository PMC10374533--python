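"""Multi-label spectrogram CNN: 512x128 log-Mel input -> 16 sigmoid scores/class.

Architecture
------------
Five identically structured 2-D blocks; block ``b`` holds two 3x3
convolutions with the same filter count (32, 64, 96, 128, 160 at full size)
and ReLU activations, followed by non-overlapping 2x2 max pooling.  Every
convolution is preceded by a batch-normalization layer.  Five poolings halve
both axes five times, so the 512x128 input reaches a 16x4 map with 160
channels; that map is reshaped to a 16-step sequence of 640 features and run
through two kernel-size-1 1-D convolutions (256 filters each, batch norm +
ReLU), then a final kernel-size-1 convolution with sigmoid activation — one
score per class for each of the 16 time columns (each covering 5/16 s).

Training minimizes binary cross-entropy summed over columns, classes and the
batch with the Adam optimizer.  "Same" padding is used throughout: with
valid padding five 2x2 poolings could not produce the 16 output columns.

The network is written directly on NumPy (im2col convolutions, explicit
backward passes); everything is float32 and deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from botopam.annotations import N_COLUMNS, TARGET_CLASSES
from botopam.augmentation import AugmentPolicy, oversample, transform

DTYPE = np.float32


@dataclass(frozen=True)
class NetworkSpec:
    """Hyper-structure of the classifier.

    ``block_filters`` at full size is ``(32, 64, 96, 128, 160)``; the
    scaled-down configuration used for desk experiments is
    ``(8, 16, 24, 32, 40)`` with a 64-wide head.
    """

    n_classes: int = 3
    block_filters: tuple[int, ...] = (32, 64, 96, 128, 160)
    convs_per_block: int = 2
    head_filters: int = 256
    input_shape: tuple[int, int] = (512, 128)

    def __post_init__(self) -> None:
        if len(self.block_filters) != 5:
            raise ValueError("the architecture uses exactly 5 blocks")
        h, w = self.input_shape
        if h % 32 or w % 32:
            raise ValueError("input height and width must be divisible by 2**5")

    @property
    def n_time_steps(self) -> int:
        return self.input_shape[0] // 2 ** len(self.block_filters)

    @property
    def head_input_width(self) -> int:
        return (self.input_shape[1] // 2 ** len(self.block_filters)) * self.block_filters[-1]

    @classmethod
    def scaled_down(cls, n_classes: int = 3) -> "NetworkSpec":
        return cls(n_classes=n_classes, block_filters=(8, 16, 24, 32, 40), head_filters=64)


# ---------------------------------------------------------------------------
# layers (NHWC layout)
# ---------------------------------------------------------------------------


class _Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(_Layer):
    """3x3 convolution, 'same' zero padding, stride 1.

    Implemented as cache-blocked im2col GEMMs: each (sample, row-chunk)
    gathers a small column buffer sized to stay L2-resident, so the gather
    and the matmul both run at cache speed instead of memory speed — the
    dominant cost on bandwidth-limited hosts.  The backward pass rebuilds
    the same chunks (recompute beats caching hundreds of MB of columns).
    """

    _COL_BUDGET = 300_000  # column-buffer elements kept cache-resident

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = 9 * c_in
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.params["W"] = (rng.standard_normal((fan_in, c_out)) * scale).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.c_in, self.c_out = c_in, c_out

    def _chunk_rows(self, h: int, w: int) -> int:
        rows = max(8, self._COL_BUDGET // (w * 9 * self.c_in))
        return min(h, rows)

    @staticmethod
    def _gather(col: np.ndarray, xp_n: np.ndarray, h0: int, rows: int, w: int) -> None:
        k = 0
        for i in range(3):
            for j in range(3):
                col[:, :, k, :] = xp_n[h0 + i : h0 + i + rows, j : j + w, :]
                k += 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, h, w, c = x.shape
        xp = np.zeros((b, h + 2, w + 2, c), dtype=DTYPE)
        xp[:, 1:-1, 1:-1, :] = x
        if training:
            self._cache = xp
        wm, bias = self.params["W"], self.params["b"]
        out = np.empty((b, h, w, self.c_out), dtype=DTYPE)
        rows = self._chunk_rows(h, w)
        col = np.empty((rows, w, 9, c), dtype=DTYPE)
        for n in range(b):
            for h0 in range(0, h, rows):
                r = min(rows, h - h0)
                cbuf = col if r == rows else col[:r]
                self._gather(cbuf, xp[n], h0, r, w)
                out[n, h0 : h0 + r] = (
                    cbuf.reshape(r * w, 9 * c) @ wm + bias
                ).reshape(r, w, self.c_out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._cache
        b = xp.shape[0]
        h, w = xp.shape[1] - 2, xp.shape[2] - 2
        c = self.c_in
        wm = self.params["W"]
        dw = np.zeros_like(wm)
        dxp = np.zeros_like(xp)
        rows = self._chunk_rows(h, w)
        col = np.empty((rows, w, 9, c), dtype=DTYPE)
        for n in range(b):
            for h0 in range(0, h, rows):
                r = min(rows, h - h0)
                cbuf = col if r == rows else col[:r]
                self._gather(cbuf, xp[n], h0, r, w)
                dflat = dout[n, h0 : h0 + r].reshape(r * w, self.c_out)
                dw += cbuf.reshape(r * w, 9 * c).T @ dflat
                dcol = (dflat @ wm.T).reshape(r, w, 9, c)
                k = 0
                for i in range(3):
                    for j in range(3):
                        dxp[n, h0 + i : h0 + i + r, j : j + w, :] += dcol[:, :, k, :]
                        k += 1
        self.grads["W"] = dw
        self.grads["b"] = dout.reshape(-1, self.c_out).sum(axis=0)
        self._cache = None
        return dxp[:, 1:-1, 1:-1, :]


class Dense(_Layer):
    """Kernel-size-1 convolution over a sequence == per-step dense layer."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / c_in)
        self.params["W"] = (rng.standard_normal((c_in, c_out)) * scale).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        flat_x = x.reshape(-1, x.shape[-1])
        flat_d = dout.reshape(-1, dout.shape[-1])
        self.grads["W"] = flat_x.T @ flat_d
        self.grads["b"] = flat_d.sum(axis=0)
        self._cache = None
        return dout @ self.params["W"].T


class BatchNorm(_Layer):
    """Per-channel batch normalization over all leading axes (NHWC or NTC)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c = x.shape[-1]
        flat = x.reshape(-1, c)
        if training:
            n = flat.shape[0]
            # single-pass sufficient statistics (einsum fuses the square)
            s1 = np.einsum("nc->c", flat, dtype=np.float64)
            s2 = np.einsum("nc,nc->c", flat, flat, dtype=np.float64)
            mean = (s1 / n).astype(DTYPE)
            var = np.maximum(s2 / n - (s1 / n) ** 2, 0.0).astype(DTYPE)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        x_hat = x - mean
        x_hat *= inv_std
        if training:
            self._cache = (x_hat, inv_std)
        out = x_hat * self.params["gamma"]
        out += self.params["beta"]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_hat, inv_std = self._cache
        c = dout.shape[-1]
        dflat = dout.reshape(-1, c)
        xflat = x_hat.reshape(-1, c)
        n = dflat.shape[0]
        dgamma = np.einsum("nc,nc->c", dflat, xflat)
        dbeta = np.einsum("nc->c", dflat)
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        g = self.params["gamma"]
        # dx = gamma*inv_std * (dxhat - mean(dxhat) - x_hat*mean(dxhat*x_hat))
        dx = dout - (dbeta / n + x_hat * (dgamma / n))
        dx *= g * inv_std
        self._cache = None
        return dx.astype(DTYPE, copy=False)


class ReLU(_Layer):
    """Rectifier applied in place (safe: upstream layers never cache their
    returned activation, only their own backward state)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0, out=x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2(_Layer):
    """Non-overlapping 2x2 max pooling.

    The backward pass routes the gradient to window positions equal to the
    window maximum.  Exact float ties therefore share the full gradient;
    the common tie — rectified zeros — is harmless because the preceding
    ReLU's backward mask zeroes those paths anyway.
    """

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, h, w, c = x.shape
        m = x.reshape(b, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))
        if training:
            self._cache = (x, m)
        return m

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, m = self._cache
        up = np.repeat(np.repeat(m, 2, axis=1), 2, axis=2)
        dup = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2)
        dx = np.where(x == up, dup, DTYPE(0))
        self._cache = None
        return dx


class Reshape16(_Layer):
    """(B, 16, 4, C) feature map -> (B, 16, 4*C) sequence for the 1-D head."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        b, t, f, c = x.shape
        return x.reshape(b, t, f * c)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Summed binary cross-entropy and its gradient w.r.t. the logits.

    Uses the numerically stable form
    ``max(z, 0) - z*y + log(1 + exp(-|z|))``; the loss sums over output
    columns, classes and the batch.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = float(np.sum(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (_sigmoid(z) - y).astype(DTYPE)
    return loss, grad


class Network:
    """The assembled classifier; sequential layers with explicit backward."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[_Layer] = []
        c_in = 1
        for filters in spec.block_filters:
            for _ in range(spec.convs_per_block):
                layers.append(BatchNorm(c_in))
                layers.append(Conv2D(c_in, filters, rng))
                layers.append(ReLU())
                c_in = filters
            layers.append(MaxPool2x2())
        layers.append(Reshape16())
        c_in = spec.head_input_width
        for _ in range(2):
            layers.append(BatchNorm(c_in))
            layers.append(Dense(c_in, spec.head_filters, rng))
            layers.append(ReLU())
            c_in = spec.head_filters
        layers.append(Dense(c_in, spec.n_classes, rng))  # sigmoid applied outside
        self.layers = layers

    # -- plumbing -----------------------------------------------------------
    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield (li, name), value

    @property
    def n_params(self) -> int:
        return sum(int(v.size) for _, v in self.parameters())

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h, w = self.spec.input_shape
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (h, w):
            raise ValueError(f"expected input of shape (*, {h}, {w}), got {x.shape}")
        out = x[..., None]
        for layer in self.layers:
            out = layer.forward(out, training)
        return out  # (B, 16, n_classes) logits

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        """(B, 16, n_classes) sigmoid scores, inference mode (running BN stats)."""
        return _sigmoid(self.forward_logits(x, training=False).astype(np.float64))

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for (li, name), value in self.parameters():
            state[f"{li}.{name}"] = value
        for li, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"{li}.running_mean"] = layer.running_mean
                state[f"{li}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for (li, name), value in self.parameters():
            value[...] = state[f"{li}.{name}"]
        for li, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"{li}.running_mean"], dtype=DTYPE)
                layer.running_var = np.asarray(state[f"{li}.running_var"], dtype=DTYPE)

    def content_hash(self) -> str:
        digest = hashlib.sha256()
        for key in sorted(self.state_dict()):
            digest.update(key.encode())
            digest.update(np.ascontiguousarray(self.state_dict()[key]).tobytes())
        return digest.hexdigest()[:16]


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, network: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in network.parameters()}
        self.v = {k: np.zeros_like(v) for k, v in network.parameters()}

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for li, layer in enumerate(self.network.layers):
            for name, value in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (li, name)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
                m_hat = self.m[key] / b1c
                v_hat = self.v[key] / b2c
                value -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(DTYPE)


def train_network(
    network: Network,
    X: np.ndarray,
    Y: np.ndarray,
    labelsets=None,
    policy: AugmentPolicy | None = None,
    epochs: int = 10,
    batch_size: int = 16,
    lr: float = 1e-3,
    seed: int = 0,
) -> list[float]:
    """Train with summed BCE + Adam; returns the per-epoch loss history.

    ``X`` is ``(N, H, W)`` and ``Y`` ``(N, 16, n_classes)``.  When
    ``labelsets`` and ``policy`` are given, the index list is first expanded
    by class oversampling; each epoch the whole (expanded) training set is
    re-run through the augmentation transforms with a fresh generator state,
    then visited in a new shuffled order.  Losses are recorded as the summed
    BCE per epoch divided by the number of samples visited, so histories are
    comparable across oversampling policies.  Aborts if the loss goes
    non-finite.
    """
    if len(X) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(seed)
    opt = Adam(network, lr=lr)
    if labelsets is not None and policy is not None:
        indices = np.array(oversample(labelsets, policy), dtype=int)
    else:
        indices = np.arange(len(X))
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(indices)
        epoch_loss = 0.0
        for start in range(0, len(order), batch_size):
            batch_idx = order[start : start + batch_size]
            xb = X[batch_idx].astype(DTYPE)
            if policy is not None:
                xb = np.stack([transform(x, policy, rng) for x in xb]).astype(DTYPE)
            yb = Y[batch_idx]
            logits = network.forward_logits(xb, training=True)
            loss, dlogits = bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss after {opt.t} steps"
                )
            network.backward(dlogits)
            opt.step()
            epoch_loss += loss
        history.append(epoch_loss / len(order))
    return history


def save_checkpoint(path, network: Network) -> None:
    """Single-file checkpoint: serialized weights + spec JSON header."""
    spec_json = json.dumps(
        {
            "n_classes": network.spec.n_classes,
            "block_filters": list(network.spec.block_filters),
            "convs_per_block": network.spec.convs_per_block,
            "head_filters": network.spec.head_filters,
            "input_shape": list(network.spec.input_shape),
            "model_version": network.content_hash(),
        }
    )
    np.savez(path, __spec__=np.frombuffer(spec_json.encode(), dtype=np.uint8),
             **network.state_dict())


def load_checkpoint(path) -> Network:
    data = np.load(path)
    spec_dict = json.loads(bytes(data["__spec__"]).decode())
    spec = NetworkSpec(
        n_classes=spec_dict["n_classes"],
        block_filters=tuple(spec_dict["block_filters"]),
        convs_per_block=spec_dict["convs_per_block"],
        head_filters=spec_dict["head_filters"],
        input_shape=tuple(spec_dict["input_shape"]),
    )
    network = Network(spec, seed=0)
    network.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return network


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class SpectrogramCNN:
    """sklearn-style multi-label classifier over 512x128 log-Mel matrices.

    Parameters
    ----------
    n_classes, block_filters, head_filters:
        Architecture knobs (see :class:`NetworkSpec`).
    epochs, batch_size, lr, seed:
        Training configuration; ``seed`` drives weight init, shuffling and
        augmentation draws, making ``fit`` deterministic.
    augment:
        Optional :class:`~botopam.augmentation.AugmentPolicy`; when set,
        ``fit`` oversamples under-represented classes (if ``labelsets`` is
        passed) and regenerates augmented inputs per epoch.

    Attributes (after ``fit``)
    --------------------------
    network_:     the trained :class:`Network`
    history_:     per-epoch mean summed-BCE loss
    n_params_:    total trainable parameter count
    model_version_: content hash of the trained weights
    """

    def __init__(
        self,
        n_classes: int = 3,
        block_filters: tuple[int, ...] = (32, 64, 96, 128, 160),
        head_filters: int = 256,
        epochs: int = 10,
        batch_size: int = 16,
        lr: float = 1e-3,
        seed: int = 0,
        augment: AugmentPolicy | None = None,
    ) -> None:
        self.n_classes = n_classes
        self.block_filters = block_filters
        self.head_filters = head_filters
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed
        self.augment = augment

    # sklearn protocol ------------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_classes": self.n_classes,
            "block_filters": self.block_filters,
            "head_filters": self.head_filters,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "lr": self.lr,
            "seed": self.seed,
            "augment": self.augment,
        }

    def set_params(self, **params) -> "SpectrogramCNN":
        valid = self.get_params()
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=DTYPE)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError("X must be (n_segments, 512, 128)")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray, labelsets=None) -> "SpectrogramCNN":
        """Train on mel matrices ``X`` (N, 512, 128) and targets ``y``.

        ``y`` may be column-resolved ``(N, 16, n_classes)`` or segment-level
        ``(N, n_classes)``; segment-level targets are broadcast to all 16
        output columns.
        """
        X = self._validate_X(X)
        spec = NetworkSpec(
            n_classes=self.n_classes,
            block_filters=tuple(self.block_filters),
            head_filters=self.head_filters,
            input_shape=(X.shape[1], X.shape[2]),
        )
        n_steps = spec.n_time_steps  # 16 for the standard 512-frame input
        y = np.asarray(y, dtype=DTYPE)
        if y.ndim == 2:
            y = np.repeat(y[:, None, :], n_steps, axis=1)
        if y.shape != (len(X), n_steps, self.n_classes):
            raise ValueError(
                f"y must be (n, {n_steps}, {self.n_classes}), got {y.shape}"
            )
        self.network_ = Network(spec, seed=self.seed)
        self.n_params_ = self.network_.n_params
        self.history_ = train_network(
            self.network_,
            X,
            y,
            labelsets=labelsets,
            policy=self.augment,
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            seed=self.seed,
        )
        self.model_version_ = self.network_.content_hash()
        return self

    def predict_proba(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Per-column sigmoid scores, shape (n_segments, 16, n_classes)."""
        if not hasattr(self, "network_"):
            raise RuntimeError("SpectrogramCNN is not fitted")
        X = self._validate_X(X)
        out = [
            self.network_.predict_scores(X[i : i + batch_size])
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Segment-level multi-label prediction by thresholding Q75 scores."""
        from botopam.evaluation import q75_summarize

        scores = self.predict_proba(X)
        q75 = np.stack([
            [q75_summarize(scores[i, :, c]) for c in range(scores.shape[2])]
            for i in range(len(scores))
        ])
        return (q75 >= threshold).astype(int)
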