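"""The spectrogram-image CNN classifier.

Architecture (fixed, layer by layer):

    [Conv 32 @3×3 (linear, valid) → LeakyReLU(0.1) → MaxPool 2×2 (same) → Dropout 0.25]
    [Conv 64 @3×3 → LeakyReLU(0.1) → MaxPool 2×2 → Dropout 0.25]
    [Conv 128 @3×3 → LeakyReLU(0.1) → MaxPool 2×2 → Dropout 0.4]
    Flatten → Dense 128 (linear) → LeakyReLU(0.1) → Dropout 0.3
    → Dense n_classes → softmax

trained with Adam on categorical cross-entropy.  The implementation is plain
numpy (float32, im2col convolutions backed by BLAS matmuls) with hand-written
backpropagation: it is exactly deterministic given the seed — initialization,
batch shuffling and dropout masks all come from one seeded Generator — which
is a property no GPU framework guarantees.

Convolutions use valid padding; only the pooling layers are same-padded
(ceil-division output size, pad with −inf), so a 150×150 input shrinks to a
17×17×128 feature map (150→148→74→72→36→34→17).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ModelConfig", "TrainReport", "CNN", "build_model", "train",
           "predict", "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    input_size: tuple[int, int, int] = (150, 150, 3)
    conv_filters: tuple[int, ...] = (32, 64, 128)
    kernel: tuple[int, int] = (3, 3)
    leaky_alpha: float = 0.1
    pool: tuple[int, int] = (2, 2)
    dropouts: tuple[float, ...] = (0.25, 0.25, 0.4)
    dense_units: int = 128
    dense_dropout: float = 0.3
    n_classes: int = 2
    train_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.leaky_alpha <= 0:
            raise ValueError("leaky_alpha must be > 0")
        if len(self.dropouts) != len(self.conv_filters):
            raise ValueError("one dropout rate per conv block required")
        for d in (*self.dropouts, self.dense_dropout):
            if not 0 <= d < 1:
                raise ValueError("dropout rates must lie in [0, 1)")


@dataclass
class TrainReport:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    seed: int = 0

    def to_tsv(self, path: str) -> str:
        import pandas as pd

        cols = {"epoch": np.arange(1, len(self.loss) + 1),
                "loss": self.loss, "accuracy": self.accuracy}
        if self.val_loss:
            cols["val_loss"] = self.val_loss
            cols["val_accuracy"] = self.val_accuracy
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
        return path


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs; everything float32)
# ---------------------------------------------------------------------------

class _Conv:
    name = "conv"

    def __init__(self, kh, kw, cin, cout, rng):
        fan_in = kh * kw * cin
        self.w = (rng.standard_normal((kh, kw, cin, cout))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.kh, self.kw = kh, kw

    @property
    def params(self):
        return [self.w, self.b]

    def _im2col(self, x):
        # (B, H', W', C, kh, kw) → (B, H', W', kh, kw, C)
        win = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))

    def forward(self, x, train, rng):
        cols = self._im2col(x)
        b, ho, wo = cols.shape[:3]
        flat = cols.reshape(b * ho * wo, -1)
        wr = self.w.reshape(-1, self.w.shape[-1])  # (kh·kw·C, F), patch order
        out = flat @ wr + self.b
        if train:
            self._x_shape, self._flat = x.shape, flat
        return out.reshape(b, ho, wo, -1)

    def backward(self, dy):
        b, ho, wo, cout = dy.shape
        dyf = dy.reshape(-1, cout)
        self.dw = (self._flat.T @ dyf).reshape(self.w.shape)
        self.db = dyf.sum(axis=0)
        # dx = full-correlation of dy with the flipped kernel
        pad = ((0, 0), (self.kh - 1, self.kh - 1),
               (self.kw - 1, self.kw - 1), (0, 0))
        dyp = np.pad(dy, pad)
        win = sliding_window_view(dyp, (self.kh, self.kw), axis=(1, 2))
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        flat = cols.reshape(cols.shape[0] * cols.shape[1] * cols.shape[2], -1)
        wflip = self.w[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh, kw, F, C)
        dx = flat @ wflip.reshape(-1, wflip.shape[-1])
        hin, win_ = self._x_shape[1], self._x_shape[2]
        del self._flat
        return dx.reshape(self._x_shape[0], hin, win_, -1)

    @property
    def grads(self):
        return [self.dw, self.db]


class _LeakyReLU:
    name = "leaky_relu"
    params = ()
    grads = ()

    def __init__(self, alpha):
        self.alpha = np.float32(alpha)

    def forward(self, x, train, rng):
        out = np.where(x > 0, x, self.alpha * x)
        if train:
            self._pos = x > 0
        return out

    def backward(self, dy):
        return np.where(self._pos, dy, self.alpha * dy)


class _MaxPool:
    """2×2, stride 2, same padding: output size ceil(H/2), −inf pad."""

    name = "maxpool"
    params = ()
    grads = ()

    def forward(self, x, train, rng):
        b, h, w, c = x.shape
        ph, pw = (-h) % 2, (-w) % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)),
                       constant_values=-np.inf)
        h2, w2 = x.shape[1] // 2, x.shape[2] // 2
        win = x.reshape(b, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(b, h2, w2, 4, c)
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx, self._in_shape, self._pad = idx, (b, h, w, c), (ph, pw)
        return out

    def backward(self, dy):
        b, h, w, c = self._in_shape
        ph, pw = self._pad
        h2, w2 = (h + ph) // 2, (w + pw) // 2
        dwin = np.zeros((b, h2, w2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dwin, self._idx[:, :, :, None, :],
                          dy[:, :, :, None, :], axis=3)
        dx = dwin.reshape(b, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dx = dx.reshape(b, h2 * 2, w2 * 2, c)
        return dx[:, :h, :w, :]


class _Dropout:
    name = "dropout"
    params = ()
    grads = ()

    def __init__(self, rate):
        self.rate = rate
        self._mask = None

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        self._mask = (rng.random(x.shape, dtype=np.float32) >= self.rate)
        self._mask = self._mask.astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _Flatten:
    name = "flatten"
    params = ()
    grads = ()

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dense:
    name = "dense"

    def __init__(self, nin, nout, rng):
        self.w = (rng.standard_normal((nin, nout))
                  * np.sqrt(2.0 / nin)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x, train, rng):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        del self._x
        return dy @ self.w.T

    @property
    def grads(self):
        return [self.dw, self.db]


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class CNN:
    """The stacked layers plus an Adam state; see module docstring."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        kh, kw = config.kernel
        h, w, c = config.input_size
        self.layers: list = []
        cin = c
        for nf, drop in zip(config.conv_filters, config.dropouts):
            self.layers += [_Conv(kh, kw, cin, nf, rng),
                            _LeakyReLU(config.leaky_alpha),
                            _MaxPool(), _Dropout(drop)]
            h, w = -((h - kh + 1) // -2), -((w - kw + 1) // -2)
            if h < 1 or w < 1:
                raise ValueError(
                    f"input {config.input_size} too small for "
                    f"{len(config.conv_filters)} conv/pool blocks")
            cin = nf
        self.layers.append(_Flatten())
        self.layers.append(_Dense(h * w * cin, config.dense_units, rng))
        self.layers.append(_LeakyReLU(config.leaky_alpha))
        self.layers.append(_Dropout(config.dense_dropout))
        self.layers.append(_Dense(config.dense_units, config.n_classes, rng))
        self._rng = rng
        self._adam_t = 0
        self._adam_m = [np.zeros_like(p) for p in self.parameters()]
        self._adam_v = [np.zeros_like(p) for p in self.parameters()]

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train, self._rng)
        return x

    def backward(self, dlogits):
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(self.parameters(), self.gradients(),
                              self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)

    def output_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Per-layer output shapes (audit helper), batch dimension omitted."""
        x = np.zeros((1,) + tuple(self.config.input_size), dtype=np.float32)
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, False, self._rng)
            shapes.append((layer.name, tuple(x.shape[1:])))
        return shapes


def build_model(config: ModelConfig) -> CNN:
    return CNN(config)


def train(model: CNN, images: np.ndarray, labels: np.ndarray,
          config: ModelConfig | None = None,
          validation: tuple[np.ndarray, np.ndarray] | None = None,
          ) -> tuple[CNN, TrainReport]:
    """Minimize categorical cross-entropy for exactly ``train_epochs`` passes.

    ``images``: (N, H, W, 3) floats in [0, 1]; ``labels``: (N,) integer class
    indices.  An optional ``validation`` set ``(images, labels)`` is scored
    (never trained on) after each pass.  Exactly reproducible for a given
    config seed.
    """
    config = config or model.config
    x = np.asarray(images, dtype=np.float32)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("one label per image required")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    n = x.shape[0]
    onehot = np.zeros((n, config.n_classes), dtype=np.float32)
    onehot[np.arange(n), y] = 1.0

    shuffle_rng = np.random.default_rng(config.seed + 1)
    report = TrainReport(seed=config.seed)
    for _ in range(config.train_epochs):
        order = shuffle_rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], onehot[idx]
            logits = model.forward(xb, train=True)
            probs = _softmax(logits.astype(np.float64))
            eps = 1e-12
            losses.append(float(-(yb * np.log(probs + eps)).sum() / len(idx)))
            correct += int((probs.argmax(1) == y[idx]).sum())
            dlogits = ((probs - yb) / len(idx)).astype(np.float32)
            model.backward(dlogits)
            model.adam_step(config.learning_rate)
        report.loss.append(float(np.mean(losses)))
        report.accuracy.append(correct / n)
        if validation is not None:
            xv, yv = validation
            probs = predict(model, xv)
            eps = 1e-12
            report.val_loss.append(float(
                -np.log(probs[np.arange(len(yv)), yv] + eps).mean()))
            report.val_accuracy.append(float((probs.argmax(1) == yv).mean()))
    return model, report


def predict(model: CNN, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class-probability matrix; rows sum to 1."""
    x = np.asarray(images, dtype=np.float32)
    out = []
    for start in range(0, x.shape[0], batch_size):
        logits = model.forward(x[start:start + batch_size], train=False)
        out.append(_softmax(logits.astype(np.float64)))
    return np.vstack(out)


def save_model(model: CNN, path: str) -> str:
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    np.savez(path, config=json.dumps(asdict(model.config)), **arrays)
    return path


def load_model(path: str) -> CNN:
    with np.load(path, allow_pickle=False) as archive:
        cfg_raw = json.loads(str(archive["config"]))
        for key in ("input_size", "conv_filters", "kernel", "pool", "dropouts"):
            cfg_raw[key] = tuple(cfg_raw[key])
        model = CNN(ModelConfig(**cfg_raw))
        for i, p in enumerate(model.parameters()):
            p[...] = archive[f"p{i}"]
    return model
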