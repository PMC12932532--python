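"""Positional-encoding strategies for the transformer input.

Three strategies behind one interface, all combined with the input by
addition (Z_i = inputE(x_i) + PE(i)):

* **naive** — the normalized sequence index (i / (L-1)), a single value per
  position broadcast over channels. Deterministic in the length alone.
* **sinusoidal** — the classic sine/cosine table of depth ``d_model``. The
  input (one channel) is first mapped by a learned pointwise linear
  embedding to ``d_model`` channels so the addition is well-typed; the
  table is either generated at the full sequence length (default) or a
  fixed 64-row table linearly resampled to the sequence length
  (``tile64`` mode).
* **autoencoder** — a learnable, content-aware encoding: a 1-D
  convolutional autoencoder (two conv layers with ReLU, filters 132 and
  64, dropout 0.1 between them, and a transposed-convolution
  reconstruction layer) maps the signal to a same-shaped embedding that is
  added element-wise. Unlike the static variants it depends on the signal
  content, not only on the index. It trains jointly with the classifier by
  default, or can be pretrained on its own reconstruction objective and
  frozen.
"""

from __future__ import annotations

import numpy as np

from .config import InvalidConfigError, PosencConfig
from .nn.layers import (
    F32,
    Conv1D,
    ConvTranspose1D,
    Dense,
    Dropout,
    Layer,
    ReLU,
)

__all__ = [
    "naive_encoding",
    "sinusoidal_encoding",
    "build_autoencoder_pe",
    "build_combiner",
    "combine",
    "IdentityCombiner",
    "NaiveCombiner",
    "SinusoidalCombiner",
    "AutoencoderCombiner",
]


def naive_encoding(length: int) -> np.ndarray:
    """Normalized sequence index: value at position i is i/(length-1), so
    the encoding rises strictly from 0 to 1. length == 1 yields [0]."""
    if length <= 0:
        raise ValueError("length must be >= 1")
    if length == 1:
        return np.zeros(1)
    return np.arange(length) / (length - 1)


def sinusoidal_encoding(length: int, d_model: int) -> np.ndarray:
    """Sine/cosine positional table of shape (length, d_model):
    PE(pos, 2i) = sin(pos / 10000^(2i/d_model)),
    PE(pos, 2i+1) = cos(pos / 10000^(2i/d_model))."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if d_model <= 0 or d_model % 2:
        raise ValueError("d_model must be a positive even number")
    pos = np.arange(length)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.empty((length, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class _Combiner:
    """Embedding front-end: maps the raw window (B, L, 1) to the encoded
    sequence Z entering the encoder stack, and back-propagates into its own
    trainable parts."""

    layers: list[Layer] = []

    def output_channels(self, c_in: int) -> int:
        return c_in

    def forward(self, x: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dz: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class IdentityCombiner(_Combiner):
    """strategy=none: identity input embedding, no positional term."""

    def forward(self, x, *, training=False, rng=None):
        return x

    def backward(self, dz):
        return dz


class NaiveCombiner(_Combiner):
    """Adds the normalized index to every channel; no parameters."""

    def forward(self, x, *, training=False, rng=None):
        pe = naive_encoding(x.shape[1]).astype(F32)
        return x + pe[None, :, None]

    def backward(self, dz):
        return dz


class SinusoidalCombiner(_Combiner):
    """Learned pointwise projection to d_model channels plus the static
    sine/cosine table."""

    def __init__(self, config: PosencConfig, c_in: int,
                 rng: np.random.Generator) -> None:
        self.config = config
        self.proj = Dense(c_in, config.d_model, rng)
        self.layers = [self.proj]

    def output_channels(self, c_in: int) -> int:
        return self.config.d_model

    def _table(self, length: int) -> np.ndarray:
        cfg = self.config
        if cfg.sinusoidal_mode == "tile64":
            base = sinusoidal_encoding(cfg.length, cfg.d_model)
            src = np.linspace(0, cfg.length - 1, num=length)
            cols = [np.interp(src, np.arange(cfg.length), base[:, j])
                    for j in range(cfg.d_model)]
            return np.stack(cols, axis=1)
        return sinusoidal_encoding(length, cfg.d_model)

    def forward(self, x, *, training=False, rng=None):
        z = self.proj.forward(x, training=training, rng=rng)
        return (z + self._table(x.shape[1]).astype(F32)).astype(F32)

    def backward(self, dz):
        return self.proj.backward(dz)


class AutoencoderCombiner(_Combiner):
    """Content-aware learnable encoding: Z = x + AE(x) element-wise.

    The autoencoder preserves shape for any input length (stride-1 'same'
    convolutions), so the addition is always well-typed."""

    def __init__(self, config: PosencConfig, c_in: int,
                 rng: np.random.Generator) -> None:
        f1, f2 = config.ae_filters
        k = config.ae_kernel
        self.conv1 = Conv1D(c_in, f1, k, rng)
        self.relu1 = ReLU()
        self.drop = Dropout(config.ae_dropout)
        self.conv2 = Conv1D(f1, f2, k, rng)
        self.relu2 = ReLU()
        self.convt = ConvTranspose1D(f2, c_in, k, rng)
        self._seq: list[Layer] = [self.conv1, self.relu1, self.drop,
                                  self.conv2, self.relu2, self.convt]
        self.layers = [self.conv1, self.conv2, self.convt]
        self.frozen = False

    def encode(self, x, *, training=False, rng=None):
        h = x
        for layer in self._seq:
            h = layer.forward(h, training=training, rng=rng)
        return h

    def forward(self, x, *, training=False, rng=None):
        training = training and not self.frozen
        return (x + self.encode(x, training=training, rng=rng)).astype(F32)

    def backward(self, dz):
        d = dz
        for layer in reversed(self._seq):
            d = layer.backward(d)
        return dz + d

    def freeze(self) -> None:
        self.frozen = True
        for layer in self.layers:
            layer.trainable = False

    def pretrain(self, X: np.ndarray, epochs: int, lr: float,
                 batch_size: int, rng: np.random.Generator) -> list[float]:
        """Self-supervised reconstruction fitting (targets = inputs), then
        freeze. Returns the per-epoch mean squared reconstruction error."""
        from .nn.optim import AdamW

        opt = AdamW(self.layers, lr=lr, weight_decay=0.0)
        history = []
        n = X.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, batch_size):
                xb = X[order[s:s + batch_size]]
                out = self.encode(xb, training=True, rng=rng)
                diff = out - xb
                losses.append(float(np.mean(diff * diff)))
                opt.zero_grads()
                d = (2.0 * diff / diff.size).astype(F32)
                for layer in reversed(self._seq):
                    d = layer.backward(d)
                opt.step()
            history.append(float(np.mean(losses)))
        self.freeze()
        return history


def build_autoencoder_pe(config: PosencConfig,
                         rng: np.random.Generator | None = None,
                         c_in: int = 1) -> AutoencoderCombiner:
    """Build the convolutional-autoencoder positional-encoding component."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(0)
    return AutoencoderCombiner(config, c_in, rng)


def build_combiner(config: PosencConfig, rng: np.random.Generator,
                   c_in: int = 1) -> _Combiner:
    config.validate()
    if config.strategy == "none":
        return IdentityCombiner()
    if config.strategy == "naive":
        return NaiveCombiner()
    if config.strategy == "sinusoidal":
        return SinusoidalCombiner(config, c_in, rng)
    if config.strategy == "autoencoder":
        return AutoencoderCombiner(config, c_in, rng)
    raise InvalidConfigError(f"unknown strategy {config.strategy!r}")


def combine(input_sequence: np.ndarray, encoding: np.ndarray | None,
            mode: str = "add") -> np.ndarray:
    """Add a positional encoding to an input batch (B, L, C).

    ``encoding`` may be a length-L vector (broadcast over channels) or an
    (L, C) matrix; ``mode='add'`` is the only combination rule."""
    if mode != "add":
        raise ValueError("only additive combination is supported")
    x = np.asarray(input_sequence)
    if encoding is None:
        return x
    pe = np.asarray(encoding)
    if pe.ndim == 1:
        pe = pe[:, None]
    if pe.shape[0] != x.shape[1] or (pe.shape[1] not in (1, x.shape[2])):
        raise ValueError(f"encoding {pe.shape} incompatible with input {x.shape}")
    return x + pe[None]
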