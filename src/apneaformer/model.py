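"""Transformer-encoder classifier for per-second apnea detection.

Architecture (best random-search configuration): positional-encoding
front-end -> 6 encoder blocks -> global average pooling -> dense MLP head
with a 30-unit sigmoid output, one probability per second of the 30-s
window. Each encoder block has two sub-layers, each enclosed by a residual
connection and a *subsequent* normalization layer (post-norm):

  1. multi-head self-attention (4 heads of size 256) -> dropout
  2. pointwise convolution (128 filters, ReLU) -> dropout -> pointwise
     convolution restoring the channel count

The default pooling averages over the channel axis, leaving one feature
per time step for the MLP head — required for the per-second objective
when the encoded sequence has few channels; pooling over the time axis
(one feature per channel) is available via ``pool_axis="time"``.

The estimator follows the scikit-learn protocol: ``fit(X, y)`` on a batch
of windows X (n, sequence_length, 1) with per-second labels y (n, 30),
then ``predict_proba`` / ``predict``. Training uses class-weighted binary
cross-entropy and AdamW with the constant-then-exponential-decay schedule.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .config import InvalidConfigError, ModelConfig, PosencConfig, TrainConfig
from .nn.layers import (
    F32,
    Dense,
    Dropout,
    GlobalAveragePooling,
    Layer,
    LayerNorm,
    MultiHeadSelfAttention,
    ReLU,
)
from .nn.losses import sigmoid, weighted_bce_with_logits
from .nn.optim import AdamW
from .posenc import AutoencoderCombiner, build_combiner

__all__ = [
    "EncoderBlock",
    "TransformerNet",
    "ApneaTransformerClassifier",
    "build_encoder_block",
    "build_classifier",
    "predict_seconds",
]


class EncoderBlock:
    """One post-norm transformer encoder block; preserves (B, L, C)."""

    def __init__(self, c_in: int, num_heads: int, head_size: int,
                 ff_hidden: int, dropout: float, norm_axis: str,
                 rng: np.random.Generator) -> None:
        self.attn = MultiHeadSelfAttention(c_in, num_heads, head_size, rng)
        self.drop1 = Dropout(dropout)
        self.norm1 = LayerNorm(c_in, axis=norm_axis)
        self.ff1 = Dense(c_in, ff_hidden, rng)   # pointwise conv, kernel 1
        self.relu = ReLU()
        self.drop2 = Dropout(dropout)
        self.ff2 = Dense(ff_hidden, c_in, rng)   # restores channel count
        self.norm2 = LayerNorm(c_in, axis=norm_axis)
        self.layers: list[Layer] = [
            self.attn, self.drop1, self.norm1,
            self.ff1, self.relu, self.drop2, self.ff2, self.norm2,
        ]

    def forward(self, x, *, training=False, rng=None):
        a = self.drop1.forward(
            self.attn.forward(x, training=training, rng=rng),
            training=training, rng=rng)
        h = self.norm1.forward(x + a, training=training, rng=rng)
        f = self.ff1.forward(h, training=training, rng=rng)
        f = self.relu.forward(f, training=training, rng=rng)
        f = self.drop2.forward(f, training=training, rng=rng)
        f = self.ff2.forward(f, training=training, rng=rng)
        return self.norm2.forward(h + f, training=training, rng=rng)

    def backward(self, dout):
        d = self.norm2.backward(dout)
        df = self.ff2.backward(d)
        df = self.drop2.backward(df)
        df = self.relu.backward(df)
        dh = d + self.ff1.backward(df)
        d1 = self.norm1.backward(dh)
        da = self.drop1.backward(d1)
        return d1 + self.attn.backward(da)


class TransformerNet:
    """The full network: combiner -> blocks -> pooling -> MLP head."""

    def __init__(self, sequence_length: int, model_config: ModelConfig,
                 rng: np.random.Generator, c_in: int = 1) -> None:
        model_config.validate()
        self.config = model_config
        self.sequence_length = sequence_length
        self.combiner = build_combiner(model_config.posenc, rng, c_in=c_in)
        c = self.combiner.output_channels(c_in)
        self.blocks = [
            EncoderBlock(c, model_config.num_heads, model_config.head_size,
                         model_config.ff_hidden, model_config.dropout,
                         model_config.norm_axis, rng)
            for _ in range(model_config.num_blocks)
        ]
        self.pool = GlobalAveragePooling(axis=model_config.pool_axis)
        n_features = sequence_length if model_config.pool_axis == "channels" else c
        self.mlp1 = Dense(n_features, model_config.mlp_units, rng)
        self.mlp_relu = ReLU()
        self.mlp_drop = Dropout(model_config.dropout)
        self.head = Dense(model_config.mlp_units, model_config.output_seconds, rng)

    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = list(self.combiner.layers)
        for b in self.blocks:
            out.extend(b.layers)
        out.extend([self.pool, self.mlp1, self.mlp_relu, self.mlp_drop, self.head])
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for l in self.layers for p in l.params.values()))

    def summary(self) -> list[tuple[str, int]]:
        """Per-component parameter counts."""
        rows = [("posenc", sum(p.size for l in self.combiner.layers
                               for p in l.params.values()))]
        for i, b in enumerate(self.blocks):
            rows.append((f"block_{i}", sum(p.size for l in b.layers
                                           for p in l.params.values())))
        rows.append(("mlp_head", sum(p.size for l in
                                     (self.mlp1, self.head)
                                     for p in l.params.values())))
        return rows

    def forward_logits(self, x: np.ndarray, *, training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        if x.shape[1] != self.sequence_length:
            raise ValueError(
                f"sequence length {x.shape[1]} != build-time length "
                f"{self.sequence_length}")
        z = self.combiner.forward(x, training=training, rng=rng)
        for block in self.blocks:
            z = block.forward(z, training=training, rng=rng)
        f = self.pool.forward(z, training=training, rng=rng)
        h = self.mlp1.forward(f, training=training, rng=rng)
        h = self.mlp_relu.forward(h, training=training, rng=rng)
        h = self.mlp_drop.forward(h, training=training, rng=rng)
        return self.head.forward(h, training=training, rng=rng)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.mlp_drop.backward(d)
        d = self.mlp_relu.backward(d)
        d = self.mlp1.backward(d)
        d = self.pool.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        self.combiner.backward(d)

    def forward_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x, training=False))


def build_encoder_block(config: ModelConfig, c_in: int = 1,
                        rng: np.random.Generator | None = None) -> EncoderBlock:
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(0)
    return EncoderBlock(c_in, config.num_heads, config.head_size,
                        config.ff_hidden, config.dropout,
                        config.norm_axis, rng)


class ApneaTransformerClassifier(BaseEstimator):
    """Per-second sleep-apnea classifier over 30-s single-lead ECG windows.

    Parameters mirror the published best configuration; reduce
    ``num_blocks``/``head_size`` and the sampling rate for desk-scale work.

    Attributes set by :meth:`fit` (trailing underscore): ``network_``,
    ``history_`` (per-epoch loss and learning rate), ``sequence_length_``,
    ``class_weights_``, ``n_parameters_``.
    """

    def __init__(
        self,
        num_blocks: int = 6,
        num_heads: int = 4,
        head_size: int = 256,
        ff_hidden: int = 128,
        mlp_units: int = 128,
        dropout: float = 0.1,
        output_seconds: int = 30,
        pool_axis: str = "channels",
        norm_axis: str = "time",
        posenc_strategy: str = "none",
        pe_d_model: int = 32,
        pe_length: int = 64,
        pe_sinusoidal_mode: str = "project",
        ae_filters: tuple[int, int] = (132, 64),
        ae_dropout: float = 0.1,
        ae_kernel: int = 7,
        ae_training_mode: str = "joint",
        ae_pretrain_epochs: int = 3,
        epochs: int = 15,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-4,
        lr_constant_epochs: int = 10,
        lr_decay: float = 0.9,
        lr_floor: float = 1e-4,
        class_weight: str | None = "balanced",
        random_state: int | None = None,
        verbose: int = 0,
    ) -> None:
        self.num_blocks = num_blocks
        self.num_heads = num_heads
        self.head_size = head_size
        self.ff_hidden = ff_hidden
        self.mlp_units = mlp_units
        self.dropout = dropout
        self.output_seconds = output_seconds
        self.pool_axis = pool_axis
        self.norm_axis = norm_axis
        self.posenc_strategy = posenc_strategy
        self.pe_d_model = pe_d_model
        self.pe_length = pe_length
        self.pe_sinusoidal_mode = pe_sinusoidal_mode
        self.ae_filters = ae_filters
        self.ae_dropout = ae_dropout
        self.ae_kernel = ae_kernel
        self.ae_training_mode = ae_training_mode
        self.ae_pretrain_epochs = ae_pretrain_epochs
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.lr_constant_epochs = lr_constant_epochs
        self.lr_decay = lr_decay
        self.lr_floor = lr_floor
        self.class_weight = class_weight
        self.random_state = random_state
        self.verbose = verbose

    # -- config plumbing ---------------------------------------------------

    def _model_config(self) -> ModelConfig:
        pe = PosencConfig(
            strategy=self.posenc_strategy,
            length=self.pe_length,
            d_model=self.pe_d_model,
            sinusoidal_mode=self.pe_sinusoidal_mode,
            ae_filters=tuple(self.ae_filters),
            ae_dropout=self.ae_dropout,
            ae_kernel=self.ae_kernel,
            ae_training_mode=self.ae_training_mode,
        )
        return ModelConfig(
            num_blocks=self.num_blocks,
            num_heads=self.num_heads,
            head_size=self.head_size,
            ff_hidden=self.ff_hidden,
            mlp_units=self.mlp_units,
            dropout=self.dropout,
            output_seconds=self.output_seconds,
            pool_axis=self.pool_axis,
            norm_axis=self.norm_axis,
            posenc=pe,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            init_lr=self.learning_rate,
            weight_decay=self.weight_decay,
            lr_constant_epochs=self.lr_constant_epochs,
            lr_decay=self.lr_decay,
            lr_floor=self.lr_floor,
            epochs=self.epochs,
            class_weighting=self.class_weight or "none",
            seed=self.random_state or 0,
        )

    @staticmethod
    def _validate_X(X: np.ndarray, seq_len: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=F32)
        if X.ndim == 2:
            X = X[..., None]
        if X.ndim != 3:
            raise ValueError(f"X must be (n, length, channels); got {X.shape}")
        if seq_len is not None and X.shape[1] != seq_len:
            raise ValueError(
                f"X sequence length {X.shape[1]} != fitted length {seq_len}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values; impute first")
        return X

    def learning_rate_at(self, epoch: int) -> float:
        """Learning rate of 1-indexed ``epoch``: constant for the first
        ``lr_constant_epochs``, then exponential decay floored at
        ``lr_floor``."""
        if epoch <= self.lr_constant_epochs:
            return self.learning_rate
        lr = self.learning_rate * self.lr_decay ** (epoch - self.lr_constant_epochs)
        return max(lr, self.lr_floor)

    # -- sklearn protocol --------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ApneaTransformerClassifier":
        from .train_eval import class_weights as _class_weights

        X = self._validate_X(X)
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError(f"y must be (n, {self.output_seconds}); got {y.shape}")
        if y.shape[1] != self.output_seconds:
            raise ValueError(
                f"y has {y.shape[1]} labels per window, expected "
                f"{self.output_seconds}")
        yf = y.astype(np.float64)

        if self.class_weight == "balanced":
            if yf.min() == yf.max():
                raise InvalidConfigError(
                    "balanced class weighting needs both classes present; "
                    "use class_weight=None or provide mixed labels")
            w = _class_weights(yf.ravel())
            w_pos, w_neg = w["weight_pos"], w["weight_neg"]
        else:
            w_pos = w_neg = 1.0
        self.class_weights_ = {"weight_pos": w_pos, "weight_neg": w_neg}

        seed = self.random_state if self.random_state is not None else 0
        init_rng = np.random.default_rng([seed, 0x5EED])
        train_rng = np.random.default_rng([seed, 0x7A15])

        self.network_ = TransformerNet(X.shape[1], self._model_config(),
                                       init_rng, c_in=X.shape[2])
        self.sequence_length_ = X.shape[1]
        self.n_parameters_ = self.network_.n_parameters()

        combiner = self.network_.combiner
        if (isinstance(combiner, AutoencoderCombiner)
                and self.ae_training_mode == "pretrained"
                and self.epochs > 0):
            combiner.pretrain(X, epochs=self.ae_pretrain_epochs,
                              lr=self.learning_rate,
                              batch_size=self.batch_size, rng=train_rng)

        opt = AdamW(self.network_.layers, lr=self.learning_rate,
                    weight_decay=self.weight_decay)
        history: dict[str, list[float]] = {"loss": [], "lr": []}
        n = X.shape[0]
        for epoch in range(1, self.epochs + 1):
            lr = self.learning_rate_at(epoch)
            opt.lr = lr
            order = train_rng.permutation(n)
            losses = []
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                logits = self.network_.forward_logits(
                    X[idx], training=True, rng=train_rng)
                loss, dlogits = weighted_bce_with_logits(
                    logits, yf[idx], w_pos, w_neg)
                losses.append(loss)
                opt.zero_grads()
                self.network_.backward(dlogits)
                opt.step()
            history["loss"].append(float(np.mean(losses)))
            history["lr"].append(lr)
            if self.verbose:
                print(f"epoch {epoch:3d}  lr {lr:.2e}  loss {history['loss'][-1]:.4f}")
        self.history_ = history
        return self

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Per-second apnea probabilities, shape (n, output_seconds)."""
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        X = self._validate_X(X, self.sequence_length_)
        out = np.empty((X.shape[0], self.output_seconds))
        for s in range(0, X.shape[0], batch_size):
            out[s:s + batch_size] = self.network_.forward_proba(X[s:s + batch_size])
        return out

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.int8)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Pooled per-second accuracy."""
        return float((self.predict(X) == np.asarray(y)).mean())


def build_classifier(config: ModelConfig, sequence_length: int,
                     rng: np.random.Generator | None = None,
                     c_in: int = 1) -> TransformerNet:
    """Build an initialized (untrained) network from a :class:`ModelConfig`."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return TransformerNet(sequence_length, config, rng, c_in=c_in)


def predict_seconds(
    classifier: ApneaTransformerClassifier,
    windows: np.ndarray,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary per-second predictions and the underlying probabilities."""
    proba = classifier.predict_proba(windows)
    return (proba >= threshold).astype(np.int8), proba
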