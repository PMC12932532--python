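"""Configuration dataclasses for the full pipeline.

Every stage (cohort simulation, preprocessing, positional encoding, model,
training) is parameterized by a small dataclass; :class:`RunConfig` nests
them all and round-trips through YAML unchanged, so a finished run is fully
described by its frozen config plus the global seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class InvalidConfigError(ValueError):
    """A configuration violates one of its invariants."""


#: AHI (apnea-hypopnea index, events per hour) intervals per severity class.
#: "none" is strictly below the conventional AHI<5 OSA threshold.
AHI_RANGES: dict[str, tuple[float, float]] = {
    "none": (0.5, 4.5),
    "mild": (5.0, 15.0),
    "moderate": (15.0, 30.0),
    "severe": (30.0, 60.0),
}

SEVERITY_ORDER = ("none", "mild", "moderate", "severe")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic overnight-ECG cohort generator.

    Defaults emulate the structure of a 30-patient clinical sleep cohort:
    7 subjects without OSA (AHI < 5), overnight recordings of 7-12 h sampled
    at 80 Hz, respiratory events of at least 10 s (mean ~26 s), an RR
    bradycardia-tachycardia modulation during events, additive noise and a
    small fraction of missing samples.
    """

    n_subjects: int = 30
    severity_quota: dict[str, int] = field(
        default_factory=lambda: {"none": 7, "mild": 8, "moderate": 8, "severe": 7}
    )
    ahi_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(AHI_RANGES)
    )
    duration_range: tuple[float, float] = (7.0, 12.0)  # hours
    fs: float = 80.0  # Hz
    event_min_s: float = 10.0
    event_mean_s: float = 26.0
    event_sigma: float = 0.5  # lognormal shape of event durations
    min_event_gap_s: float = 5.0
    rr_baseline: float = 0.9  # seconds
    rr_modulation_depth: float = 0.25  # fraction of baseline
    rr_jitter_sd: float = 0.02  # seconds, beat-to-beat noise
    noise_sd: float = 0.05  # fraction of beat peak amplitude
    nan_rate: float = 0.002  # fraction of samples set missing
    hypopnea_fraction: float = 2.0 / 3.0  # hypopnea:apnea = 2:1
    seed: int = 0

    def validate(self) -> None:
        if sum(self.severity_quota.values()) != self.n_subjects:
            raise InvalidConfigError(
                f"severity_quota sums to {sum(self.severity_quota.values())}, "
                f"expected n_subjects={self.n_subjects}"
            )
        if self.rr_baseline <= 0:
            raise InvalidConfigError("rr_baseline must be positive")
        if not (0 <= self.nan_rate < 1):
            raise InvalidConfigError("nan_rate must lie in [0, 1)")
        if self.fs <= 0:
            raise InvalidConfigError("fs must be positive")
        if self.event_min_s < 10.0:
            raise InvalidConfigError("events must last at least 10 s")
        if self.ahi_ranges["none"][1] >= 5.0:
            raise InvalidConfigError('class "none" must stay strictly below AHI 5')
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("duration_range must be a positive interval")


@dataclass
class PosencConfig:
    """Positional-encoding strategy and its hyperparameters.

    strategy:
        "none"        -- no positional information (identity embedding)
        "naive"       -- normalized sequence index in [0, 1], added per sample
        "sinusoidal"  -- fixed sine/cosine table of depth ``d_model`` combined
                         with a learned pointwise input projection
        "autoencoder" -- content-aware encoding from a 1-D convolutional
                         autoencoder with a transposed-convolution
                         reconstruction layer, added element-wise
    """

    strategy: str = "none"
    length: int = 64  # sinusoidal table rows (used by tile64 mode)
    d_model: int = 32
    sinusoidal_mode: str = "project"  # "project" | "tile64"
    ae_filters: tuple[int, int] = (132, 64)
    ae_dropout: float = 0.1
    ae_kernel: int = 7
    ae_training_mode: str = "joint"  # "joint" | "pretrained"

    def validate(self) -> None:
        if self.strategy not in ("none", "naive", "sinusoidal", "autoencoder"):
            raise InvalidConfigError(f"unknown posenc strategy {self.strategy!r}")
        if self.strategy == "sinusoidal" and self.d_model % 2:
            raise InvalidConfigError("sinusoidal d_model must be even")
        if not (0 <= self.ae_dropout < 1):
            raise InvalidConfigError("ae_dropout must lie in [0, 1)")
        if self.ae_training_mode not in ("joint", "pretrained"):
            raise InvalidConfigError("ae_training_mode must be joint or pretrained")
        if self.sinusoidal_mode not in ("project", "tile64"):
            raise InvalidConfigError("sinusoidal_mode must be project or tile64")


@dataclass
class ModelConfig:
    """Transformer-encoder classifier hyperparameters (best random-search set)."""

    num_blocks: int = 6
    num_heads: int = 4
    head_size: int = 256  # per-head key/query/value dimension
    ff_hidden: int = 128  # filters of the first feed-forward convolution
    mlp_units: int = 128
    dropout: float = 0.1
    output_seconds: int = 30
    pool_axis: str = "channels"  # "channels" (per-position features) | "time"
    norm_axis: str = "time"  # layer-norm axis: "time" | "channels"
    posenc: PosencConfig = field(default_factory=PosencConfig)

    def validate(self) -> None:
        for name in ("num_blocks", "num_heads", "head_size", "ff_hidden",
                     "mlp_units", "output_seconds"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if not (0 <= self.dropout < 1):
            raise InvalidConfigError("dropout must lie in [0, 1)")
        if self.pool_axis not in ("channels", "time"):
            raise InvalidConfigError("pool_axis must be channels or time")
        if self.norm_axis not in ("channels", "time"):
            raise InvalidConfigError("norm_axis must be channels or time")
        self.posenc.validate()


@dataclass
class TrainConfig:
    """AdamW training schedule: constant learning rate for the first 10
    epochs, then exponential decay (factor ``lr_decay`` per epoch) floored
    at ``lr_floor``."""

    batch_size: int = 32
    init_lr: float = 1e-3
    weight_decay: float = 1e-4
    lr_constant_epochs: int = 10
    lr_decay: float = 0.9
    lr_floor: float = 1e-4
    epochs: int = 15
    class_weighting: str = "balanced"  # "balanced" | "none"
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size <= 0:
            raise InvalidConfigError("batch_size must be positive")
        if self.lr_floor > self.init_lr:
            raise InvalidConfigError("lr_floor must not exceed init_lr")
        if self.class_weighting not in ("balanced", "none"):
            raise InvalidConfigError("class_weighting must be balanced or none")


@dataclass
class RunConfig:
    """Top-level pipeline configuration; serializes to/from YAML."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    window_s: float = 30.0
    normalize_scope: str = "recording"  # "recording" | "window"
    test_fraction: float = 0.2
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        self.synthetic.validate()
        self.model.validate()
        self.train.validate()
        if self.normalize_scope not in ("recording", "window"):
            raise InvalidConfigError("normalize_scope must be recording or window")


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in fields:
            raise InvalidConfigError(f"unknown config key {key!r} for {cls.__name__}")
        f = fields[key]
        if dataclasses.is_dataclass(f.type) or f.type in (
            SyntheticConfig, PosencConfig, ModelConfig, TrainConfig,
        ) or f.name in ("synthetic", "model", "train", "posenc"):
            sub_cls = {"synthetic": SyntheticConfig, "model": ModelConfig,
                       "train": TrainConfig, "posenc": PosencConfig}[f.name]
            value = _from_plain(sub_cls, value)
        elif isinstance(value, list):
            value = tuple(value) if f.name != "severity_quota" else value
        elif isinstance(value, dict) and f.name == "ahi_ranges":
            value = {k: tuple(v) for k, v in value.items()}
        kwargs[key] = value
    return cls(**kwargs)


def config_to_dict(config: Any) -> dict[str, Any]:
    return _to_plain(config)


def run_config_from_dict(data: dict[str, Any]) -> RunConfig:
    cfg = _from_plain(RunConfig, data)
    cfg.validate()
    return cfg


def save_run_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return run_config_from_dict(data)
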