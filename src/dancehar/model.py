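"""The convolutional window classifier.

The network consumes a (9·|locations|) × 100 matrix — one second of
stacked 9-channel IMU data — and predicts one activity class at a
single classification level.  The filter geometry is the defining
feature: layer-1 filters are 9 channels tall and 25 frames wide and are
applied with a vertical stride of 9, so each application learns from
exactly one sensor location's accelerometer, gyroscope and magnetometer
at once; layer-2 filters (10 frames wide) then operate on each
location's feature-map stack.  Global max pooling over time, one dense
layer and a softmax output complete the model; the whole network is
trained with the Adam optimizer on (optionally class-weighted)
cross-entropy.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .segmentation import SegmentSet
from .session import N_CHANNELS, SensorLocation

CANONICAL_CONV1_TIME = 25
CANONICAL_CONV2_TIME = 10
CANONICAL_CHANNEL_EXTENT = 9
CANONICAL_CHANNEL_STRIDE = 9


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the window classifier.

    The filter geometry defaults (25×9 and 10×9 filters, channel stride
    9) are the canonical configuration; overriding the time extents is
    allowed but flagged with a warning.  Channel extent/stride other
    than 9 would let filters straddle location blocks and is not
    supported.
    """

    conv1_filters: int = 32
    conv1_time: int = CANONICAL_CONV1_TIME
    conv2_filters: int = 64
    conv2_time: int = CANONICAL_CONV2_TIME
    channel_extent: int = CANONICAL_CHANNEL_EXTENT
    channel_stride: int = CANONICAL_CHANNEL_STRIDE
    pooling: str = "global_max"
    dense_units: int = 128
    activation: str = "relu"
    dropout: float = 0.5
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 30
    batch_size: int = 64
    seed: int = 0
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if self.channel_extent != 9 or self.channel_stride != 9:
            raise ValueError(
                "channel extent/stride must be 9 (one filter application per "
                "sensor-location block)"
            )
        if self.pooling != "global_max" or self.activation != "relu":
            raise ValueError("supported: pooling='global_max', activation='relu'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if (self.conv1_time, self.conv2_time) != (
            CANONICAL_CONV1_TIME,
            CANONICAL_CONV2_TIME,
        ):
            warnings.warn(
                f"non-canonical filter time extents "
                f"({self.conv1_time}, {self.conv2_time}); canonical is (25, 10)",
                stacklevel=3,
            )


@dataclass
class TrainedModel:
    """A (possibly still untrained) classifier bound to one level."""

    config: ModelConfig
    level: int
    class_names: tuple[str, ...]
    locations: tuple[SensorLocation, ...]
    params: dict[str, np.ndarray]
    training_log: list[dict] = field(default_factory=list)
    norm_stats: "NormStats | None" = None

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    def layer_geometry(self, window: int = 100) -> dict[str, int]:
        """Shape bookkeeping for the fixed architecture."""
        L = self.n_locations
        return {
            "input_rows": N_CHANNELS * L,
            "input_cols": window,
            "conv1_vertical_positions": (N_CHANNELS * L - self.config.channel_extent)
            // self.config.channel_stride
            + 1,
            "conv1_time_positions": window - self.config.conv1_time + 1,
            "conv2_time_positions": window
            - self.config.conv1_time
            + 1
            - self.config.conv2_time
            + 1,
            "n_classes": len(self.class_names),
        }


@dataclass(frozen=True)
class NormStats:
    """Per-channel z-scoring statistics (one row = one sensor channel)."""

    mean: np.ndarray
    sd: np.ndarray


def build_model(
    config: ModelConfig,
    n_locations: int | Sequence[SensorLocation],
    class_names: Sequence[str],
    level: int = 1,
) -> TrainedModel:
    """Initialize an untrained model (parameters seeded from config.seed)."""
    if isinstance(n_locations, int):
        from .session import ALL_LOCATIONS

        locations = ALL_LOCATIONS[:n_locations]
    else:
        locations = tuple(n_locations)
    if len(locations) < 1:
        raise ValueError("need at least one sensor location")
    if len(class_names) < 2:
        raise ValueError(f"need at least 2 classes, got {list(class_names)}")
    rng = np.random.default_rng([config.seed, 0])
    params = nn.init_params(
        n_locations=len(locations),
        n_classes=len(class_names),
        conv1_filters=config.conv1_filters,
        conv1_time=config.conv1_time,
        conv2_filters=config.conv2_filters,
        conv2_time=config.conv2_time,
        dense_units=config.dense_units,
        rng=rng,
    )
    return TrainedModel(
        config=config,
        level=level,
        class_names=tuple(class_names),
        locations=locations,
        params=params,
    )


def normalize(
    segments: SegmentSet, stats: NormStats | None = None
) -> tuple[SegmentSet, NormStats]:
    """Per-channel z-scoring.

    When ``stats`` is None they are computed from the given set (a
    training fold) and returned; test folds must reuse the training
    stats so no information leaks from held-out participants.
    """
    rows = segments.data.shape[1]
    if stats is None:
        mean = segments.data.mean(axis=(0, 2))
        sd = segments.data.std(axis=(0, 2))
        # numerically-zero variance (constant channel up to rounding)
        zero = sd <= 1e-10 * np.maximum(1.0, np.abs(mean))
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance channel(s); sd clamped to 1",
                stacklevel=2,
            )
            sd = np.where(zero, 1.0, sd)
        stats = NormStats(mean=mean, sd=sd)
    if stats.mean.shape != (rows,):
        raise ValueError(
            f"stats have {stats.mean.shape[0]} channels, data has {rows}"
        )
    data = (segments.data - stats.mean[None, :, None]) / stats.sd[None, :, None]
    return replace(segments, data=data), stats


def _label_indices(labels: np.ndarray, class_names: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    try:
        return np.array([index[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(
            f"label {exc.args[0]!r} not in class_names {list(class_names)}"
        ) from exc


def _class_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse-frequency weights (absent classes get weight 0)."""
    counts = np.bincount(y, minlength=n_classes).astype(np.float64)
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = len(y) / (present.sum() * counts[present])
    return w


def train(
    model: TrainedModel, train_segments: SegmentSet, level: int | None = None
) -> TrainedModel:
    """Train in place for ``config.epochs`` epochs; returns the model.

    With a fixed seed and fixed input order, training is bit-reproducible
    on one device.  The training log records per-epoch mean loss and
    training accuracy.
    """
    if level is None:
        level = model.level
    if len(train_segments) == 0:
        raise ValueError("empty training set")
    cfg = model.config
    x = train_segments.data.astype(nn.DTYPE)
    y = _label_indices(train_segments.labels_at(level), model.class_names)
    expected_rows = N_CHANNELS * model.n_locations
    if x.shape[1] != expected_rows:
        raise ValueError(
            f"segment geometry mismatch: expected {expected_rows} rows "
            f"for {model.n_locations} locations, got {x.shape[1]}"
        )

    weights = _class_weights(y, len(model.class_names)) if cfg.class_weighting else None
    adam = nn.Adam(cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.epsilon)
    rng = np.random.default_rng([cfg.seed, 1])

    n = len(y)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits, cache = nn.forward(
                model.params,
                xb,
                cfg.conv1_time,
                cfg.conv2_time,
                dropout=cfg.dropout,
                dropout_rng=rng,
            )
            loss, dlogits = nn.cross_entropy(logits, yb, weights)
            grads = nn.backward(
                model.params, cache, dlogits, cfg.conv1_time, cfg.conv2_time
            )
            adam.step(model.params, grads)
            losses.append(loss * len(idx))
            correct += int((np.argmax(logits, axis=1) == yb).sum())
        model.training_log.append(
            {
                "epoch": epoch,
                "loss": float(np.sum(losses) / n),
                "accuracy": correct / n,
            }
        )
    return model


def predict(
    model: TrainedModel, segments: SegmentSet, batch_size: int = 256
) -> tuple[list[str], np.ndarray]:
    """Predicted class names and softmax probability rows.

    Argmax ties break toward the lowest class index; probability rows
    sum to 1 within float tolerance.
    """
    expected_rows = N_CHANNELS * model.n_locations
    if segments.data.shape[1:] != (expected_rows, segments.window):
        raise ValueError(
            f"segment geometry mismatch: expected (n, {expected_rows}, "
            f"{segments.window}), got {segments.data.shape}"
        )
    cfg = model.config
    x = segments.data.astype(nn.DTYPE)
    probs = []
    for lo in range(0, len(x), batch_size):
        logits, _ = nn.forward(
            model.params, x[lo : lo + batch_size], cfg.conv1_time, cfg.conv2_time
        )
        probs.append(nn.softmax(logits.astype(np.float64)))
    prob = np.concatenate(probs) if probs else np.zeros((0, len(model.class_names)))
    names = [model.class_names[i] for i in np.argmax(prob, axis=1)]
    return names, prob


def derive_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary labelled parts."""
    return zlib.crc32(":".join(str(p) for p in parts).encode()) % (2**31)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist parameters + config as a compressed numpy archive."""
    meta = {
        "config": asdict(model.config),
        "level": model.level,
        "class_names": list(model.class_names),
        "locations": [l.value for l in model.locations],
        "training_log": model.training_log,
        "has_norm": model.norm_stats is not None,
    }
    arrays = dict(model.params)
    if model.norm_stats is not None:
        arrays["norm_mean"] = model.norm_stats.mean
        arrays["norm_sd"] = model.norm_stats.sd
    np.savez_compressed(path, _meta=np.frombuffer(json.dumps(meta).encode(), np.uint8), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as archive:
        meta = json.loads(archive["_meta"].tobytes().decode())
        params = {
            k: archive[k]
            for k in archive.files
            if k not in ("_meta", "norm_mean", "norm_sd")
        }
        norm = None
        if meta["has_norm"]:
            norm = NormStats(mean=archive["norm_mean"], sd=archive["norm_sd"])
    return TrainedModel(
        config=ModelConfig(**meta["config"]),
        level=meta["level"],
        class_names=tuple(meta["class_names"]),
        locations=tuple(SensorLocation(v) for v in meta["locations"]),
        params=params,
        training_log=meta["training_log"],
        norm_stats=norm,
    )
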