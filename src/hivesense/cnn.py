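"""Training/inference harness for the 5-class spectrogram-image classifier.

Acoustic classes (queen-loss, weak, normal, early-swarm, late-swarm) are
predicted from the 224 x 224 single-channel mean-response image.  The
harness fixes the training recipe (Adam lr 0.001, 80/20 split, 100 epochs of
batch-64 updates, per-epoch validation metrics) and treats the network
architecture as pluggable: a compact convolutional net is built in for
desk-scale data, and additional builders (residual, inception-style, ...)
can be registered by name.  Architecture-specific hyperparameters — label
smoothing 0.1 for the inception-style net, first-stage stride (2,2) with
dropout 0.2 for the 18-layer residual net, stride (1,1) with no dropout for
the 50-layer one, depth 40 / widen factor 4 for the wide residual net — are
carried and validated by :class:`ArchConfig` so a registered builder
receives them ready-checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .audio import CROP, GrayImage
from .errors import ConfigError, ShapeError, StateError
from .metrics import ConfusionMatrix, EpochMetrics, accuracy
from .nn_core import (
    AvgPoolStem,
    Conv2D,
    Dense,
    Flatten,
    MaxPool2D,
    Network,
    ReLU,
    TrainConfig,
    train_network,
)
from .synth import AUDIO_CLASS_NAMES

log = logging.getLogger(__name__)

N_AUDIO_CLASSES = 5

#: Knobs each named architecture accepts (anything else is a config error).
_ARCH_KNOBS: dict[str, set[str]] = {
    "compact": set(),
    "resnet18": {"first_stride", "dropout"},
    "resnet50": {"first_stride", "dropout"},
    "inception_v3": {"label_smoothing"},
    "wide_resnet40": {"depth", "widen_factor"},
}

#: Published per-architecture defaults for the standard nets.
_ARCH_DEFAULTS: dict[str, dict] = {
    "resnet18": {"first_stride": (2, 2), "dropout": 0.2},
    "resnet50": {"first_stride": (1, 1), "dropout": 0.0},
    "inception_v3": {"label_smoothing": 0.1},
    "wide_resnet40": {"depth": 40, "widen_factor": 4},
}


@dataclass
class AudioClassLabel:
    """One of the five acoustic condition classes."""

    id: int
    name: str = ""
    confidence: float = 0.0

    def __post_init__(self) -> None:
        if self.id not in range(N_AUDIO_CLASSES):
            raise ConfigError(f"audio class id must be 0-{N_AUDIO_CLASSES - 1}")
        if not self.name:
            self.name = AUDIO_CLASS_NAMES[self.id]


@dataclass
class ArchConfig:
    """Architecture selection plus its per-architecture hyperparameters."""

    name: str = "compact"
    label_smoothing: float | None = None
    first_stride: tuple[int, int] | None = None
    dropout: float | None = None
    depth: int | None = None
    widen_factor: int | None = None

    def __post_init__(self) -> None:
        if self.name not in _ARCH_KNOBS:
            raise ConfigError(
                f"unknown architecture {self.name!r}; known: {sorted(_ARCH_KNOBS)}"
            )
        allowed = _ARCH_KNOBS[self.name]
        for knob in ("label_smoothing", "first_stride", "dropout", "depth", "widen_factor"):
            value = getattr(self, knob)
            if value is not None and knob not in allowed:
                raise ConfigError(f"{knob} is not a valid knob for {self.name}")
        for knob, default in _ARCH_DEFAULTS.get(self.name, {}).items():
            if getattr(self, knob) is None:
                setattr(self, knob, default)
        if self.dropout is not None and not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout probability must be in [0, 1)")


#: name -> builder(arch, rng) -> Network
_BUILDERS: dict[str, Callable[[ArchConfig, np.random.Generator], Network]] = {}


def register_architecture(name: str, builder: Callable[[ArchConfig, np.random.Generator], Network]) -> None:
    """Plug in a builder for a named architecture."""
    _ARCH_KNOBS.setdefault(name, set())
    _BUILDERS[name] = builder


def _build_compact(arch: ArchConfig, rng: np.random.Generator) -> Network:
    """Compact convolutional net for desk-scale experiments.

    8x8 average-pool stem (224 -> 28), one 3x3 convolution with 8 filters,
    2x2 max pool, then dense 32 -> 5.  Small enough to train in seconds on
    a few hundred images while still reading band-position structure.
    """
    layers = [
        AvgPoolStem(8),
        Conv2D(3, 1, 8, rng),
        ReLU(),
        MaxPool2D(2),
        Flatten(),
        Dense(13 * 13 * 8, 32, rng),
        ReLU(),
        Dense(32, N_AUDIO_CLASSES, rng),
    ]
    return Network(layers, n_classes=N_AUDIO_CLASSES)


register_architecture("compact", _build_compact)


def build_classifier(arch: ArchConfig | str = "compact", seed: int = 0) -> Network:
    """Instantiate a classifier network for the named architecture."""
    if isinstance(arch, str):
        arch = ArchConfig(name=arch)
    builder = _BUILDERS.get(arch.name)
    if builder is None:
        raise ConfigError(
            f"no builder registered for architecture {arch.name!r}; "
            "register one with register_architecture()"
        )
    net = builder(arch, np.random.default_rng(seed))
    # fixed 8-bit input scaling: pixel 0-255 -> 0-1
    net.input_mean = np.float32(0.0)
    net.input_scale = np.float32(255.0)
    return net


def _stack_images(images) -> np.ndarray:
    arrs = [img.pixels if isinstance(img, GrayImage) else np.asarray(img) for img in images]
    stacked = np.stack(arrs).astype(np.float32)
    if stacked.ndim != 3 or stacked.shape[1:] != (CROP, CROP):
        raise ShapeError(f"images must be single-channel {CROP}x{CROP}, got {stacked.shape[1:]}")
    return stacked[..., None]  # NHWC with one channel


def train_classifier(
    images,
    labels: np.ndarray,
    arch: ArchConfig | str = "compact",
    config: TrainConfig | None = None,
) -> tuple[Network, EpochMetrics]:
    """Train an image classifier on labelled grayscale spectrogram images.

    Splits 80/20 (seeded), trains with cross-entropy (label smoothing if the
    architecture configures it) and no L1 penalty, and stores the held-out
    accuracy on the returned network (``holdout_accuracy`` in percent).
    """
    if isinstance(arch, str):
        arch = ArchConfig(name=arch)
    config = config or TrainConfig(l1_lambda=0.0)
    if arch.label_smoothing is not None:
        config.label_smoothing = arch.label_smoothing
    X = _stack_images(images)
    y = np.asarray(labels, dtype=np.int64)
    if len(X) != len(y):
        raise ShapeError("images and labels differ in length")
    if len(X) < 2 * N_AUDIO_CLASSES:
        log.warning("very small image dataset (%d); holdout metrics are unreliable", len(X))
    net = build_classifier(arch, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(X))
    n_train = max(1, int(round(config.train_fraction * len(X))))
    tr, te = perm[:n_train], perm[n_train:]
    metrics = train_network(net, X[tr], y[tr], config, standardize=False)
    if len(te):
        pred = net.predict(X[te])
        cm = ConfusionMatrix.from_predictions(y[te], pred, N_AUDIO_CLASSES)
        net.holdout_confusion = cm
        net.holdout_accuracy = 100.0 * accuracy(cm)
    else:
        net.holdout_accuracy = None
    log.info(
        "trained %s classifier: %d params, holdout accuracy %s",
        arch.name, net.n_params,
        f"{net.holdout_accuracy:.1f}%" if net.holdout_accuracy is not None else "n/a",
    )
    return net, metrics


def save_classifier(net: Network, arch: ArchConfig, base_path: str) -> None:
    """Write weights (.npz) plus a JSON sidecar describing the architecture."""
    import json

    net.save_weights(base_path + ".npz")
    sidecar = {
        "architecture": arch.name,
        "label_smoothing": arch.label_smoothing,
        "holdout_accuracy": getattr(net, "holdout_accuracy", None),
    }
    with open(base_path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_classifier(base_path: str) -> tuple[Network, ArchConfig]:
    """Rebuild a classifier from a checkpoint written by :func:`save_classifier`."""
    import json
    import os

    if not os.path.exists(base_path + ".json"):
        raise StateError(f"no classifier checkpoint at {base_path}")
    with open(base_path + ".json") as fh:
        sidecar = json.load(fh)
    arch = ArchConfig(name=sidecar["architecture"])
    net = build_classifier(arch)
    net.load_weights(base_path + ".npz")
    net.holdout_accuracy = sidecar.get("holdout_accuracy")
    return net, arch


def infer_image(net: Network, image: GrayImage | np.ndarray) -> tuple[AudioClassLabel, np.ndarray]:
    """Classify one grayscale image; returns (label, 5 normalised class scores)."""
    if not net.trained:
        raise StateError("the classifier has not been trained")
    X = _stack_images([image])
    proba = net.predict_proba(X)[0]
    winner = int(np.argmax(proba))
    return AudioClassLabel(id=winner, confidence=float(proba[winner])), proba
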