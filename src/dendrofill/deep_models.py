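"""The five deep reconstruction architectures and their training loop.

Each network maps a sentinel-encoded segment (segment_length x n_channels,
values in {-1} union [0, 1]) to a full prediction of the same shape — every
time stamp of every channel is predicted, not only the gap entries — trained
with mean squared error over all output entries against the clean segment,
Adam, dropout, and early stopping on validation loss.

The five architectures:

``lstm``
    Two stacked sequence-to-sequence LSTM layers with a per-stamp linear
    head; optional L1/L2 weight penalties.
``lstm_cnn``
    Two 1-D convolutional layers feeding an LSTM encoder-decoder pair
    (both sequence-to-sequence), then a per-stamp head. The convolutions
    supply local shape context around each stamp, the recurrences the
    longer-range diurnal/seasonal structure.
``lstm_encoder``
    An LSTM encoder compressing the segment to a single latent vector,
    repeated across time and expanded by an LSTM decoder.
``autoencoder_2d``
    The segment treated as a one-channel image (time x channels); three
    strided 2-D convolutions down to a latent map, mirrored transposed
    convolutions back up.
``lstm_autoencoder``
    A strided 1-D convolutional encoder (4x temporal downsampling), an LSTM
    bottleneck, and a transposed-convolution decoder.

All outputs pass through a sigmoid so predictions land in (0, 1);
:func:`reconstruct` additionally clips to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .gap_simulation import GapMask, SENTINEL, apply_sentinel
from .preprocess import Segment

__all__ = [
    "ARCHITECTURES",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "train_model",
    "reconstruct",
    "make_training_arrays",
]

ARCHITECTURES = ("lstm", "lstm_cnn", "lstm_encoder", "autoencoder_2d", "lstm_autoencoder")

#: Architectures mixing recurrent and convolutional/encoder families.
HYBRID_ARCHITECTURES = ("lstm_cnn", "lstm_encoder", "lstm_autoencoder")
#: Single-family architectures.
SINGLE_FAMILY_ARCHITECTURES = ("lstm", "autoencoder_2d")


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop settings shared by all five architectures.

    The loss is always mean squared error over every output entry, the
    optimizer Adam; ``l1``/``l2`` weight penalties are used by the plain
    LSTM variant.
    """

    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 20
    learning_rate: float = 1e-3
    dropout: float = 0.2
    l1: float = 0.0
    l2: float = 0.0
    rng_seed: int = 0


@dataclass
class TrainedModel:
    architecture: str
    network: nn.NeuralNetwork
    config: TrainConfig
    history: dict[str, list[float]]
    hyperparams: dict = field(default_factory=dict)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.history["val_loss"]))


def _default_hp(hyperparams: dict | None) -> dict:
    hp = {"units": 128, "filters": 64, "kernel": 5, "dropout": 0.2}
    if hyperparams:
        hp.update(hyperparams)
    return hp


def build_model(
    architecture: str,
    n_channels: int,
    segment_length: int,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> nn.NeuralNetwork:
    """Construct one of the five reconstruction networks.

    ``hyperparams`` may override ``units`` (recurrent width), ``filters``
    (convolutional width), ``kernel`` and ``dropout``.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}; pick one of {ARCHITECTURES}")
    hp = _default_hp(hyperparams)
    u, f, k, drop = hp["units"], hp["filters"], hp["kernel"], hp["dropout"]
    C, T = n_channels, segment_length
    rng = np.random.default_rng(seed)

    if architecture == "lstm":
        layers = [
            nn.LSTM(C, u, rng),
            nn.Dropout(drop),
            nn.LSTM(u, u, rng),
            nn.Dense(u, C, rng),
            nn.Sigmoid(),
        ]
    elif architecture == "lstm_cnn":
        # Convolutions give every stamp acausal local context; the LSTM
        # encoder compresses the whole segment to a latent vector that is
        # tiled back alongside the conv features (global context at every
        # stamp), and the LSTM decoder emits the sequence. Gaps longer than
        # the conv receptive field thus still see both boundaries.
        layers = [
            nn.Conv1D(C, f, k, rng),
            nn.ReLU(),
            nn.Conv1D(f, f, k, rng),
            nn.ReLU(),
            nn.Dropout(drop),
            nn.GlobalContextConcat(nn.LSTM(f, u, rng, return_sequences=False)),
            nn.LSTM(f + u, u, rng),      # decoder, sequence output
            nn.Dense(u, C, rng),
            nn.Sigmoid(),
        ]
    elif architecture == "lstm_encoder":
        # the latent vector is the decoder's only context, so the encoder
        # reads the sequence from both ends (a causal read alone would let
        # early-segment information fade before the latent is formed) and
        # dropout sits on the decoder output rather than on the latent
        layers = [
            nn.Bidirectional(
                nn.LSTM(C, u, rng, return_sequences=False),
                nn.LSTM(C, u, rng, return_sequences=False),
            ),
            nn.RepeatVector(T),
            nn.LSTM(2 * u, u, rng),
            nn.Dropout(drop),
            nn.Dense(u, C, rng),
            nn.Sigmoid(),
        ]
    elif architecture == "autoencoder_2d":
        if T % 8 or C % 8:
            raise ValueError(
                "autoencoder_2d needs segment_length and n_channels divisible by 8"
            )
        layers = [
            nn.Reshape((T, C, 1)),
            nn.Conv2D(1, f, (3, 3), rng, stride=(2, 2)),
            nn.ReLU(),
            nn.Conv2D(f, 2 * f, (3, 3), rng, stride=(2, 2)),
            nn.ReLU(),
            nn.Dropout(drop),
            nn.Conv2D(2 * f, 2 * f, (3, 3), rng, stride=(2, 2)),  # latent map
            nn.ReLU(),
            nn.Conv2DTranspose(2 * f, 2 * f, (3, 3), rng, stride=(2, 2)),
            nn.ReLU(),
            nn.Conv2DTranspose(2 * f, f, (3, 3), rng, stride=(2, 2)),
            nn.ReLU(),
            nn.Conv2DTranspose(f, 1, (3, 3), rng, stride=(2, 2)),
            nn.Reshape((T, C)),
            nn.Sigmoid(),
        ]
    else:  # lstm_autoencoder
        if T % 4:
            raise ValueError("lstm_autoencoder needs segment_length divisible by 4")
        layers = [
            nn.Conv1D(C, f, k, rng, stride=2),
            nn.ReLU(),
            nn.Conv1D(f, f, k, rng, stride=2),
            nn.ReLU(),
            nn.Dropout(drop),
            nn.LSTM(f, u, rng),          # bottleneck recurrence at T/4
            nn.Conv1DTranspose(u, f, k, rng, stride=2),
            nn.ReLU(),
            nn.Conv1DTranspose(f, f, k, rng, stride=2),
            nn.Dense(f, C, rng),
            nn.Sigmoid(),
        ]
    return nn.NeuralNetwork(nn.Sequential(layers), loss="mse", seed=seed)


def latent_size(architecture: str, n_channels: int, segment_length: int,
                hyperparams: dict | None = None) -> int:
    """Dimensionality of the narrowest internal representation."""
    hp = _default_hp(hyperparams)
    C, T = n_channels, segment_length
    if architecture == "lstm_encoder":
        return hp["units"]
    if architecture == "autoencoder_2d":
        return (T // 8) * (C // 8) * 2 * hp["filters"]
    if architecture == "lstm_autoencoder":
        return (T // 4) * hp["units"]
    return T * max(hp["units"], hp["filters"])


def make_training_arrays(
    segments: Sequence[Segment],
    masks: Sequence[GapMask],
    sentinel: float = SENTINEL,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (corrupted input, clean target) arrays from normalized segments."""
    if len(segments) != len(masks):
        raise ValueError("need one mask per segment")
    X = np.stack([apply_sentinel(s.values, m, sentinel) for s, m in zip(segments, masks)])
    Y = np.stack([s.values for s in segments])
    return X, Y


def train_model(
    architecture: str,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
    hyperparams: dict | None = None,
) -> TrainedModel:
    """Build and fit one architecture; returns the model restored to its
    best-validation-epoch parameters together with the full loss history."""
    hp = _default_hp(hyperparams)
    hp["dropout"] = config.dropout
    n_channels = X_train.shape[2]
    segment_length = X_train.shape[1]
    network = build_model(architecture, n_channels, segment_length, hp, seed=config.rng_seed)
    history = network.fit(
        X_train,
        Y_train,
        X_val,
        Y_val,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        lr=config.learning_rate,
        l1=config.l1 if architecture == "lstm" else 0.0,
        l2=config.l2 if architecture == "lstm" else 0.0,
    )
    return TrainedModel(
        architecture=architecture,
        network=network,
        config=config,
        history=history,
        hyperparams=hp,
    )


def reconstruct(model: TrainedModel | nn.NeuralNetwork, corrupted: np.ndarray) -> np.ndarray:
    """Full-matrix prediction for sentinel-encoded input, clipped to [0, 1].

    Accepts a single segment (T, C) or a batch (n, T, C).
    """
    network = model.network if isinstance(model, TrainedModel) else model
    single = corrupted.ndim == 2
    X = corrupted[None] if single else corrupted
    pred = np.clip(network.predict(X), 0.0, 1.0)
    return pred[0] if single else pred
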