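"""Species-classification validation of the gap-filling procedure.

Does imputation actually add usable data? Two segment datasets are built
from the same tree cohort: a *standard* set containing only naturally
complete 30-day segments, and a *reconstructed* set obtained by tiling each
training/validation series into fixed 30-day windows and repairing every
incomplete tile with the trained imputer — provided less than two-thirds of
its stamps are missing, otherwise the tile is discarded. A 1-D residual
convolutional network (ResNet) is then trained repeatedly on each variant
with fresh tree-atomic train/validation splits and evaluated on one fixed
test set of complete segments; confusion matrices are averaged over the
repetitions. If reconstruction adds information rather than noise, the
reconstructed variant should classify at least as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import nn
from .deep_models import TrainedModel, reconstruct
from .evaluation import inpaint
from .gap_simulation import SENTINEL
from .preprocess import (
    Segment,
    extract_segments,
    normalize_segment,
    split_by_tree,
)
from .timeseries_core import (
    CHANNEL_NAMES,
    MEASURED_CHANNELS,
    MultiChannelSeries,
)

__all__ = [
    "ClassConfig",
    "ClassificationData",
    "ConfusionMatrix",
    "build_datasets",
    "build_resnet",
    "run_experiment",
]


@dataclass(frozen=True)
class ClassConfig:
    """Classification-experiment settings."""

    test_fraction: float = 0.10
    train_fraction: float = 0.80
    val_fraction: float = 0.10
    epochs: int = 300
    patience: int = 30
    repetitions: int = 10
    reconstruction_threshold: float = 2.0 / 3.0
    batch_size: int = 16
    learning_rate: float = 1e-3
    dropout: float = 0.2
    filters: tuple[int, int, int] = (64, 128, 128)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = self.test_fraction + self.train_fraction + self.val_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("test/train/val fractions must sum to 1")
        if not 0.0 < self.reconstruction_threshold < 1.0:
            raise ValueError("reconstruction threshold must lie in (0, 1)")


@dataclass
class ClassificationData:
    """The two training variants plus the shared test set."""

    standard: list[Segment]
    reconstructed: list[Segment]
    test: list[Segment]
    species: tuple[str, ...]
    counts: pd.DataFrame  # per-species segment counts, both variants


@dataclass
class ConfusionMatrix:
    """Row-normalized percentages (rows = true species), optionally averaged
    over repetitions; overall accuracy is the unweighted mean of the diagonal
    (every species counts equally), with a segment-weighted variant too."""

    matrix: np.ndarray
    species: tuple[str, ...]
    accuracy: float
    weighted_accuracy: float


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------


def _missing_stamp_fraction(values: np.ndarray, per_stamp_any: bool = True) -> float:
    nan = np.isnan(values)
    if per_stamp_any:
        return float(nan.any(axis=1).mean())
    return float(nan.mean())


def _normalize_with_missing(tile: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize per channel over observed entries; NaN preserved.

    Returns the normalized matrix and the (min, max) parameters. A channel
    with no observed entry keeps all-NaN and gets (0, 1) placeholders.
    """
    lo = np.empty(tile.shape[1])
    hi = np.empty(tile.shape[1])
    out = np.empty_like(tile)
    for c in range(tile.shape[1]):
        col = tile[:, c]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            lo[c], hi[c] = 0.0, 1.0
            out[:, c] = np.nan
            continue
        lo[c], hi[c] = obs.min(), obs.max()
        span = hi[c] - lo[c] if hi[c] > lo[c] else 1.0
        out[:, c] = (col - lo[c]) / span
    return out, np.column_stack([lo, hi])


def _tile_series(series: MultiChannelSeries, segment_length: int):
    """Fixed tiling anchored at the series start with stride = tile length."""
    values = series.data[list(MEASURED_CHANNELS)].to_numpy()
    tod = series.time_of_day()
    n = len(values)
    for start in range(0, n - segment_length + 1, segment_length):
        block = np.column_stack(
            [values[start : start + segment_length], tod[start : start + segment_length]]
        )
        yield start, block


def build_datasets(
    series_list: Sequence[MultiChannelSeries],
    imputer: TrainedModel | None,
    config: ClassConfig = ClassConfig(),
    segment_length: int = 720,
) -> ClassificationData:
    """Build the standard and reconstructed segment datasets.

    Test trees are chosen once (tree-atomic, by segment count); their
    naturally complete segments form the shared test set. From the remaining
    trees, the standard variant keeps complete segments only, while the
    reconstructed variant tiles each series into fixed windows and repairs
    incomplete tiles whose missing-stamp fraction (a stamp counts as missing
    if any measured channel is missing) is below the two-thirds threshold.
    """
    all_species = tuple(sorted({s.species for s in series_list}))
    complete_by_tree = {
        s.tree_id: [normalize_segment(seg) for seg in extract_segments(s, segment_length)]
        for s in series_list
    }
    all_complete = [seg for segs in complete_by_tree.values() for seg in segs]
    if not all_complete:
        raise ValueError("no complete segments in the collection")
    for sp in all_species:
        if not any(seg.species == sp for seg in all_complete):
            raise ValueError(f"species {sp!r} has no complete segments")
    # stratify the tree-atomic test split by species so every species is
    # represented in the fixed test set
    assignment: dict[str, str] = {}
    for k, sp in enumerate(all_species):
        sp_segments = [seg for seg in all_complete if seg.species == sp]
        assignment.update(
            split_by_tree(
                sp_segments,
                {"trainval": 1.0 - config.test_fraction, "test": config.test_fraction},
                rng_seed=config.rng_seed + k,
            )
        )
    test = [seg for seg in all_complete if assignment[seg.tree_id] == "test"]
    standard = [seg for seg in all_complete if assignment[seg.tree_id] == "trainval"]

    reconstructed: list[Segment] = []
    for series in series_list:
        if assignment.get(series.tree_id) != "trainval":
            continue
        for start, tile in _tile_series(series, segment_length):
            frac = _missing_stamp_fraction(tile[:, : len(MEASURED_CHANNELS)])
            if frac == 0.0:
                seg = Segment(
                    tree_id=series.tree_id,
                    species=series.species,
                    start=series.timestamps[start],
                    values=tile,
                    channels=CHANNEL_NAMES,
                )
                reconstructed.append(normalize_segment(seg))
                continue
            if frac >= config.reconstruction_threshold:
                continue
            if imputer is None:
                continue
            normed, params = _normalize_with_missing(tile)
            corrupted = normed.copy()
            missing = np.isnan(corrupted)
            corrupted[missing] = SENTINEL
            prediction = reconstruct(imputer, corrupted)
            filled = inpaint(np.nan_to_num(normed), prediction, missing)
            reconstructed.append(
                Segment(
                    tree_id=series.tree_id,
                    species=series.species,
                    start=series.timestamps[start],
                    values=filled,
                    channels=CHANNEL_NAMES,
                    norm_params=params,
                )
            )

    counts = pd.DataFrame(
        [
            {
                "species": sp,
                "n_trees": sum(1 for s in series_list if s.species == sp),
                "segments_standard": sum(1 for g in standard if g.species == sp),
                "segments_reconstructed": sum(1 for g in reconstructed if g.species == sp),
                "segments_test": sum(1 for g in test if g.species == sp),
            }
            for sp in all_species
        ]
    )
    return ClassificationData(
        standard=standard,
        reconstructed=reconstructed,
        test=test,
        species=all_species,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# ResNet classifier
# ---------------------------------------------------------------------------


def build_resnet(
    n_classes: int,
    n_channels: int,
    filters: tuple[int, int, int] = (64, 128, 128),
    dropout: float = 0.2,
    seed: int = 0,
) -> nn.NeuralNetwork:
    """1-D residual network for time-series classification.

    Three residual blocks (three convolutions each, kernels 8/5/3, batch
    normalization, ReLU, identity shortcuts with 1x1 projections where the
    filter counts change), global average pooling, dropout and a softmax
    head.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    f1, f2, f3 = filters
    net = nn.Sequential(
        [
            nn.ResidualBlock1D(n_channels, f1, (8, 5, 3), rng),
            nn.ResidualBlock1D(f1, f2, (8, 5, 3), rng),
            nn.ResidualBlock1D(f2, f3, (8, 5, 3), rng),
            nn.GlobalAvgPool1D(),
            nn.Dropout(dropout),
            nn.Dense(f3, n_classes, rng),
        ]
    )
    return nn.NeuralNetwork(net, loss="softmax_ce", seed=seed)


def _arrays(segments: Sequence[Segment], species: tuple[str, ...]):
    X = np.stack([s.values for s in segments])
    y = np.array([species.index(s.species) for s in segments])
    onehot = np.eye(len(species))[y]
    return X, y, onehot


def _confusion(pred: np.ndarray, true: np.ndarray, k: int) -> np.ndarray:
    m = np.zeros((k, k))
    for t, p in zip(true, pred):
        m[t, p] += 1
    row = m.sum(axis=1, keepdims=True)
    return 100.0 * m / np.where(row == 0, 1, row)


def _train_one_run(
    segments: Sequence[Segment],
    test_segments: Sequence[Segment],
    species: tuple[str, ...],
    config: ClassConfig,
    seed: int,
) -> np.ndarray:
    """One classifier realization: fresh tree-atomic train/val split, train
    with validation checkpointing, confusion matrix on the fixed test set."""
    val_share = config.val_fraction / (config.train_fraction + config.val_fraction)
    assignment = split_by_tree(
        segments, {"train": 1.0 - val_share, "val": val_share}, rng_seed=seed
    )
    train = [s for s in segments if assignment[s.tree_id] == "train"]
    val = [s for s in segments if assignment[s.tree_id] == "val"]
    X_tr, _, Y_tr = _arrays(train, species)
    X_va, _, Y_va = _arrays(val, species)
    X_te, y_te, _ = _arrays(test_segments, species)
    for attempt in range(3):
        model = build_resnet(
            len(species),
            X_tr.shape[2],
            filters=config.filters,
            dropout=config.dropout,
            seed=seed + 1000 * attempt,
        )
        try:
            model.fit(
                X_tr,
                Y_tr,
                X_va,
                Y_va,
                batch_size=config.batch_size,
                max_epochs=config.epochs,
                patience=config.patience,
                lr=config.learning_rate,
            )
        except RuntimeError:
            continue  # diverged; reinitialize with a new seed
        pred = np.argmax(model.predict(X_te), axis=1)
        return _confusion(pred, y_te, len(species))
    raise RuntimeError("classifier training diverged 3 times in a row")


def run_experiment(
    data: ClassificationData, config: ClassConfig = ClassConfig()
) -> dict[str, ConfusionMatrix]:
    """Train both variants ``repetitions`` times and average confusion matrices.

    Returns {'standard': ConfusionMatrix, 'reconstructed': ConfusionMatrix}.
    Both variants share the one fixed test set of complete segments; any
    tree contributing to the test set contributes to neither training
    variant (hard assertion).
    """
    test_trees = {s.tree_id for s in data.test}
    for name, segs in (("standard", data.standard), ("reconstructed", data.reconstructed)):
        leak = {s.tree_id for s in segs} & test_trees
        if leak:
            raise AssertionError(f"tree-level leakage into {name} variant: {sorted(leak)}")
    results: dict[str, ConfusionMatrix] = {}
    k = len(data.species)
    test_counts = np.array(
        [sum(1 for s in data.test if s.species == sp) for sp in data.species]
    )
    for name, segs in (("standard", data.standard), ("reconstructed", data.reconstructed)):
        mats = []
        for rep in range(config.repetitions):
            seed = config.rng_seed + 10_000 * (1 if name == "standard" else 2) + rep
            mats.append(_train_one_run(segs, data.test, data.species, config, seed))
        avg = np.mean(mats, axis=0)
        diag = np.diag(avg)
        results[name] = ConfusionMatrix(
            matrix=avg,
            species=data.species,
            accuracy=float(diag.mean()),
            weighted_accuracy=float((diag * test_counts).sum() / test_counts.sum()),
        )
    return results
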