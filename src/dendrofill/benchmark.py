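"""The scaled synthetic reconstruction benchmark.

One fixed synthetic dataset (a growing-season cohort), one fixed artificial
gap draw and one fixed tree-atomic test split, on which all five deep
architectures and the four regression baselines are trained and scored by
median gap-only stem-radius MSE, repeatedly under different training seeds.

The problem sizes are scaled-down study conditions chosen once: 12 trees on
3 sites over 120 growing-season days, 96-hour segments with 32-hour gaps
(the same 1:3 gap-to-segment ratio as the full-size 240 h / 720 h setting),
recurrent width 48 and 40 training epochs. They keep one training seed's
nine model fits to under two CPU-minutes while preserving the structure that
separates the model families: gaps longer than any convolutional receptive
field, so bridging them requires combining local context with segment-wide
memory. Models are deliberately trained far short of full convergence;
docs/methods.md discusses which comparative margins survive that and which
do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .baseline_models import BaselineSpec, fit_baseline, predict_sr
from .deep_models import (
    ARCHITECTURES,
    TrainConfig,
    TrainedModel,
    make_training_arrays,
    reconstruct,
    train_model,
)
from .evaluation import gap_mse
from .gap_simulation import GapMask, make_gap_mask
from .preprocess import Segment, extract_segments, normalize_segment, split_by_tree
from .synthetic_data import generate_dataset
from .timeseries_core import TARGET_CHANNEL

__all__ = [
    "BenchmarkConfig",
    "BenchmarkData",
    "make_benchmark_data",
    "run_reconstruction_benchmark",
    "sign_test_wins",
]

BASELINE_IDS = ("ridge_local", "ridge_global", "mlp_local", "mlp_global")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Frozen study conditions of the scaled benchmark."""

    n_trees: int = 12
    n_sites: int = 3
    n_hours: int = 2880            # 120 days of growing season
    start: str = "2020-05-01"
    segment_length: int = 96       # hours
    gap_length: int = 32           # hours; same 1:3 ratio as 240/720
    p_gap: float = 0.5
    train_fraction: float = 0.6
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    units: int = 48
    filters: int = 24
    filters_2d: int = 8
    kernel: int = 5
    batch_size: int = 32
    max_epochs: int = 40
    patience: int = 15
    learning_rate: float = 4e-3
    noise_free: bool = False


@dataclass
class BenchmarkData:
    """Segments, masks and sentinel-encoded arrays of one benchmark draw."""

    groups: dict[str, list[Segment]]
    masks: dict[str, list[GapMask]]
    arrays: dict[str, tuple[np.ndarray, np.ndarray]]  # set -> (X, Y)
    sr_index: int
    config: BenchmarkConfig


def make_benchmark_data(seed: int, config: BenchmarkConfig = BenchmarkConfig()) -> BenchmarkData:
    """Generate the dataset, segments, split and gap masks for one draw.

    ``seed`` controls the dataset realization, the split and the gap draw;
    training seeds vary separately so that all training repetitions share
    one fixed benchmark instance (in particular one fixed test set).
    """
    _, clean, _ = generate_dataset(
        n_trees=config.n_trees,
        n_sites=config.n_sites,
        n_hours=config.n_hours,
        gap_process=None,
        seed=seed,
        noise_free=config.noise_free,
        start=config.start,
    )
    segments = []
    for s in clean:
        segments.extend(
            normalize_segment(g) for g in extract_segments(s, config.segment_length)
        )
    assignment = split_by_tree(
        segments,
        {
            "train": config.train_fraction,
            "val": config.val_fraction,
            "test": config.test_fraction,
        },
        rng_seed=seed + 1,
    )
    groups = {
        name: [s for s in segments if assignment[s.tree_id] == name]
        for name in ("train", "val", "test")
    }
    rng = np.random.default_rng(seed + 2)
    masks = {
        name: [
            make_gap_mask(config.segment_length, s.channels, config.gap_length, rng,
                          config.p_gap)
            for s in segs
        ]
        for name, segs in groups.items()
    }
    arrays = {
        name: make_training_arrays(groups[name], masks[name]) for name in groups
    }
    sr_index = segments[0].channels.index(TARGET_CHANNEL)
    return BenchmarkData(groups=groups, masks=masks, arrays=arrays,
                         sr_index=sr_index, config=config)


def _hyperparams(arch: str, config: BenchmarkConfig) -> dict:
    return {
        "units": config.units,
        "filters": config.filters_2d if arch == "autoencoder_2d" else config.filters,
        "kernel": config.kernel,
    }


def train_benchmark_model(
    data: BenchmarkData, arch: str, train_seed: int
) -> TrainedModel:
    cfg = TrainConfig(
        batch_size=data.config.batch_size,
        max_epochs=data.config.max_epochs,
        patience=data.config.patience,
        learning_rate=data.config.learning_rate,
        rng_seed=train_seed,
    )
    Xt, Yt = data.arrays["train"]
    Xv, Yv = data.arrays["val"]
    return train_model(arch, Xt, Yt, Xv, Yv, cfg, _hyperparams(arch, data.config))


def deep_model_sr_errors(data: BenchmarkData, model: TrainedModel) -> np.ndarray:
    """Per-test-segment gap-only SR MSE of a reconstruction network."""
    Xe, Ye = data.arrays["test"]
    pred = reconstruct(model, Xe)
    return np.array(
        [
            gap_mse(pred[i], Ye[i], data.masks["test"][i], channel_index=data.sr_index)
            for i in range(len(Xe))
        ]
    )


def baseline_sr_errors(data: BenchmarkData, model_id: str, train_seed: int) -> np.ndarray:
    """Per-test-segment gap-only SR MSE of one regression baseline."""
    method, scope = model_id.split("_")
    spec = BaselineSpec(method=method, scope=scope, rng_seed=train_seed, max_iter=300)
    model = fit_baseline(data.groups["train"] + data.groups["val"], spec)
    _, Ye = data.arrays["test"]
    errs = []
    for i, s in enumerate(data.groups["test"]):
        pred = s.values.copy()
        pred[:, data.sr_index] = predict_sr(model, s.values)
        errs.append(
            gap_mse(pred, Ye[i], data.masks["test"][i], channel_index=data.sr_index)
        )
    return np.array(errs)


def run_reconstruction_benchmark(
    seed: int = 0,
    train_seeds: Sequence[int] = tuple(range(10)),
    config: BenchmarkConfig = BenchmarkConfig(),
    architectures: Sequence[str] = ARCHITECTURES,
    baselines: Sequence[str] = BASELINE_IDS,
    data: BenchmarkData | None = None,
) -> pd.DataFrame:
    """Median gap-only SR MSE of every model under every training seed.

    Returns a long DataFrame (train_seed, model, median_gap_mse). The
    benchmark instance (dataset, split, gap masks, test set) is fixed by
    ``seed``; only initialization, batching and train/val usage vary with
    the training seed.
    """
    if data is None:
        data = make_benchmark_data(seed, config)
    rows = []
    for ts in train_seeds:
        for arch in architectures:
            model = train_benchmark_model(data, arch, ts)
            errs = deep_model_sr_errors(data, model)
            rows.append({"train_seed": ts, "model": arch,
                         "median_gap_mse": float(np.median(errs))})
        for b in baselines:
            errs = baseline_sr_errors(data, b, ts)
            rows.append({"train_seed": ts, "model": b,
                         "median_gap_mse": float(np.median(errs))})
    return pd.DataFrame(rows)


def sign_test_wins(results: pd.DataFrame, model_a: str, model_b: str) -> tuple[int, int, float]:
    """Paired per-seed comparison of two models' median errors.

    Returns (wins of a, n pairs, one-sided sign-test p-value for the
    hypothesis that a's median error is smaller; ties split evenly).
    """
    from scipy import stats

    a = results[results["model"] == model_a].set_index("train_seed")["median_gap_mse"]
    b = results[results["model"] == model_b].set_index("train_seed")["median_gap_mse"]
    seeds = a.index.intersection(b.index)
    diffs = (a.loc[seeds] - b.loc[seeds]).to_numpy()
    wins = int((diffs < 0).sum()) + 0.5 * int((diffs == 0).sum())
    n = len(diffs)
    p = float(stats.binomtest(int(np.ceil(wins)), n, 0.5, alternative="greater").pvalue)
    return int(wins), n, p
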