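"""Dataset variants (standard vs reconstructed), the two-thirds repair rule,
the residual classifier, and leakage guards."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dendrofill import species_classification as sc
from dendrofill import synthetic_data as sd
from dendrofill.deep_models import TrainConfig, make_training_arrays, train_model
from dendrofill.gap_simulation import make_gap_mask
from dendrofill.preprocess import extract_segments, normalize_segment
from dendrofill.timeseries_core import MEASURED_CHANNELS

L = 96  # scaled segment length used throughout these tests


@pytest.fixture(scope="module")
def gappy_dataset():
    observed, clean, meta = sd.generate_dataset(
        n_trees=8, n_sites=2, n_hours=1920, seed=77, start="2020-05-15"
    )
    return observed, clean, meta


@pytest.fixture(scope="module")
def tiny_imputer(gappy_dataset):
    """A small trained reconstruction network for repairing tiles."""
    _, clean, _ = gappy_dataset
    segs = []
    for s in clean:
        segs.extend(normalize_segment(g) for g in extract_segments(s, L))
    rng = np.random.default_rng(5)
    masks = [make_gap_mask(L, s.channels, L // 3, rng) for s in segs]
    X, Y = make_training_arrays(segs, masks)
    k = max(4, len(segs) // 5)
    cfg = TrainConfig(batch_size=16, max_epochs=8, patience=8, learning_rate=3e-3, rng_seed=0)
    return train_model("lstm_cnn", X[k:], Y[k:], X[:k], Y[:k], cfg,
                       {"units": 16, "filters": 8, "kernel": 5})


def test_two_thirds_threshold_boundary_at_480_of_720():
    """A 720-stamp tile with 481 missing stamps exceeds the two-thirds
    threshold (2/3 of 720 = 480) and is discarded; 479 is repairable."""
    cfg = sc.ClassConfig()
    tile = np.ones((720, 7))
    tile[:481, 3] = np.nan  # one missing channel marks the stamp missing
    frac = sc._missing_stamp_fraction(tile)
    assert frac == pytest.approx(481 / 720)
    assert frac >= cfg.reconstruction_threshold
    tile2 = np.ones((720, 7))
    tile2[:479, 3] = np.nan
    assert sc._missing_stamp_fraction(tile2) < cfg.reconstruction_threshold


def test_build_datasets_counts_and_threshold(gappy_dataset, tiny_imputer):
    observed, _, _ = gappy_dataset
    cfg = sc.ClassConfig(test_fraction=0.25, train_fraction=0.65, val_fraction=0.10,
                         rng_seed=1)
    data = sc.build_datasets(observed, tiny_imputer, cfg, segment_length=L)
    assert data.species == ("fagoid", "piceoid")
    # reconstructed keeps every complete tile plus every repairable one
    assert len(data.reconstructed) >= len(data.standard)
    # counts table is consistent with the segment lists
    for sp in data.species:
        row = data.counts[data.counts["species"] == sp].iloc[0]
        assert row["segments_standard"] == sum(s.species == sp for s in data.standard)
        assert row["segments_reconstructed"] == sum(
            s.species == sp for s in data.reconstructed
        )
    # repaired tiles contain no NaN and stay in [0, 1]
    for seg in data.reconstructed:
        assert np.isfinite(seg.values).all()
        assert seg.values.min() >= 0.0 and seg.values.max() <= 1.0


def test_build_datasets_no_missing_data_gives_identical_counts(gappy_dataset, tiny_imputer):
    _, clean, _ = gappy_dataset
    cfg = sc.ClassConfig(test_fraction=0.25, train_fraction=0.65, val_fraction=0.10,
                         rng_seed=1)
    data = sc.build_datasets(clean, tiny_imputer, cfg, segment_length=L)
    # complete series: tiling and greedy extraction agree, nothing to repair
    assert len(data.reconstructed) == len(data.standard)


def test_reconstructed_count_equals_standard_plus_repairable(gappy_dataset, tiny_imputer):
    observed, _, _ = gappy_dataset
    cfg = sc.ClassConfig(test_fraction=0.25, train_fraction=0.65, val_fraction=0.10,
                         rng_seed=1)
    data = sc.build_datasets(observed, tiny_imputer, cfg, segment_length=L)
    test_trees = {s.tree_id for s in data.test}
    n_repairable = 0
    n_complete_tiles = 0
    for s in observed:
        if s.tree_id in test_trees:
            continue
        values = s.data[list(MEASURED_CHANNELS)].to_numpy()
        for start in range(0, len(values) - L + 1, L):
            frac = float(np.isnan(values[start : start + L]).any(axis=1).mean())
            if frac == 0.0:
                n_complete_tiles += 1
            elif frac < cfg.reconstruction_threshold:
                n_repairable += 1
    assert len(data.reconstructed) == n_complete_tiles + n_repairable
    # greedy extraction can only find at least as many complete windows as
    # the fixed tiling (it may re-anchor after gaps)
    assert len(data.standard) >= n_complete_tiles


def test_resnet_outputs_probabilities():
    net = sc.build_resnet(3, 8, filters=(4, 8, 8), seed=0)
    x = np.random.default_rng(0).random((5, 32, 8)).astype(np.float32)
    logits = net.predict(x)
    from dendrofill.nn import softmax

    p = softmax(logits)
    assert p.shape == (5, 3)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p >= 0).all()
    assert np.isfinite(net.predict(np.zeros((2, 32, 8), dtype=np.float32))).all()


def test_resnet_shortcut_projection_rule():
    net = sc.build_resnet(2, 8, filters=(4, 8, 8), seed=0)
    blocks = [l for l in net.net.layers if hasattr(l, "shortcut")]
    assert len(blocks) == 3
    # projections exactly where input/output channel counts differ
    assert blocks[0].shortcut is not None  # 8 -> 4
    assert blocks[1].shortcut is not None  # 4 -> 8
    assert blocks[2].shortcut is None      # 8 -> 8


def test_resnet_rejects_single_class():
    with pytest.raises(ValueError):
        sc.build_resnet(1, 8)


def test_run_experiment_leakage_guard(gappy_dataset, tiny_imputer):
    observed, _, _ = gappy_dataset
    cfg = sc.ClassConfig(test_fraction=0.25, train_fraction=0.65, val_fraction=0.10,
                         rng_seed=1)
    data = sc.build_datasets(observed, tiny_imputer, cfg, segment_length=L)
    # inject a test tree's segment into the standard variant
    poisoned = sc.ClassificationData(
        standard=data.standard + [data.test[0]],
        reconstructed=data.reconstructed,
        test=data.test,
        species=data.species,
        counts=data.counts,
    )
    with pytest.raises(AssertionError, match="leakage"):
        sc.run_experiment(poisoned, cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        sc.ClassConfig(test_fraction=0.5, train_fraction=0.6, val_fraction=0.1)
    with pytest.raises(ValueError):
        sc.ClassConfig(reconstruction_threshold=1.5)


def test_confusion_matrix_rows_sum_to_100(gappy_dataset, tiny_imputer):
    """A miniature end-to-end run: averaged confusion rows are percentages."""
    observed, _, _ = gappy_dataset
    cfg = sc.ClassConfig(
        test_fraction=0.25, train_fraction=0.65, val_fraction=0.10,
        epochs=3, patience=3, repetitions=2, filters=(4, 8, 8),
        batch_size=16, rng_seed=3,
    )
    data = sc.build_datasets(observed, tiny_imputer, cfg, segment_length=L)
    results = sc.run_experiment(data, cfg)
    assert set(results) == {"standard", "reconstructed"}
    for cm in results.values():
        assert cm.matrix.shape == (2, 2)
        assert np.allclose(cm.matrix.sum(axis=1), 100.0, atol=0.5)
        assert 0.0 <= cm.accuracy <= 100.0
        assert 0.0 <= cm.weighted_accuracy <= 100.0
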