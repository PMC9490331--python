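"""Cleaning, segment extraction, normalization and tree-atomic splitting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dendrofill import preprocess as pp
from dendrofill import timeseries_core as tsc


def _series_from_sr(sr, freq="h", start="2021-06-01", tree_id="t0"):
    n = len(sr)
    df = pd.DataFrame(
        {c: np.zeros(n) for c in tsc.MEASURED_CHANNELS},
        index=pd.date_range(start, periods=n, freq=freq),
    )
    df["SR"] = np.asarray(sr, dtype=float)
    return tsc.MultiChannelSeries(tree_id, "sp", "s0", df)


# ---------------------------------------------------------------------------
# Hourly coarse-graining
# ---------------------------------------------------------------------------


def test_coarse_grain_means_and_missing_hours():
    sr = [1, 2, 3, 4, 5, 6] + [2, np.nan, 4, np.nan, 6, np.nan] + [np.nan] * 6
    s = _series_from_sr(sr, freq="10min")
    hourly = pp.coarse_grain_hourly(s)
    out = hourly.data["SR"].to_numpy()
    assert out[0] == pytest.approx(3.5)   # mean of 1..6
    assert out[1] == pytest.approx(4.0)   # mean of observed {2, 4, 6}
    assert np.isnan(out[2])               # all six samples missing


def test_coarse_grain_rejects_off_grid_timestamps():
    idx = pd.date_range("2021-06-01", periods=6, freq="7min")
    df = pd.DataFrame({c: np.zeros(6) for c in tsc.MEASURED_CHANNELS}, index=idx)
    s = tsc.MultiChannelSeries("t", "sp", "s", df)
    with pytest.raises(ValueError, match="10-minute grid"):
        pp.coarse_grain_hourly(s)


# ---------------------------------------------------------------------------
# Jump filter
# ---------------------------------------------------------------------------


def test_filter_jumps_level_shift_removes_only_first_value():
    """A step change flags the value ending the jump but does not cascade:
    the follower is close to its raw predecessor and survives."""
    s = _series_from_sr([100.0, 350.0, 360.0])
    out, frac = pp.filter_jumps(s, 200.0)
    sr = out.data["SR"].to_numpy()
    assert np.isnan(sr[1])            # |350-100| = 250 > 200
    assert sr[2] == 360.0             # close to raw predecessor 350
    assert frac == pytest.approx(1 / 3)


def test_filter_jumps_spike_only_removes_one_value():
    # the spike's successor is close to the retained context (100), so a
    # lone spike costs exactly one observation
    s = _series_from_sr([100.0, 350.0, 110.0, 120.0])
    out, frac = pp.filter_jumps(s, 200.0)
    sr = out.data["SR"].to_numpy()
    assert np.isnan(sr[1])
    assert sr[2] == 110.0 and sr[3] == 120.0
    assert frac == pytest.approx(0.25)


def test_filter_jumps_no_op_below_threshold_and_infinite_threshold(rng):
    s = _series_from_sr([100.0, 150.0, 200.0])
    out, frac = pp.filter_jumps(s, 200.0)
    assert frac == 0.0
    assert (out.data["SR"] == s.data["SR"]).all()

    walk = np.cumsum(rng.normal(0, 150, size=200))
    s2 = _series_from_sr(walk)
    out2, frac2 = pp.filter_jumps(s2, np.inf)
    assert frac2 == 0.0
    n_obs = lambda x: int((~x.data["SR"].isna()).sum())
    assert n_obs(out2) == n_obs(s2)


def test_filter_jumps_never_increases_observations(rng):
    sr = rng.normal(0, 120, size=300)
    sr[rng.random(300) < 0.2] = np.nan
    s = _series_from_sr(sr)
    out, _ = pp.filter_jumps(s, 200.0)
    assert int(out.data["SR"].notna().sum()) <= int(s.data["SR"].notna().sum())
    # non-SR channels untouched
    assert (out.data["temp"] == s.data["temp"]).all()


def test_filter_jumps_rejects_bad_threshold():
    with pytest.raises(ValueError):
        pp.filter_jumps(_series_from_sr([1.0]), 0.0)


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------


def test_extract_segments_fully_observed_is_tiled():
    s = _series_from_sr(np.zeros(300))
    segs = pp.extract_segments(s, 100)
    assert [seg.start for seg in segs] == [s.timestamps[0], s.timestamps[100], s.timestamps[200]]
    assert all(seg.length == 100 for seg in segs)
    assert segs[0].channels == tsc.CHANNEL_NAMES


def test_extract_segments_restarts_after_missing_stamp():
    sr = np.zeros(500)
    sr[100] = np.nan
    segs = pp.extract_segments(_series_from_sr(sr), 200)
    assert segs[0].start == _series_from_sr(sr).timestamps[101]


def test_extract_segments_empty_cases():
    assert pp.extract_segments(_series_from_sr(np.zeros(50)), 100) == []
    sr = np.full(300, np.nan)
    assert pp.extract_segments(_series_from_sr(sr), 100) == []


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_extract_segments_disjoint_and_complete(seed):
    rng = np.random.default_rng(seed)
    sr = np.zeros(400)
    sr[rng.random(400) < 0.05] = np.nan
    s = _series_from_sr(sr)
    segs = pp.extract_segments(s, 50)
    spans = []
    for seg in segs:
        assert not np.isnan(seg.values).any()
        i0 = int((s.timestamps == seg.start).argmax())
        assert not np.isnan(sr[i0 : i0 + 50]).any()
        spans.append((i0, i0 + 50))
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        assert a1 <= b0  # disjoint and ordered


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def test_normalize_affine_map_and_constant_channel():
    s = _series_from_sr([10.0, 20.0, 30.0])
    seg = pp.extract_segments(s, 3)[0]
    normed = pp.normalize_segment(seg)
    sr_col = normed.values[:, list(normed.channels).index("SR")]
    assert sr_col == pytest.approx([0.0, 0.5, 1.0])
    temp_col = normed.values[:, list(normed.channels).index("temp")]
    assert (temp_col == 0.0).all()  # constant channel maps to zero
    lo, hi = normed.norm_params[list(normed.channels).index("temp")]
    assert lo == hi == 0.0


def test_normalize_denormalize_round_trip(clean_segments):
    for seg in clean_segments[:10]:
        restored = pp.denormalize_segment(seg)
        # rebuild the un-normalized values from the stored parameters
        lo = seg.norm_params[:, 0]
        hi = seg.norm_params[:, 1]
        renormed = (restored - lo) / np.where(hi > lo, hi - lo, 1.0)
        assert np.allclose(renormed, seg.values, atol=1e-9)
        assert seg.values.min() >= 0.0 and seg.values.max() <= 1.0


# ---------------------------------------------------------------------------
# Tree-atomic splitting
# ---------------------------------------------------------------------------


def _fake_segments(counts: dict[str, int]):
    segs = []
    for tree, n in counts.items():
        for k in range(n):
            segs.append(
                pp.Segment(
                    tree_id=tree,
                    species="sp",
                    start=pd.Timestamp("2021-01-01") + pd.Timedelta(hours=k),
                    values=np.zeros((4, len(tsc.CHANNEL_NAMES))),
                    channels=tsc.CHANNEL_NAMES,
                )
            )
    return segs


def test_split_by_tree_exact_on_equal_counts():
    segs = _fake_segments({f"t{i}": 10 for i in range(10)})
    assignment = pp.split_by_tree(segs, {"trainval": 0.8, "test": 0.2}, rng_seed=5)
    test_trees = [t for t, v in assignment.items() if v == "test"]
    assert len(test_trees) == 2


def test_split_by_tree_is_tree_atomic_and_total(clean_segments):
    assignment = pp.split_by_tree(
        clean_segments, {"train": 0.6, "val": 0.2, "test": 0.2}, rng_seed=0
    )
    groups = pp.split_segments(clean_segments, assignment)
    assert sum(len(v) for v in groups.values()) == len(clean_segments)
    for name, segs in groups.items():
        for seg in segs:
            assert assignment[seg.tree_id] == name
    assert set(assignment.values()) == {"train", "val", "test"}


def test_split_by_tree_deterministic_and_errors():
    segs = _fake_segments({"a": 5, "b": 5, "c": 5})
    a1 = pp.split_by_tree(segs, {"x": 0.5, "y": 0.5}, rng_seed=9)
    a2 = pp.split_by_tree(segs, {"x": 0.5, "y": 0.5}, rng_seed=9)
    assert a1 == a2
    with pytest.raises(ValueError, match="at least"):
        pp.split_by_tree(_fake_segments({"a": 5}), {"x": 0.5, "y": 0.5})


def test_segment_store_round_trip(tmp_path, clean_segments):
    path = tmp_path / "segments.npz"
    pp.save_segments(clean_segments, path)
    back = pp.load_segments(path)
    assert len(back) == len(clean_segments)
    for a, b in zip(clean_segments, back):
        assert a.tree_id == b.tree_id and a.species == b.species
        assert a.start == b.start
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.norm_params, b.norm_params)
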