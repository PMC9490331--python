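"""Cleaning and segment preparation.

Raw dendrometer records arrive at 10-minute resolution and are coarse-grained
to hourly means. Unphysical jumps in the stem-radius channel (mechanical
disturbances of the sensor) are removed with an absolute-difference filter.
Model-ready data are fixed-length, fully observed windows ("segments") of all
channels, min-max normalized per channel, and split into train/validation/test
sets at the level of whole trees so that no tree leaks across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .timeseries_core import (
    AUXILIARY_CHANNEL,
    CHANNEL_NAMES,
    MEASURED_CHANNELS,
    TARGET_CHANNEL,
    MultiChannelSeries,
)

__all__ = [
    "PreprocessConfig",
    "Segment",
    "coarse_grain_hourly",
    "filter_jumps",
    "extract_segments",
    "normalize_segment",
    "denormalize_segment",
    "split_by_tree",
    "save_segments",
    "load_segments",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning and segmentation parameters.

    jump_threshold: maximum plausible hour-to-hour change in stem radius, in
    micrometres; larger jumps are treated as sensor artefacts and removed.
    segment_length_hours: window length of a training segment (720 h = 30 d).
    test_fraction: share of segments reserved (by whole trees) for testing.
    val_fraction: share of the remaining segments used for validation.
    """

    jump_threshold: float = 200.0
    segment_length_hours: int = 720
    test_fraction: float = 0.20
    val_fraction: float = 0.20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.segment_length_hours < 2:
            raise ValueError("segment_length_hours must be >= 2")
        for f in (self.test_fraction, self.val_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0, 1)")


@dataclass
class Segment:
    """A fully observed fixed-length window of all channels of one tree.

    ``values`` has shape (segment_length, n_channels) in the order of
    ``channels`` (measured channels plus the auxiliary time-of-day channel
    last). ``norm_params`` maps channel -> (min, max) in original units once
    the segment has been normalized to [0, 1]; None while un-normalized.
    """

    tree_id: str
    species: str
    start: pd.Timestamp
    values: np.ndarray
    channels: tuple[str, ...]
    norm_params: np.ndarray | None = None  # (n_channels, 2) of (min, max)

    @property
    def normalized(self) -> bool:
        return self.norm_params is not None

    @property
    def length(self) -> int:
        return int(self.values.shape[0])

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    @property
    def segment_id(self) -> str:
        return f"{self.tree_id}@{self.start.isoformat()}"


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def coarse_grain_hourly(series: MultiChannelSeries) -> MultiChannelSeries:
    """Average 10-minute samples to an hourly grid.

    Each hourly value is the arithmetic mean of the observed sub-hour samples
    of that hour; an hour with no observed sample is missing. Timestamps must
    sit on the 10-minute grid.
    """
    idx = series.timestamps
    offset = (idx.minute % 10).to_numpy()
    if (offset != 0).any() or (idx.second.to_numpy() != 0).any():
        raise ValueError("raw timestamps must be aligned to the 10-minute grid")
    hourly = series.data.groupby(series.data.index.floor("h")).mean()
    full = pd.date_range(hourly.index[0], hourly.index[-1], freq="h")
    hourly = hourly.reindex(full)
    hourly.index.name = series.data.index.name
    return MultiChannelSeries(series.tree_id, series.species, series.site_id, hourly)


def filter_jumps(
    series: MultiChannelSeries, jump_threshold: float = 200.0
) -> tuple[MultiChannelSeries, float]:
    """Remove unphysical jumps from the stem-radius channel.

    An observed SR value is flagged as a sensor artefact when it differs by
    more than ``jump_threshold`` (micrometres) from *both* the last retained
    observed value and the immediately preceding raw observation. Requiring
    both references means an isolated spike costs exactly one observation
    (its successor is close to the retained context) while a genuine level
    shift (sensor re-anchoring) removes only the first value after the jump
    instead of cascading. Other channels are untouched. Returns the cleaned
    series and the flagged fraction of observed SR values.
    """
    if jump_threshold <= 0:
        raise ValueError("jump_threshold must be positive")
    out = series.copy()
    sr = out.data[TARGET_CHANNEL].to_numpy(copy=True)
    observed = np.flatnonzero(~np.isnan(sr))
    flagged = 0
    last_retained: float | None = None
    prev_raw: float | None = None
    for i in observed:
        value = sr[i]
        jumped = (
            last_retained is not None
            and abs(value - last_retained) > jump_threshold
            and abs(value - prev_raw) > jump_threshold
        )
        if jumped:
            sr[i] = np.nan
            flagged += 1
        else:
            last_retained = value
        prev_raw = value
    out.data[TARGET_CHANNEL] = sr
    frac = flagged / len(observed) if len(observed) else 0.0
    return out, frac


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------


def extract_segments(
    series: MultiChannelSeries, segment_length_hours: int = 720
) -> list[Segment]:
    """Greedy left-to-right extraction of disjoint fully observed windows.

    Starting from the earliest stamp, a segment is emitted whenever the next
    ``segment_length_hours`` stamps are observed in every measured channel;
    the scan then advances by the segment length. On hitting a missing entry
    the scan restarts just after it. The auxiliary time-of-day channel is
    appended to each emitted segment.
    """
    L = segment_length_hours
    values = series.data[list(MEASURED_CHANNELS)].to_numpy()
    ok = ~np.isnan(values).any(axis=1)
    tod = series.time_of_day()
    n = len(ok)
    segments: list[Segment] = []
    i = 0
    while i + L <= n:
        window = ok[i : i + L]
        if window.all():
            mat = np.column_stack([values[i : i + L], tod[i : i + L]])
            segments.append(
                Segment(
                    tree_id=series.tree_id,
                    species=series.species,
                    start=series.timestamps[i],
                    values=mat,
                    channels=CHANNEL_NAMES,
                )
            )
            i += L
        else:
            i += int(np.flatnonzero(~window)[0]) + 1
    return segments


def normalize_segment(segment: Segment) -> Segment:
    """Min-max normalize each channel of the segment to [0, 1].

    Uses the segment's own per-channel minimum and maximum, which are stored
    for inversion. A constant channel maps to 0 everywhere.
    """
    if segment.normalized:
        raise ValueError("segment already normalized")
    v = segment.values
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    span = hi - lo
    safe = np.where(span == 0.0, 1.0, span)
    out = (v - lo) / safe
    return Segment(
        tree_id=segment.tree_id,
        species=segment.species,
        start=segment.start,
        values=out,
        channels=segment.channels,
        norm_params=np.column_stack([lo, hi]),
    )


def denormalize_segment(segment: Segment, values: np.ndarray | None = None) -> np.ndarray:
    """Map a normalized matrix back to original units via stored (min, max)."""
    if not segment.normalized:
        raise ValueError("segment carries no normalization parameters")
    v = segment.values if values is None else values
    lo = segment.norm_params[:, 0]
    hi = segment.norm_params[:, 1]
    return v * (hi - lo) + lo


# ---------------------------------------------------------------------------
# Tree-atomic splitting
# ---------------------------------------------------------------------------


def split_by_tree(
    segments: Sequence[Segment],
    fractions: Mapping[str, float],
    rng_seed: int = 0,
) -> dict[str, str]:
    """Assign whole trees to named sets so segment counts match ``fractions``.

    Trees are shuffled with the seed, ordered by descending segment count,
    and greedily assigned to the set with the largest remaining segment
    deficit; every segment of a tree inherits the tree's set, preventing
    leakage between sets.
    """
    total_frac = sum(fractions.values())
    if abs(total_frac - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    counts: dict[str, int] = {}
    for s in segments:
        counts[s.tree_id] = counts.get(s.tree_id, 0) + 1
    trees = list(counts)
    if len(trees) < len(fractions):
        raise ValueError(
            f"need at least {len(fractions)} trees for {len(fractions)} sets, got {len(trees)}"
        )
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(trees)
    trees.sort(key=lambda t: -counts[t])  # stable: ties keep shuffled order
    total = sum(counts.values())
    targets = {name: f * total for name, f in fractions.items()}
    assigned = {name: 0 for name in fractions}
    names = list(fractions)
    out: dict[str, str] = {}
    for i, tree in enumerate(trees):
        # guarantee every set receives at least one tree
        unfilled = [n for n in names if assigned[n] == 0]
        remaining = len(trees) - i
        if 0 < len(unfilled) == remaining:
            choice = unfilled[0]
        else:
            choice = max(names, key=lambda n: targets[n] - assigned[n])
        out[tree] = choice
        assigned[choice] += counts[tree]
    return out


def split_segments(
    segments: Sequence[Segment], assignment: Mapping[str, str]
) -> dict[str, list[Segment]]:
    """Group segments by their tree's assigned set."""
    out: dict[str, list[Segment]] = {}
    for s in segments:
        out.setdefault(assignment[s.tree_id], []).append(s)
    return out


# ---------------------------------------------------------------------------
# Segment store
# ---------------------------------------------------------------------------


def save_segments(segments: Sequence[Segment], path: str | Path) -> None:
    """Persist segments to a single ``.npz`` container."""
    if not segments:
        raise ValueError("no segments to save")
    channels = segments[0].channels
    norm = [
        s.norm_params if s.norm_params is not None else np.full((len(channels), 2), np.nan)
        for s in segments
    ]
    np.savez_compressed(
        Path(path),
        values=np.stack([s.values for s in segments]),
        norm_params=np.stack(norm),
        tree_id=np.array([s.tree_id for s in segments]),
        species=np.array([s.species for s in segments]),
        start=np.array([s.start.isoformat() for s in segments]),
        channels=np.array(channels),
    )


def load_segments(path: str | Path) -> list[Segment]:
    with np.load(Path(path), allow_pickle=False) as z:
        channels = tuple(str(c) for c in z["channels"])
        out = []
        for i in range(z["values"].shape[0]):
            norm = z["norm_params"][i]
            out.append(
                Segment(
                    tree_id=str(z["tree_id"][i]),
                    species=str(z["species"][i]),
                    start=pd.Timestamp(str(z["start"][i])),
                    values=z["values"][i],
                    channels=channels,
                    norm_params=None if np.isnan(norm).all() else norm,
                )
            )
    return out
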