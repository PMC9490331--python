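"""Data model for multi-channel tree stem-radius time series.

A point dendrometer records the radius of a tree stem (SR, in micrometres)
at sub-hourly resolution; weather and soil sensors at the same site provide
covariate channels (temperature, relative humidity, vapour pressure deficit,
solar radiation, soil water potential, precipitation). Each tree therefore
owns a long multi-channel hourly time series with substantial stretches of
missing data in individual channels.

This module defines the series container, CSV readers/writers, and the
descriptive missing-data statistics (which channel combinations are missing
simultaneously, and the distribution of gap lengths per channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelSpec",
    "CHANNELS",
    "MEASURED_CHANNELS",
    "TARGET_CHANNEL",
    "AUXILIARY_CHANNEL",
    "MultiChannelSeries",
    "GapRun",
    "read_series",
    "write_series",
    "read_metadata",
    "write_metadata",
    "missing_pattern_table",
    "gap_lengths",
    "gap_length_percentiles",
]


@dataclass(frozen=True)
class ChannelSpec:
    """One channel of the multi-channel series.

    role: ``target`` (the channel the imputer is judged on), ``covariate``
    (a measured environmental channel), or ``auxiliary`` (derived from the
    timestamp, never missing, never masked).
    """

    name: str
    units: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ("target", "covariate", "auxiliary"):
            raise ValueError(f"unknown channel role: {self.role!r}")


#: Canonical channel set: seven measured properties plus a time-of-day
#: auxiliary channel (hour of day scaled to [0, 1]).
CHANNELS: tuple[ChannelSpec, ...] = (
    ChannelSpec("SR", "um", "target"),
    ChannelSpec("temp", "degC", "covariate"),
    ChannelSpec("rh", "%", "covariate"),
    ChannelSpec("vpd", "kPa", "covariate"),
    ChannelSpec("rad", "W m-2", "covariate"),
    ChannelSpec("swp", "kPa", "covariate"),
    ChannelSpec("total_precip", "mm", "covariate"),
    ChannelSpec("tod", "1", "auxiliary"),
)

TARGET_CHANNEL = "SR"
AUXILIARY_CHANNEL = "tod"
MEASURED_CHANNELS: tuple[str, ...] = tuple(
    c.name for c in CHANNELS if c.role != "auxiliary"
)
CHANNEL_NAMES: tuple[str, ...] = tuple(c.name for c in CHANNELS)

_names = [c.name for c in CHANNELS]
if len(set(_names)) != len(_names):  # pragma: no cover - guarded at import
    raise RuntimeError("channel names must be unique")
del _names


@dataclass
class MultiChannelSeries:
    """One tree's hourly record across all measured channels.

    ``data`` is a DataFrame indexed by a strictly increasing hourly
    DatetimeIndex with one column per measured channel; NaN marks a missing
    observation. The auxiliary time-of-day channel is derived on demand and
    is not stored.
    """

    tree_id: str
    species: str
    site_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("series index must be a DatetimeIndex")
        if idx.has_duplicates:
            raise ValueError(f"duplicate timestamps in series {self.tree_id}")
        if not idx.is_monotonic_increasing:
            raise ValueError(f"timestamps not increasing in series {self.tree_id}")
        self.data.index.name = "timestamp"

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index  # type: ignore[return-value]

    @property
    def missing(self) -> pd.DataFrame:
        """Boolean frame, True where an observation is absent."""
        return self.data.isna()

    def n_missing(self, channel: str | None = None) -> int:
        if channel is None:
            return int(self.data.isna().to_numpy().sum())
        return int(self.data[channel].isna().sum())

    def validate_physical_ranges(self) -> None:
        """Assert physically meaningful bounds on observed values."""
        d = self.data
        checks = [
            ("rh", lambda s: (s >= 0) & (s <= 100)),
            ("rad", lambda s: s >= 0),
            ("total_precip", lambda s: s >= 0),
        ]
        for name, ok in checks:
            if name not in d.columns:
                continue
            obs = d[name].dropna()
            if len(obs) and not bool(ok(obs).all()):
                raise ValueError(
                    f"channel {name} of tree {self.tree_id} violates its physical range"
                )

    def time_of_day(self) -> np.ndarray:
        """Auxiliary channel: hour of day scaled to [0, 1] (0h -> 0, 23h -> 1)."""
        return self.timestamps.hour.to_numpy(dtype=float) / 23.0

    def copy(self) -> "MultiChannelSeries":
        return MultiChannelSeries(
            self.tree_id, self.species, self.site_id, self.data.copy()
        )


@dataclass(frozen=True)
class GapRun:
    """A maximal run of consecutive missing hourly stamps in one channel."""

    channel: str
    start: pd.Timestamp
    length_hours: int

    def __post_init__(self) -> None:
        if self.length_hours <= 0:
            raise ValueError("gap length must be positive")


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

_TIMESTAMP_COL = "timestamp"


def read_series(
    path: str | Path,
    tree_id: str | None = None,
    species: str = "",
    site_id: str = "",
    channels: Sequence[str] | None = None,
) -> MultiChannelSeries:
    """Read one tree's series from CSV (ISO-8601 timestamps, empty cell = missing).

    Rows are sorted by timestamp; duplicate timestamps are an error; columns
    not in the expected channel set are an error.
    """
    path = Path(path)
    expected = list(channels) if channels is not None else list(MEASURED_CHANNELS)
    df = pd.read_csv(path, parse_dates=[_TIMESTAMP_COL])
    unknown = [c for c in df.columns if c != _TIMESTAMP_COL and c not in expected]
    if unknown:
        raise ValueError(f"unknown channel column(s) in {path.name}: {unknown}")
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing channel column(s) in {path.name}: {missing_cols}")
    df = df.sort_values(_TIMESTAMP_COL).set_index(_TIMESTAMP_COL)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate timestamps in {path.name}: first {dupes[0]}")
    df = df[expected].astype(float)
    return MultiChannelSeries(
        tree_id=tree_id if tree_id is not None else path.stem,
        species=species,
        site_id=site_id,
        data=df,
    )


def write_series(series: MultiChannelSeries, path: str | Path) -> None:
    """Inverse of :func:`read_series`; missing values become empty cells."""
    df = series.data.copy()
    df.index.name = _TIMESTAMP_COL
    df.to_csv(path, na_rep="")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Tree metadata table with columns tree_id, species, site_id."""
    df = pd.read_csv(path, dtype=str)
    required = {"tree_id", "species", "site_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def load_dataset(data_dir: str | Path) -> list[MultiChannelSeries]:
    """Load every per-tree CSV listed in ``metadata.csv`` under ``data_dir``."""
    data_dir = Path(data_dir)
    meta = read_metadata(data_dir / "metadata.csv")
    out = []
    for row in meta.itertuples(index=False):
        out.append(
            read_series(
                data_dir / f"{row.tree_id}.csv",
                tree_id=row.tree_id,
                species=row.species,
                site_id=row.site_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Missing-data statistics
# ---------------------------------------------------------------------------


def missing_pattern_table(series: Iterable[MultiChannelSeries]) -> pd.DataFrame:
    """Tabulate which channel combinations are missing simultaneously.

    One row per distinct set of simultaneously missing channels among the
    time stamps that have at least one missing channel, with the stamp count,
    the share within all missing stamps (%), and the share of all stamps (%).
    Rows are sorted by descending count.
    """
    counts: dict[tuple[str, ...], int] = {}
    total_stamps = 0
    for s in series:
        miss = s.missing.to_numpy()
        total_stamps += miss.shape[0]
        any_missing = miss.any(axis=1)
        cols = np.asarray(s.channels)
        for row in miss[any_missing]:
            key = tuple(cols[row])
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return pd.DataFrame(
            columns=["channels", "count", "share_of_missing_pct", "share_of_total_pct"]
        )
    total_missing = sum(counts.values())
    rows = [
        {
            "channels": ", ".join(combo),
            "count": n,
            "share_of_missing_pct": 100.0 * n / total_missing,
            "share_of_total_pct": 100.0 * n / total_stamps,
        }
        for combo, n in counts.items()
    ]
    table = pd.DataFrame(rows).sort_values(
        ["count", "channels"], ascending=[False, True], ignore_index=True
    )
    return table


def gap_lengths(series: MultiChannelSeries, channel: str) -> list[GapRun]:
    """All maximal missing runs of ``channel`` as :class:`GapRun` objects."""
    if channel not in series.channels:
        raise KeyError(f"unknown channel {channel!r}")
    miss = series.data[channel].isna().to_numpy()
    runs: list[GapRun] = []
    n = len(miss)
    i = 0
    while i < n:
        if miss[i]:
            j = i
            while j < n and miss[j]:
                j += 1
            runs.append(GapRun(channel, series.timestamps[i], j - i))
            i = j
        else:
            i += 1
    return runs


def gap_length_percentiles(
    runs: Sequence[GapRun], q: Sequence[float] = (50, 90, 95)
) -> dict[float, float]:
    """Percentiles (linear interpolation) of gap lengths in hours.

    Computed on the full gap set; no tail truncation.
    """
    if not runs:
        return {float(p): float("nan") for p in q}
    lengths = np.array([r.length_hours for r in runs], dtype=float)
    return {float(p): float(np.percentile(lengths, p)) for p in q}
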