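"""Artificial data gaps and sentinel encoding.

Training and evaluating a reconstruction network requires segments whose
ground truth is known. Gaps of a fixed length (default 240 h = 10 days) are
therefore cut into fully observed segments: the stem-radius channel always
receives a gap, each other measured channel receives one independently with
probability ``p_gap`` (at least one non-SR channel is always gapped), and the
removed entries are encoded with an out-of-range sentinel value of -1 so the
network can tell them from real [0, 1]-normalized data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .timeseries_core import AUXILIARY_CHANNEL, CHANNEL_NAMES, TARGET_CHANNEL

__all__ = ["GapMask", "make_gap_mask", "apply_sentinel", "SENTINEL"]

SENTINEL = -1.0


@dataclass
class GapMask:
    """Boolean matrix (segment_length, n_channels); True = artificially removed."""

    mask: np.ndarray
    channels: tuple[str, ...]
    gap_length_hours: int

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise TypeError("mask must be boolean")
        if self.mask.shape[1] != len(self.channels):
            raise ValueError("mask width must match channel count")

    def gapped_channels(self) -> list[str]:
        return [c for i, c in enumerate(self.channels) if self.mask[:, i].any()]


def make_gap_mask(
    segment_length: int,
    channels: Sequence[str] = CHANNEL_NAMES,
    gap_length: int = 240,
    rng: np.random.Generator | int | None = None,
    p_gap: float = 0.5,
) -> GapMask:
    """Draw one artificial gap mask for a segment.

    The SR channel is always gapped; each other measured channel is gapped
    independently with probability ``p_gap``, redrawn until at least one
    non-SR channel carries a gap; the auxiliary time-of-day channel never is.
    Every gap is a single run of exactly ``gap_length`` stamps whose start is
    uniform on [0, segment_length - gap_length].
    """
    if gap_length >= segment_length:
        raise ValueError("gap_length must be smaller than segment_length")
    if not 0.0 < p_gap <= 1.0:
        raise ValueError("p_gap must be in (0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    channels = tuple(channels)
    maskable = [
        c for c in channels if c not in (TARGET_CHANNEL, AUXILIARY_CHANNEL)
    ]
    while True:
        gapped = [c for c in maskable if rng.random() < p_gap]
        if gapped:
            break
    gapped.append(TARGET_CHANNEL)
    mask = np.zeros((segment_length, len(channels)), dtype=bool)
    for name in channels:  # fixed draw order keeps masks seed-reproducible
        if name not in gapped:
            continue
        start = int(rng.integers(0, segment_length - gap_length + 1))
        mask[start : start + gap_length, channels.index(name)] = True
    return GapMask(mask=mask, channels=channels, gap_length_hours=gap_length)


def apply_sentinel(
    values: np.ndarray, mask: GapMask | np.ndarray, sentinel: float = SENTINEL
) -> np.ndarray:
    """Replace masked entries of a [0, 1]-normalized segment with the sentinel.

    All unmasked entries are returned unchanged, so the output range is
    {sentinel} union [0, 1].
    """
    m = mask.mask if isinstance(mask, GapMask) else mask
    if m.shape != values.shape:
        raise ValueError(f"mask shape {m.shape} != values shape {values.shape}")
    if np.nanmin(values) < 0.0 or np.nanmax(values) > 1.0:
        raise ValueError("apply_sentinel expects a [0, 1]-normalized segment")
    out = values.copy()
    out[m] = sentinel
    nan = np.isnan(out)  # real missing values get the same encoding
    out[nan] = sentinel
    return out
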