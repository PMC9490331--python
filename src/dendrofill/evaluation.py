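"""Model assessment: inpainting substitution and gap-only error statistics.

A reconstruction network predicts every entry of a segment, but only the
artificially removed entries are unknown, so the reconstructed signal keeps
the observed data and substitutes predictions at gap positions only
(inpainting), and the error metric is the mean squared error over the gap
entries alone. Per-model error distributions are summarized with box-plot
statistics (quartiles, 1.5*IQR whiskers, mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gap_simulation import GapMask
from .timeseries_core import TARGET_CHANNEL

__all__ = [
    "EvaluationRecord",
    "BoxplotSummary",
    "inpaint",
    "gap_mse",
    "evaluate_segment",
    "summarize",
    "summarize_models",
]


@dataclass(frozen=True)
class EvaluationRecord:
    """Gap-only errors of one model on one segment.

    ``per_channel`` holds the gap-only MSE for each channel that actually
    carries a gap; channels without gaps are absent (never reported as 0).
    ``overall`` is the gap-only MSE over all masked entries; the SR channel
    entry is the headline figure.
    """

    segment_id: str
    model_id: str
    per_channel: dict[str, float]
    overall: float


@dataclass(frozen=True)
class BoxplotSummary:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    mean: float
    n: int


def inpaint(
    original: np.ndarray, prediction: np.ndarray, mask: GapMask | np.ndarray
) -> np.ndarray:
    """Substitute predictions at masked positions only."""
    m = mask.mask if isinstance(mask, GapMask) else mask
    if original.shape != prediction.shape or original.shape != m.shape:
        raise ValueError("original, prediction and mask shapes must agree")
    return np.where(m, prediction, original)


def gap_mse(
    prediction: np.ndarray,
    truth: np.ndarray,
    mask: GapMask | np.ndarray,
    channel_index: int | None = None,
) -> float:
    """Mean squared error over masked entries only.

    With ``channel_index`` the scope narrows to one channel's masked entries.
    Raises if the scope contains no masked entry (the error is undefined,
    not zero).
    """
    m = mask.mask if isinstance(mask, GapMask) else mask
    if prediction.shape != truth.shape or prediction.shape != m.shape:
        raise ValueError("prediction, truth and mask shapes must agree")
    if channel_index is not None:
        scope = np.zeros_like(m)
        scope[:, channel_index] = m[:, channel_index]
        m = scope
    if not m.any():
        raise ValueError("gap MSE undefined: no masked entries in scope")
    diff = prediction[m] - truth[m]
    return float(np.mean(diff * diff))


def evaluate_segment(
    segment_id: str,
    model_id: str,
    prediction: np.ndarray,
    truth: np.ndarray,
    mask: GapMask,
) -> EvaluationRecord:
    """Per-channel and overall gap-only MSE of one reconstructed segment."""
    per_channel: dict[str, float] = {}
    for i, name in enumerate(mask.channels):
        if mask.mask[:, i].any():
            per_channel[name] = gap_mse(prediction, truth, mask, channel_index=i)
    return EvaluationRecord(
        segment_id=segment_id,
        model_id=model_id,
        per_channel=per_channel,
        overall=gap_mse(prediction, truth, mask),
    )


def sr_errors(records: Iterable[EvaluationRecord]) -> np.ndarray:
    """Headline per-segment errors: gap-only MSE of the SR channel."""
    return np.array(
        [r.per_channel[TARGET_CHANNEL] for r in records if TARGET_CHANNEL in r.per_channel]
    )


def summarize(values: Sequence[float]) -> BoxplotSummary:
    """Box-plot statistics: quartiles by linear interpolation, 1.5*IQR whiskers
    clamped to the data range, and the mean over all values (outliers beyond
    the whiskers are excluded only from whisker positions, never from the
    mean or median)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxplotSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        mean=float(x.mean()),
        n=int(x.size),
    )


def summarize_models(
    errors_by_model: Mapping[str, Sequence[float]], min_records: int = 5
) -> tuple[dict[str, BoxplotSummary], list[str]]:
    """Per-model box-plot summaries plus the ranking by median error."""
    summaries = {}
    for model, errs in errors_by_model.items():
        if len(errs) < min_records:
            raise ValueError(f"model {model!r} has fewer than {min_records} records")
        summaries[model] = summarize(errs)
    ranking = sorted(summaries, key=lambda m: summaries[m].median)
    return summaries, ranking


def records_to_frame(records: Iterable[EvaluationRecord]) -> pd.DataFrame:
    """Long-format table: segment_id, model, channel, gap_mse."""
    rows = []
    for r in records:
        for channel, err in r.per_channel.items():
            rows.append(
                {
                    "segment_id": r.segment_id,
                    "model": r.model_id,
                    "channel": channel,
                    "gap_mse": err,
                }
            )
    return pd.DataFrame(rows, columns=["segment_id", "model", "channel", "gap_mse"])
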