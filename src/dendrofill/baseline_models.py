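"""Reference regression models: {ridge, multi-layer perceptron} x {local, global}.

The baselines predict the stem-radius channel from the other channels of
clean (un-gapped) normalized segments. A *local* model regresses SR at one
time stamp on the covariate values at that same stamp (one sample per
stamp); a *global* model regresses the entire 720-value SR sequence on all
covariate channels of the segment flattened into one vector (one sample per
segment). Covariates must be fully observed at prediction time; inputs with
covariate gaps are rejected — filling those is what the deep models are for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPRegressor

from .gap_simulation import GapMask
from .preprocess import Segment
from .timeseries_core import TARGET_CHANNEL

__all__ = ["BaselineSpec", "BaselineModel", "fit_baseline", "predict_sr"]

_SERIAL_VERSION = 1


@dataclass(frozen=True)
class BaselineSpec:
    """Configuration of one baseline model.

    alpha: ridge regularization strength (the library default of 1.0 changed
    results little in practice, so it stays the default). The perceptron
    starts from the library defaults (one hidden layer of 100 units) with
    early stopping on.
    """

    method: str = "ridge"  # "ridge" | "mlp"
    scope: str = "local"   # "local" | "global"
    alpha: float = 1.0
    fit_intercept: bool = True
    hidden_layer_sizes: tuple[int, ...] = (100,)
    learning_rate_init: float = 1e-3
    early_stopping: bool = True
    max_iter: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("ridge", "mlp"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.scope not in ("local", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def model_id(self) -> str:
        return f"{self.method}_{self.scope}"


@dataclass
class BaselineModel:
    spec: BaselineSpec
    estimator: object
    channels: tuple[str, ...]
    segment_length: int

    @property
    def sr_index(self) -> int:
        return self.channels.index(TARGET_CHANNEL)

    def save(self, path: str | Path) -> None:
        joblib.dump({"version": _SERIAL_VERSION, "model": self}, Path(path))

    @staticmethod
    def load(path: str | Path) -> "BaselineModel":
        blob = joblib.load(Path(path))
        if blob.get("version") != _SERIAL_VERSION:
            raise ValueError(f"unsupported model file version {blob.get('version')}")
        return blob["model"]


def _make_estimator(spec: BaselineSpec):
    if spec.method == "ridge":
        return Ridge(alpha=spec.alpha, fit_intercept=spec.fit_intercept)
    return MLPRegressor(
        hidden_layer_sizes=spec.hidden_layer_sizes,
        learning_rate_init=spec.learning_rate_init,
        early_stopping=spec.early_stopping,
        max_iter=spec.max_iter,
        random_state=spec.rng_seed,
    )


def _covariate_matrix(values: np.ndarray, sr_index: int) -> np.ndarray:
    return np.delete(values, sr_index, axis=1)


def fit_baseline(segments: Sequence[Segment], spec: BaselineSpec) -> BaselineModel:
    """Fit a local or global baseline on clean normalized segments."""
    if not segments:
        raise ValueError("empty training set")
    lengths = {s.length for s in segments}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent segment lengths: {sorted(lengths)}")
    channels = segments[0].channels
    sr_index = channels.index(TARGET_CHANNEL)
    est = _make_estimator(spec)
    if spec.scope == "local":
        X = np.concatenate([_covariate_matrix(s.values, sr_index) for s in segments])
        y = np.concatenate([s.values[:, sr_index] for s in segments])
    else:
        X = np.stack(
            [_covariate_matrix(s.values, sr_index).ravel(order="F") for s in segments]
        )
        y = np.stack([s.values[:, sr_index] for s in segments])
    est.fit(X, y)
    return BaselineModel(
        spec=spec,
        estimator=est,
        channels=tuple(channels),
        segment_length=lengths.pop(),
    )


def predict_sr(
    model: BaselineModel,
    values: np.ndarray,
    mask: GapMask | np.ndarray | None = None,
) -> np.ndarray:
    """Predict the full SR sequence of one segment from its covariates.

    The covariate channels must be fully observed: if ``mask`` marks any
    non-SR entry as missing (or any covariate is NaN), prediction is refused
    with a pointer to the deep models, which accept corrupted covariates.
    """
    sr_index = model.sr_index
    cov = _covariate_matrix(values, sr_index)
    cov_gapped = np.isnan(cov).any()
    if mask is not None:
        m = mask.mask if isinstance(mask, GapMask) else mask
        cov_gapped = cov_gapped or bool(_covariate_matrix(m, sr_index).any())
    if cov_gapped:
        raise ValueError(
            "baseline models need fully observed covariate channels; "
            "use a deep reconstruction model for segments with covariate gaps"
        )
    if values.shape[0] != model.segment_length:
        raise ValueError(
            f"segment length {values.shape[0]} != model length {model.segment_length}"
        )
    if model.spec.scope == "local":
        pred = model.estimator.predict(cov)
    else:
        pred = model.estimator.predict(cov.ravel(order="F")[None, :])[0]
    return np.asarray(pred, dtype=float)
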