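"""Per-tool class weights from forecast next-month usage.

A tool that has been used heavily in the recent past is more relevant to
recommend, so its misclassification should cost more. For each tool a
support vector regression is fitted to its trailing 12 monthly usage
counts (5-fold cross-validated grid search over kernel x degree), the
next month's usage is forecast, and ln(1 + forecast) becomes the tool's
positive class weight w_i in the training loss. The logarithm compresses
the scale: a handful of tools dominate raw usage by orders of magnitude
and would otherwise monopolize the loss.

Tools with no usage data (or a zero forecast) receive a default weight of
1.0 so that no label's loss contribution vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVR

from .corpus_io import UsageSeries
from .encoding import ToolVocabulary
from .errors import ValidationError

# 3 kernels x 2 degrees = 6 candidate regressors per tool
SVR_PARAM_GRID = {"kernel": ["rbf", "poly", "linear"], "degree": [2, 3]}
SVR_CV_FOLDS = 5
DEFAULT_WEIGHT = 1.0


@dataclass(frozen=True)
class ToolWeights:
    """Map from tool index (1..V) to its positive class weight."""

    weight_of: dict[int, float] = field(default_factory=dict)
    default_weight: float = DEFAULT_WEIGHT

    def __post_init__(self) -> None:
        if self.default_weight <= 0 or not np.isfinite(self.default_weight):
            raise ValidationError("default_weight must be positive and finite")
        for idx, w in self.weight_of.items():
            if w <= 0 or not np.isfinite(w):
                raise ValidationError(f"weight for tool index {idx} must be > 0")

    def weight(self, index: int) -> float:
        return self.weight_of.get(index, self.default_weight)

    def vector(self, size: int) -> np.ndarray:
        """Dense weight vector aligned with 0-based label positions."""
        vec = np.full(size, self.default_weight, dtype=np.float64)
        for idx, w in self.weight_of.items():
            if 1 <= idx <= size:
                vec[idx - 1] = w
        return vec

    def to_table(self, vocab: ToolVocabulary) -> pd.DataFrame:
        id_of = vocab.id_of
        rows = [
            {"tool_id": id_of[idx], "weight": w}
            for idx, w in sorted(self.weight_of.items())
            if idx in id_of
        ]
        return pd.DataFrame(rows, columns=["tool_id", "weight"])


def _grid_search(counts: np.ndarray) -> GridSearchCV:
    x = np.arange(1, len(counts) + 1, dtype=float).reshape(-1, 1)
    search = GridSearchCV(
        SVR(),
        SVR_PARAM_GRID,
        cv=SVR_CV_FOLDS,
        scoring="neg_mean_squared_error",
    )
    search.fit(x, counts)
    return search


def fit_usage_trend(series: UsageSeries, return_search: bool = False):
    """Forecast next-month usage by grid-searched SVR.

    Month ordinals 1..12 are the sole regressor feature; the six
    (kernel, degree) combinations are compared by 5-fold cross-validated
    mean squared error and the winner predicts month 13. The forecast is
    clipped below at 0. An all-zero series short-circuits to 0.
    """
    counts = np.asarray(series.counts, dtype=float)
    if np.all(counts == 0):
        return (0.0, None) if return_search else 0.0
    search = _grid_search(counts)
    horizon = np.array([[len(counts) + 1.0]])
    forecast = max(float(search.predict(horizon)[0]), 0.0)
    return (forecast, search) if return_search else forecast


def compute_tool_weights(
    usage: list[UsageSeries], vocab: ToolVocabulary
) -> ToolWeights:
    """Turn usage series into the w_i weight map over the vocabulary.

    weight = ln(1 + forecast); zero forecasts and tools absent from the
    usage table fall back to the default weight so every weight stays
    strictly positive.
    """
    weight_of: dict[int, float] = {}
    for series in usage:
        if series.tool not in vocab:
            continue
        forecast = fit_usage_trend(series)
        w = float(np.log1p(forecast))
        if w > 0:
            weight_of[vocab.index(series.tool)] = w
    return ToolWeights(weight_of=weight_of, default_weight=DEFAULT_WEIGHT)
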