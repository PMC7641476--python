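"""Evaluation metrics for path selection and reporting.

R-squared for quantitative traits, AUC for binary traits.  The AUC is
computed as the exact Mann-Whitney rank statistic (ties counted half),
which equals the trapezoidal area under the ROC curve but is O(n log n)
and tie-exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateResponseError


@dataclass(frozen=True)
class MetricRecord:
    lam: float
    split: str
    value: float
    metric_name: str


def r_squared(y: np.ndarray, prediction: np.ndarray) -> float:
    """1 - SS_res / SS_tot, with SS_tot taken about mean(y) on this split."""
    y = np.asarray(y, dtype=np.float64)
    prediction = np.asarray(prediction, dtype=np.float64)
    if y.shape != prediction.shape:
        raise ValueError("y and prediction must have equal length")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise DegenerateResponseError("R^2 undefined for a constant response")
    ss_res = np.sum((y - prediction) ** 2)
    return float(1.0 - ss_res / ss_tot)


def auc(y: np.ndarray, score: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_case > score_control) + 0.5 P(tie)."""
    y = np.asarray(y)
    score = np.asarray(score, dtype=np.float64)
    if y.shape != score.shape:
        raise ValueError("y and score must have equal length")
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = y.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateResponseError("AUC requires both classes present")
    ranks = rankdata(score)  # average ranks handle ties exactly
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def r_squared_stderr(y: np.ndarray, prediction: np.ndarray) -> float:
    """Delta-method standard error of R^2 (large-sample)."""
    y = np.asarray(y, dtype=np.float64)
    prediction = np.asarray(prediction, dtype=np.float64)
    n = y.shape[0]
    r2 = r_squared(y, prediction)
    # variance of R^2 approx 4 r2 (1-r2)^2 / n for a linear predictor
    return float(np.sqrt(max(4.0 * r2 * (1.0 - r2) ** 2, 0.0) / n))


def auc_stderr_bound(y: np.ndarray) -> float:
    """Upper bound 1 / sqrt(4 * min(n_pos, n_neg)) on the AUC standard error."""
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = y.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateResponseError("AUC requires both classes present")
    return float(1.0 / np.sqrt(4.0 * min(n_pos, n_neg)))
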