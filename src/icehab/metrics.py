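"""Goodness-of-fit metrics used across tuning, evaluation and importance."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["auc", "r_squared"]


def auc(labels, scores) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney pair statistic
    P(score_presence > score_absence) + 0.5 * P(tie) over all
    presence/absence pairs.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def r_squared(observed, predicted, variant: str = "ss") -> float:
    """Coefficient of determination of predictions against observations.

    ``variant="ss"`` (default) is 1 - SS_res/SS_tot, which can be negative
    for predictions worse than the observed mean; ``variant="corr"`` is
    the squared Pearson correlation.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have the same shape")
    if len(observed) < 2:
        raise ValueError("R^2 needs at least 2 observations")
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values have zero variance")
    if variant == "ss":
        ss_res = float(((observed - predicted) ** 2).sum())
        return 1.0 - ss_res / ss_tot
    if variant == "corr":
        if predicted.std() == 0:
            return 0.0
        return float(np.corrcoef(observed, predicted)[0, 1] ** 2)
    raise ValueError(f"unknown variant {variant!r}; use 'ss' or 'corr'")
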