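"""Misclassification-rate accounting for three-group predictions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .simulate import GROUPS

__all__ = ["RateRecord", "misclassification_rates", "confusion_matrix"]


@dataclass(frozen=True)
class RateRecord:
    """Overall and per-group misclassification rates for one fitted model.

    ``group_rates[k-1]`` is the fraction of true-group-``k`` cases whose
    prediction disagrees; ``overall`` is the count-weighted mean of the
    group rates.
    """

    overall: float
    group_rates: tuple[float, float, float]
    method: str = ""
    replication: int = -1
    condition: dict = field(default_factory=dict, hash=False, compare=False)


def misclassification_rates(pred, truth, method: str = "",
                            replication: int = -1, condition: dict | None = None
                            ) -> RateRecord:
    """Score predictions against reference labels, overall and per group.

    Every group must be present in ``truth`` (an absent group has no defined
    rate and is signalled as an error).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    rates = []
    for g in GROUPS:
        mask = truth == g
        if not mask.any():
            raise ValueError(f"group {g} absent from reference labels")
        rates.append(float(np.mean(pred[mask] != g)))
    return RateRecord(float(np.mean(pred != truth)), tuple(rates),
                      method, replication, dict(condition or {}))


def confusion_matrix(pred, truth) -> np.ndarray:
    """3x3 count table with true groups as rows and predicted groups as columns."""
    return _sk_confusion(np.asarray(truth), np.asarray(pred), labels=list(GROUPS))
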