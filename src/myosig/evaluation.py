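"""ROC evaluation of a signature score as a binary cell-identity classifier.

Higher score is always treated as evidence for the positive class — the
direction is never auto-flipped, so a signature that fails to mark its
population shows up as AUC < 0.5 rather than being silently rescued.
Tied scores contribute half a concordant pair, the standard Mann–Whitney
convention, making AUC identical to U/(n1·n0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

__all__ = ["RocResult", "roc_curve", "auc"]


@dataclass
class RocResult:
    thresholds: np.ndarray  # descending score cutoffs (first = +inf sentinel)
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr})

    def plot(self, ax=None, label: str | None = None):
        """ROC curve with the chance diagonal; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.fpr, self.tpr, label=label or f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = labels.astype(int).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if labels.all() or not labels.any():
        raise ValueError("labels contain a single class; ROC is undefined")
    return scores, labels


def roc_curve(scores, labels) -> RocResult:
    """ROC curve of a score against binary labels (True/1 = positive class).

    One point per distinct score threshold plus the (0, 0) endpoint; ties
    collapse to a single threshold.
    """
    scores, labels = _validate(scores, labels)
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    # trapezoid accumulation can stray an ulp outside [0, 1]
    area = float(np.clip(np.trapezoid(tpr, fpr), 0.0, 1.0))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=area)


def auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal; equals tie-aware U/(n1·n0))."""
    return roc_curve(scores, labels).auc
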