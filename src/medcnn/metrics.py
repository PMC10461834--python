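"""Confusion-matrix metrics and the rank-based AUC.

Sensitivity, specificity, accuracy and Matthews' correlation coefficient
are computed from the thresholded confusion counts; the AUC is the
positive-class rank-sum form

    AUC = (sum of ascending-score ranks over positives
           - n_pos (n_pos + 1) / 2) / (n_pos * n_neg),

with mid-ranks for tied scores, which equals the tie-corrected
Mann-Whitney probability that a random positive outscores a random
negative. Metrics are reported as proportions in [0, 1]; any percent
scaling belongs to the presentation layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "basic_metrics",
    "auc_rank",
    "roc_curve",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """SN/SP/ACC/MCC/AUC plus the confusion counts they derive from."""

    SN: float
    SP: float
    ACC: float
    MCC: float
    AUC: float
    counts: ConfusionCounts
    n_pos: int
    n_neg: int

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_row(self, dataset: str = "") -> str:
        """One tab-separated record for tabular logs."""
        return "\t".join(
            [dataset, str(self.n_pos), str(self.n_neg)]
            + [f"{v:.6f}" for v in (self.SN, self.SP, self.ACC, self.MCC,
                                    self.AUC)]
        )


def _scores_labels(predictions, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(
        [p.probability if hasattr(p, "probability") else p for p in predictions],
        dtype=np.float64,
    )
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    return scores, labels


def confusion_counts(predictions, labels, threshold: float = 0.5
                     ) -> ConfusionCounts:
    """Count TP/TN/FP/FN at a decision threshold (predicted positive: p >= t)."""
    scores, labels = _scores_labels(predictions, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def basic_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(SN, SP, ACC, MCC) from confusion counts.

    A zero marginal makes the MCC denominator vanish; MCC is then defined
    as 0 with a warning (the conventional continuity choice).
    """
    if c.total == 0:
        raise ValueError("no evaluated records")
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0
    acc = (c.TP + c.TN) / c.total
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        warnings.warn("MCC denominator is zero; returning 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)
    return sn, sp, acc, float(mcc)


def auc_rank(scores, labels) -> float:
    """Rank-sum AUC with mid-ranks for ties (Mann-Whitney form)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores, method="average")
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve(scores, labels) -> np.ndarray:
    """ROC staircase points (FPR, TPR) from (0,0) to (1,1).

    Trapezoidal area under the returned points equals :func:`auc_rank`
    (exactly so in the tie-free case).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined: both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def evaluate(predictions, labels, threshold: float = 0.5) -> MetricsReport:
    """Assemble the full metric report at one threshold."""
    scores, labels = _scores_labels(predictions, labels)
    c = confusion_counts(scores, labels, threshold)
    sn, sp, acc, mcc = basic_metrics(c)
    auc = auc_rank(scores, labels)
    return MetricsReport(
        SN=sn, SP=sp, ACC=acc, MCC=mcc, AUC=auc, counts=c,
        n_pos=int(np.sum(labels == 1)), n_neg=int(np.sum(labels == 0)),
    )
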