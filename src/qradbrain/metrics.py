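"""Binary classification metrics computed in-house.

ROC-AUC uses the Mann-Whitney rank statistic with midranks for ties;
balanced accuracy is the mean of the per-class recalls; precision / recall
/ F1 come from the confusion matrix at the decision threshold.  Labels are
``{-1, +1}`` with ``+1`` the positive (glioma-like) class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricsReport", "classification_report", "roc_auc"]


@dataclass
class MetricsReport:
    bacc: float
    roc_auc: float
    per_class: dict[int, dict[str, float]]
    confusion: dict[str, int]
    macro: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bacc": self.bacc,
            "roc_auc": self.roc_auc,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "confusion": self.confusion,
            "macro": self.macro,
        }


def roc_auc(labels, scores) -> float:
    """Probability that a random positive outranks a random negative."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC requires both classes")
    ranks = rankdata(scores)  # midranks for ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def classification_report(labels, scores, threshold: float = 0.0
                          ) -> MetricsReport:
    """Threshold the scores (score >= threshold predicts +1) and report
    bACC, ROC-AUC and per-class precision / recall / F1."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = np.where(scores < threshold, -1, 1)

    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == -1) & (labels == -1)).sum())
    fp = int(((pred == 1) & (labels == -1)).sum())
    fn = int(((pred == -1) & (labels == 1)).sum())

    def _prf(tp_, fp_, fn_):
        prec = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
        rec = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return {"precision": prec, "recall": rec, "f1": f1}

    per_class = {1: _prf(tp, fp, fn), -1: _prf(tn, fn, fp)}
    bacc = (per_class[1]["recall"] + per_class[-1]["recall"]) / 2.0
    macro = {
        m: (per_class[1][m] + per_class[-1][m]) / 2.0
        for m in ("precision", "recall", "f1")
    }
    return MetricsReport(
        bacc=bacc,
        roc_auc=roc_auc(labels, scores),
        per_class=per_class,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        macro=macro,
    )
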