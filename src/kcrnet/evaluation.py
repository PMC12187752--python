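"""Binary-classification metrics: confusion counts, Sn/Sp/Acc/MCC, ROC/AUC.

Conventions, pinned by tests:

* a sample is called positive when its score is **>=** the threshold;
* MCC returns 0 when its denominator is zero;
* AUC uses the midrank (tie = 1/2) convention, so the trapezoidal area under
  the threshold-sweep ROC equals the probability that a random positive
  outscores a random negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics_from_confusion",
           "roc_auc", "roc_points", "evaluate"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def _check_inputs(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.ndim != 1 or labels.ndim != 1:
        raise ValueError("scores and labels must be 1-D")
    if len(scores) != len(labels):
        raise ValueError(f"length mismatch: {len(scores)} scores vs {len(labels)} labels")
    if len(scores) == 0:
        raise ValueError("empty input")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    return scores, labels.astype(np.int64)


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with 'predict positive iff score >= threshold'."""
    scores, labels = _check_inputs(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics_from_confusion(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sn, Sp, Acc, MCC).

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    with MCC = 0 when the denominator vanishes.  Sn (resp. Sp) is NaN when
    there are no positives (resp. negatives); all-zero counts are an error.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all-zero confusion counts")
    sn = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    sp = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    acc = (tp + tn) / total
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return sn, sp, acc, mcc


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC by threshold sweep over the unique scores (plus sentinels).

    Returns a frame with columns fpr, tpr, threshold, ordered from the
    all-negative corner (0, 0) to the all-positive corner (1, 1).
    """
    scores, labels = _check_inputs(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s, l = scores[order], labels[order]
    # cumulative counts at each distinct-score cut (predict >= threshold)
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    tps = np.cumsum(l)[distinct]
    fps = (distinct + 1) - tps
    thresholds = s[distinct]
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    thr = np.r_[np.inf, thresholds]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """(ROC points, AUC by trapezoidal integration).

    With the threshold sweep over unique scores the trapezoid rule handles
    ties as half-wins, so the area equals P(score_pos > score_neg) +
    0.5 * P(tie) — the Mann-Whitney statistic.
    """
    pts = roc_points(scores, labels)
    auc = float(np.trapezoid(pts["tpr"].to_numpy(), pts["fpr"].to_numpy()))
    return pts, auc


def evaluate(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Assemble the full report: Sn, Sp, Acc, MCC at the threshold, plus AUC."""
    c = confusion(scores, labels, threshold)
    sn, sp, acc, mcc = metrics_from_confusion(c)
    _, auc = roc_auc(scores, labels)
    return MetricReport(sn=sn, sp=sp, acc=acc, mcc=mcc, auc=auc,
                        n_pos=c.n_pos, n_neg=c.n_neg)
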