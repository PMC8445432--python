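"""Confusion-matrix construction and binary classification metrics.

The report carries the six statistics used to judge a two-class spectral
classifier: sensitivity TP/(TP+FN), specificity TN/(TN+FP), overall accuracy
(TP+TN)/total, the false-positive-rate error FP/(FP+TN), the Matthews
correlation coefficient, and the composite rigidity statistic

    rigidity = 2 * (accuracy - error) / (1 + accuracy - error),

which is 1 exactly when accuracy is 1 and error is 0, and 0 at chance-level
symmetry (accuracy = error).  A metric whose denominator is zero is reported
as missing (None), never as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from .spectra_io import ACC, PA


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with an explicit positive class."""

    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: str = ACC

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def correct(self) -> int:
        """Diagonal sum: number of correctly classified observations."""
        return self.tp + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """The same counts with the positive class swapped."""
        other = PA if self.positive_class == ACC else ACC
        return ConfusionMatrix(
            tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp, positive_class=other
        )


@dataclass(frozen=True)
class MetricsReport:
    """Derived metrics; None marks a metric whose denominator was zero."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    error: float | None
    mcc: float | None
    rigidity: float | None

    def as_dict(self, decimals: int | None = None) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "error": self.error,
            "mcc": self.mcc,
            "rigidity": self.rigidity,
        }
        if decimals is not None:
            d = {
                k: (None if v is None else round(v, decimals)) for k, v in d.items()
            }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"full_precision": self.as_dict(), "display_2dp": self.as_dict(2)}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def confusion_from_labels(
    true_labels, predicted_labels, positive_class: str = ACC
) -> ConfusionMatrix:
    """Tally TP/TN/FP/FN from parallel label sequences."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"label lengths differ: {len(t)} vs {len(p)}")
    valid = {PA, ACC}
    if positive_class not in valid:
        raise ValueError(f"positive_class must be one of {valid}")
    tp = tn = fp = fn = 0
    for ti, pi in zip(t, p):
        if ti not in valid or pi not in valid:
            raise ValueError(f"unknown label in pair ({ti!r}, {pi!r})")
        if ti == positive_class:
            if pi == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if pi == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn, positive_class=positive_class)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute the six metrics from confusion counts.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/total; error (false-positive rate) = FP/(FP+TN);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN));
    rigidity = 2*(accuracy - error) / (1 + accuracy - error).
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    accuracy = _ratio(tp + tn, cm.total)
    error = _ratio(fp, fp + tn)
    mcc_den = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / math.sqrt(mcc_den)
    if accuracy is None or error is None:
        rigidity = None
    else:
        rig_den = 1.0 + accuracy - error
        rigidity = None if rig_den == 0 else 2.0 * (accuracy - error) / rig_den
    return MetricsReport(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        error=error,
        mcc=mcc,
        rigidity=rigidity,
    )
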