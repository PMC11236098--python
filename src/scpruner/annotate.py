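"""Consensus annotation, open-set rejection and evaluation metrics.

The pruned sub-network labels each query cell by the per-cell mode of its
paths' predictions.  Confidence is the mean probability the selected paths
assign to that consensus label; cells below the rejection threshold tau
(default 0.65) are relabeled "unknown", which lets the annotator flag cell
types absent from the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score, matthews_corrcoef

from .exceptions import ConfigError, ValidationError
from .ensemble import PathPredictionMatrix
from .matrix import UNKNOWN_LABEL
from .pruning import ConsensusEvaluator

#: Default rejection threshold on consensus confidence.
DEFAULT_TAU = 0.65


@dataclass
class AnnotationResult:
    labels: np.ndarray      # categories plus possibly "unknown"
    confidence: np.ndarray  # in [0, 1]
    tau: float


@dataclass
class MetricsReport:
    acc: float
    macro_f1: float
    mcc: float
    confusion: np.ndarray
    classes: list[str]

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "macro_f1": self.macro_f1,
            "mcc": self.mcc,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
        }


def consensus(preds: PathPredictionMatrix,
              mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Consensus labels and confidences of the masked paths (mask nonempty)."""
    bits = np.asarray(mask, dtype=np.uint8)
    if bits.sum() == 0:
        raise ConfigError("cannot annotate with an empty sub-network")
    return ConsensusEvaluator(preds).consensus(bits)


def reject_unknown(labels: np.ndarray, confidence: np.ndarray,
                   tau: float = DEFAULT_TAU) -> AnnotationResult:
    """Relabel cells with confidence strictly below tau as unknown."""
    if not 0.0 <= tau <= 1.0:
        raise ValidationError("tau must lie in [0, 1]")
    labels = np.asarray(labels, dtype=object).copy()
    confidence = np.asarray(confidence, dtype=float)
    labels[confidence < tau] = UNKNOWN_LABEL
    return AnnotationResult(labels, confidence, tau)


def score(pred, truth) -> MetricsReport:
    """Accuracy, macro-F1 and multiclass MCC over the observed label union."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValidationError("prediction and truth lengths differ")
    classes = sorted(set(pred.tolist()) | set(truth.tolist()))
    conf = confusion_matrix(truth, pred, labels=classes)
    acc = float(np.trace(conf) / conf.sum())
    macro = float(f1_score(truth, pred, labels=classes, average="macro",
                           zero_division=0))
    mcc = float(matthews_corrcoef(truth, pred))
    return MetricsReport(acc, macro, mcc, conf, classes)


def threshold_sweep(preds: PathPredictionMatrix, mask: np.ndarray, truth,
                    taus) -> pd.DataFrame:
    """Metrics per rejection threshold; unknown counts as its own class."""
    taus = list(taus)
    if any(not 0.0 <= t <= 1.0 for t in taus):
        raise ValidationError("all taus must lie in [0, 1]")
    labels, conf = consensus(preds, mask)
    rows = []
    for tau in taus:
        res = reject_unknown(labels, conf, tau)
        rep = score(res.labels, truth)
        rows.append({
            "tau": tau,
            "n_unknown": int(np.count_nonzero(res.labels == UNKNOWN_LABEL)),
            "acc": rep.acc,
            "macro_f1": rep.macro_f1,
            "mcc": rep.mcc,
        })
    return pd.DataFrame(rows)
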