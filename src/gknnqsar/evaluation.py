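"""Classification accuracy of continuous activity estimates.

Continuous scores on [0, 1] are binarized at a threshold (0.1 by default:
a chemical is active iff its score strictly exceeds it) on both the truth
and the prediction side, and summarized by seven metrics: sensitivity,
specificity, balanced accuracy, accuracy, precision, negative predictive
value, and ROC AUC (computed on the continuous estimates against the
binarized truth). Parameterizations are ranked by the composite score

    score = balanced_accuracy * accuracy * roc_auc,

which is robust across the individual metrics. Ratios with a zero
denominator are reported as NaN and flagged, never silently zeroed; the
composite score is undefined whenever one of its factors is.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.1


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts plus the seven accuracy metrics and composite score.

    ``undefined`` names the metrics whose denominator was zero (their
    value is NaN).
    """

    sensitivity: float
    specificity: float
    balanced_accuracy: float
    accuracy: float
    precision: float
    npv: float
    roc_auc: float
    score: float
    counts: ConfusionCounts
    threshold: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "npv": self.npv,
            "roc_auc": self.roc_auc,
            "score": self.score,
        }


def binarize(score: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Active iff the activity score strictly exceeds the cutoff."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"activity score {score} outside [0, 1]")
    return score > threshold


def confusion(
    truth: Sequence[float],
    predicted: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> ConfusionCounts:
    """Binarize both sides at the same threshold and tally the confusion."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("truth and predictions must be equal-length, non-empty 1-D")
    ta = t > threshold
    pa = p > threshold
    return ConfusionCounts(
        tp=int(np.sum(ta & pa)),
        fp=int(np.sum(~ta & pa)),
        fn=int(np.sum(ta & ~pa)),
        tn=int(np.sum(~ta & ~pa)),
    )


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return math.nan
    return num / den


def metrics(
    truth: Sequence[float],
    predicted_scores: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> MetricsReport:
    """The seven accuracy metrics and composite score for one estimate set.

    ROC AUC is computed from the continuous predicted scores against the
    binarized truth (ties at 0.5, Mann-Whitney convention); with a
    single-class truth it is undefined and flagged.
    """
    c = confusion(truth, predicted_scores, threshold)
    undefined: set[str] = set()
    tpr = _ratio(c.tp, c.tp + c.fn, "sensitivity", undefined)
    tnr = _ratio(c.tn, c.tn + c.fp, "specificity", undefined)
    ppv = _ratio(c.tp, c.tp + c.fp, "precision", undefined)
    npv = _ratio(c.tn, c.tn + c.fn, "npv", undefined)
    acc = (c.tp + c.tn) / c.total
    ner = 0.5 * (tpr + tnr)
    if math.isnan(ner):
        undefined.add("balanced_accuracy")

    t = np.asarray(truth, dtype=float) > threshold
    if t.all() or not t.any():
        undefined.add("roc_auc")
        auc = math.nan
    else:
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(t, np.asarray(predicted_scores, dtype=float)))

    score = ner * acc * auc
    if math.isnan(score):
        undefined.add("score")
    return MetricsReport(
        sensitivity=tpr,
        specificity=tnr,
        balanced_accuracy=ner,
        accuracy=acc,
        precision=ppv,
        npv=npv,
        roc_auc=auc,
        score=score,
        counts=c,
        threshold=threshold,
        undefined=frozenset(undefined),
    )


def stratify_by_confidence(
    predictions: Sequence,
    truth: Mapping[str, float] | Sequence[float],
    cutoffs: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[float, tuple[MetricsReport, int]]:
    """Recompute metrics on the subsets with confidence q >= cutoff.

    ``truth`` is either a chem_id -> score mapping or a sequence aligned
    with ``predictions``. Returns cutoff -> (report, stratum size); empty
    strata are skipped with a notice.
    """
    preds = list(predictions)
    if isinstance(truth, Mapping):
        truth_vec = [truth[p.chem_id] for p in preds]
    else:
        truth_vec = list(truth)
        if len(truth_vec) != len(preds):
            raise ValueError("truth length does not match predictions")
    q = np.array([p.confidence for p in preds], dtype=float)
    est = np.array([p.estimate for p in preds], dtype=float)
    t = np.asarray(truth_vec, dtype=float)
    out: dict[float, tuple[MetricsReport, int]] = {}
    for cut in cutoffs:
        mask = q >= cut
        n = int(mask.sum())
        if n == 0:
            logger.info("confidence stratum q >= %g is empty; skipped", cut)
            continue
        out[cut] = (metrics(t[mask], est[mask], threshold), n)
    return out
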