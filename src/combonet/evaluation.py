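"""Classification metrics: confusion counts, accuracy, ROC-AUC.

Synergism is the positive class. Indeterminate calls are never correct:
they count as FN when the true label is synergism and FP when it is
antagonism, keeping the evaluation two-class without dropping pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_POS = "synergism"
_NEG = "antagonism"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvaluationResult:
    counts: ConfusionCounts
    accuracy: float
    auc: float | None
    accuracy_synergy: float | None
    accuracy_antagonism: float | None


def confusion(calls: Sequence[str], labels: Sequence[str]) -> ConfusionCounts:
    """Tally calls against true labels (positive class = synergism)."""
    if len(calls) != len(labels):
        raise ValueError(f"length mismatch: {len(calls)} calls vs {len(labels)} labels")
    if not labels:
        raise ValueError("no pairs to evaluate")
    tp = tn = fp = fn = 0
    for call, label in zip(calls, labels):
        if label == _POS:
            if call == _POS:
                tp += 1
            else:  # antagonism or indeterminate
                fn += 1
        elif label == _NEG:
            if call == _NEG:
                tn += 1
            else:
                fp += 1
        else:
            raise ValueError(f"unknown true label {label!r}")
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(counts: ConfusionCounts) -> float:
    if counts.total == 0:
        raise ValueError("accuracy undefined for zero evaluated pairs")
    return (counts.tp + counts.tn) / counts.total


def roc_curve_points(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(thresholds, fpr, tpr) arrays for the threshold sweep, tie groups merged."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == _POS else 0 for l in labels])
    order = np.argsort(-scores, kind="stable")
    scores, y = scores[order], y[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    # last index of each tie group = points where the threshold drops
    distinct = np.where(np.diff(scores))[0]
    idx = np.concatenate([distinct, [len(y) - 1]])
    tps = np.cumsum(y)[idx]
    fps = (idx + 1) - tps
    thresholds = np.concatenate([[np.inf], scores[idx]])
    tpr = np.concatenate([[0.0], tps / n_pos]) if n_pos else np.zeros(len(idx) + 1)
    fpr = np.concatenate([[0.0], fps / n_neg]) if n_neg else np.zeros(len(idx) + 1)
    return thresholds, fpr, tpr


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float | None:
    """Area under the TPR-vs-FPR curve, trapezoidal over all thresholds.

    Equals the concordance probability with ties counted 0.5. Pairs with a
    None score must be excluded by the caller; single-class inputs yield
    None with a warning.
    """
    if len(scores) != len(labels):
        raise ValueError(f"length mismatch: {len(scores)} scores vs {len(labels)} labels")
    labelset = set(labels)
    if labelset - {_POS, _NEG}:
        raise ValueError(f"unknown labels: {sorted(labelset - {_POS, _NEG})}")
    if len(labelset) < 2:
        logger.warning("roc_auc: single-class input, AUC undefined")
        return None
    _, fpr, tpr = roc_curve_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def evaluate(
    calls: Sequence[str],
    labels: Sequence[str],
    scores: Sequence[float | None] | None = None,
) -> EvaluationResult:
    """Bundle confusion counts, accuracy, per-class recalls and (optional) AUC.

    ``scores`` may contain None entries; those pairs are excluded from the
    AUC (with a warning) but still count toward accuracy.
    """
    counts = confusion(calls, labels)
    auc = None
    if scores is not None:
        kept = [(s, l) for s, l in zip(scores, labels) if s is not None]
        if len(kept) < len(labels):
            logger.warning("evaluate: %d pair(s) without score excluded from AUC", len(labels) - len(kept))
        if kept:
            auc = roc_auc([s for s, _ in kept], [l for _, l in kept])
    acc_syn = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    acc_ant = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    return EvaluationResult(
        counts=counts,
        accuracy=accuracy(counts),
        auc=auc,
        accuracy_synergy=acc_syn,
        accuracy_antagonism=acc_ant,
    )


def write_report(result: EvaluationResult, path) -> None:
    """Write a (metric, value) TSV report."""
    c = result.counts

    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.6f}"

    rows = [
        ("tp", str(c.tp)),
        ("tn", str(c.tn)),
        ("fp", str(c.fp)),
        ("fn", str(c.fn)),
        ("accuracy", fmt(result.accuracy)),
        ("accuracy_synergy", fmt(result.accuracy_synergy)),
        ("accuracy_antagonism", fmt(result.accuracy_antagonism)),
        ("auc", fmt(result.auc)),
    ]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(path, sep="\t", index=False)
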