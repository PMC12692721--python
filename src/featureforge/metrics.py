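"""Residue-level evaluation: Q score, per-class/macro F1, confusion matrices.

Q is the fraction of unmasked residues whose predicted label equals the true
label — class-set agnostic, so the same definition serves 3-, 8- or
16-state tasks. F1 per class is 2TP / (2TP + FP + FN); the macro average
runs over the full fixed class set (absent classes contribute 0). Confusion
rows are true classes, columns predicted, with a row-normalized view.
Masked (unresolved, Ø) positions never enter any metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chain import LABELS3, LABELS8, EIGHT_TO_THREE, MASK


def _validate(true, pred, mask):
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.shape != pred.shape:
        raise ValueError("true and pred must have equal length")
    if mask is None:
        mask = true != MASK
    mask = np.asarray(mask, dtype=bool) & (true != MASK)
    return true, pred, mask


def q_score(true: Sequence[str], pred: Sequence[str],
            mask: Optional[Sequence[bool]] = None) -> float:
    """Fraction of unmasked residues predicted correctly."""
    true, pred, mask = _validate(true, pred, mask)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no unmasked residues to score")
    return float(np.sum((true == pred) & mask) / n)


@dataclass
class ConfusionMatrix:
    """Counts (true x predicted) over a fixed class order, mask excluded."""

    classes: tuple[str, ...]
    counts: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        """Rows divided by row totals; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / totals
        out[~np.isfinite(out)] = 0.0
        return out

    @property
    def q(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


def confusion(true: Sequence[str], pred: Sequence[str],
              mask: Optional[Sequence[bool]] = None,
              class_set: Sequence[str] = LABELS8) -> ConfusionMatrix:
    """Confusion counts over ``class_set`` (default the 8 DSSP states)."""
    true, pred, mask = _validate(true, pred, mask)
    index = {c: i for i, c in enumerate(class_set)}
    counts = np.zeros((len(class_set), len(class_set)), dtype=int)
    for t, p, m in zip(true, pred, mask):
        if not m:
            continue
        if t not in index or p not in index:
            raise ValueError(f"label outside class set: true={t!r} pred={p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=tuple(class_set), counts=counts)


def f1_scores(true: Sequence[str], pred: Sequence[str],
              mask: Optional[Sequence[bool]] = None,
              class_set: Sequence[str] = LABELS8) -> tuple[dict[str, float], float]:
    """Per-class F1 and the unweighted macro average over ``class_set``.

    A class with TP = FP = FN = 0 scores 0 and still enters the macro mean.
    """
    cm = confusion(true, pred, mask, class_set)
    per_class = {}
    for i, c in enumerate(cm.classes):
        tp = cm.counts[i, i]
        fp = cm.counts[:, i].sum() - tp
        fn = cm.counts[i, :].sum() - tp
        denom = 2 * tp + fp + fn
        per_class[c] = 0.0 if denom == 0 else float(2 * tp / denom)
    macro = float(np.mean(list(per_class.values())))
    return per_class, macro


def collapse_to_three(cm8: ConfusionMatrix) -> ConfusionMatrix:
    """Aggregate an 8-state confusion matrix to the 3-state scheme."""
    if tuple(cm8.classes) != LABELS8:
        raise ValueError("expected an 8-state confusion matrix")
    idx3 = {c: i for i, c in enumerate(LABELS3)}
    counts = np.zeros((3, 3), dtype=int)
    for i, ti in enumerate(cm8.classes):
        for j, pj in enumerate(cm8.classes):
            counts[idx3[EIGHT_TO_THREE[ti]], idx3[EIGHT_TO_THREE[pj]]] += cm8.counts[i, j]
    return ConfusionMatrix(classes=tuple(LABELS3), counts=counts)


def evaluation_report(true: Sequence[str], pred: Sequence[str],
                      mask: Optional[Sequence[bool]] = None,
                      class_set: Sequence[str] = LABELS8) -> dict:
    """Bundle Q, per-class F1, macro F1 and the confusion matrix as a dict."""
    cm = confusion(true, pred, mask, class_set)
    per_class, macro = f1_scores(true, pred, mask, class_set)
    return {
        "q": q_score(true, pred, mask),
        "f1_per_class": per_class,
        "f1_macro": macro,
        "classes": list(class_set),
        "confusion_counts": cm.counts.tolist(),
        "confusion_normalized": cm.normalized.tolist(),
    }
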