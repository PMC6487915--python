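"""Sleep-scoring evaluation: confusion matrices and the standard metric set.

Conventions: confusion-matrix rows are the reference (ground-truth) stage,
columns the predicted stage. Per class, sensitivity is recall
(diagonal / row total), selectivity is precision (diagonal / column total),
specificity is the one-vs-rest true-negative rate, and F1 the harmonic mean
of sensitivity and selectivity; macro averages are unweighted. Cohen's kappa
corrects overall agreement for chance using the row/column marginals.
Percentages are reported to one decimal (half-up).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .stages import AASM5, StageSequence, StageVocabulary

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "overall_accuracy",
    "cohen_kappa",
    "per_class_metrics",
    "transition_split",
    "round_percent",
]


def round_percent(x: float, ndigits: int = 1) -> float:
    """Half-up rounding of a percentage, matching tabular reporting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Y x Y counts: rows = reference stage, columns = predicted stage."""

    counts: np.ndarray
    vocab: StageVocabulary = field(default_factory=StageVocabulary)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        Y = self.vocab.Y
        if self.counts.shape != (Y, Y):
            raise ValueError(f"counts must be {Y}x{Y}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Overall and per-class metrics derived from one confusion matrix."""

    accuracy: float
    kappa: float
    macro_f1: float
    macro_sensitivity: float
    macro_specificity: float
    per_class: Dict[str, Dict[str, float]]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "MF1": self.macro_f1,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "per_class": self.per_class,
        }


def confusion_matrix(
    reference: StageSequence | Sequence[str],
    predicted: StageSequence | Sequence[str],
    vocab: Optional[StageVocabulary] = None,
) -> ConfusionMatrix:
    """Tally reference-by-predicted stage counts."""
    if vocab is None:
        vocab = reference.vocab if isinstance(reference, StageSequence) else AASM5
    ref = list(reference)
    pred = list(predicted)
    if len(ref) != len(pred):
        raise ValueError(
            f"reference has {len(ref)} epochs but prediction has {len(pred)}"
        )
    for lab in set(ref) | set(pred):
        if lab not in vocab:
            raise KeyError(
                f"unknown stage {lab!r}; valid stages are {list(vocab.labels)}"
            )
    counts = _sk_confusion(ref, pred, labels=list(vocab.labels))
    return ConfusionMatrix(counts=counts, vocab=vocab)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: fraction of correctly staged epochs."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    total = c.sum()
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) / total) @ (c.sum(axis=0) / total))
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class sensitivity/selectivity/specificity/F1 plus macro averages.

    Classes with an empty denominator are excluded from the corresponding
    macro average with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    total = c.sum()
    diag = np.diag(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    per_class: Dict[str, Dict[str, float]] = {}
    sens_list, spec_list, f1_list = [], [], []
    for k, lab in enumerate(cm.vocab.labels):
        entry: Dict[str, float] = {}
        sens = diag[k] / row[k] if row[k] > 0 else np.nan
        sel = diag[k] / col[k] if col[k] > 0 else np.nan
        tn = total - row[k] - col[k] + diag[k]
        fp = col[k] - diag[k]
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        if np.isfinite(sens) and np.isfinite(sel) and (sens + sel) > 0:
            f1 = 2 * sens * sel / (sens + sel)
        elif np.isfinite(sens) and np.isfinite(sel):
            f1 = 0.0
        else:
            f1 = np.nan
        entry.update(sensitivity=sens, selectivity=sel, specificity=spec, f1=f1)
        per_class[lab] = {k2: float(v) for k2, v in entry.items()}
        for val, acc in ((sens, sens_list), (spec, spec_list), (f1, f1_list)):
            if np.isfinite(val):
                acc.append(val)
            else:
                warnings.warn(
                    f"class {lab!r} excluded from a macro average (empty denominator)"
                )
    return MetricsReport(
        accuracy=overall_accuracy(cm),
        kappa=cohen_kappa(cm),
        macro_f1=float(np.mean(f1_list)),
        macro_sensitivity=float(np.mean(sens_list)),
        macro_specificity=float(np.mean(spec_list)),
        per_class=per_class,
    )


def transition_split(reference: StageSequence | Sequence[str]) -> np.ndarray:
    """Boolean mask per epoch: True where the epoch sits at a stage transition.

    An epoch is *non-transition* iff every existing neighbor (left and right,
    clipped at recording boundaries) shares its label; otherwise it is a
    transition epoch.
    """
    labels = list(reference)
    n = len(labels)
    if n < 1:
        raise ValueError("need at least one epoch")
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in (i - 1, i + 1):
            if 0 <= j < n and labels[j] != labels[i]:
                mask[i] = True
                break
    return mask
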