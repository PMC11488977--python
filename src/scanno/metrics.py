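"""Classification and clustering evaluation.

Macro precision/recall/F1 treat every cell type equally regardless of
abundance; micro F1 pools counts and equals accuracy for single-label
multiclass predictions. Partition agreement is measured by NMI (arithmetic
normalization) and ARI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    precision_recall_fscore_support,
)

from .datatypes import ValidationError


@dataclass
class ClassificationReport:
    precision_macro: float
    recall_macro: float
    f1_macro: float
    f1_micro: float
    per_class: pd.DataFrame  # index: class; columns: precision, recall, f1, support

    def to_dict(self) -> dict[str, float]:
        return {
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "f1_micro": self.f1_micro,
        }


def classification_report(
    true_labels, predicted_labels, classes: list[str] | None = None
) -> ClassificationReport:
    """Macro precision/recall/F1 and micro F1 over the given class list.

    Classes with no predicted (resp. true) instances get precision (resp.
    recall) 0, keeping macro averages computable on unbalanced data.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if len(y_true) == 0:
        raise ValidationError("empty label vectors")
    if len(y_true) != len(y_pred):
        raise ValidationError("label vectors differ in length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    p, r, f, s = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    micro = float(np.mean(y_true == y_pred))
    return ClassificationReport(
        precision_macro=float(p.mean()),
        recall_macro=float(r.mean()),
        f1_macro=float(f.mean()),
        f1_micro=micro,
        per_class=pd.DataFrame(
            {"precision": p, "recall": r, "f1": f, "support": s}, index=classes
        ),
    )


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information with arithmetic-mean normalization.

    Defined as 0 when exactly one of the partitions is a single cluster
    (the information-free degenerate case).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValidationError("label vectors differ in length")
    single_a = len(set(a.tolist())) == 1
    single_b = len(set(b.tolist())) == 1
    if single_a != single_b:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (pair counting with expected-index correction)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValidationError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))
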