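"""Pseudo-label construction and the KL training objective.

Raw relevance scores are mapped row-wise onto the probability simplex; the
resulting soft labels are the targets of classifier pretraining. The same KL
divergence is minimized again during self-training, with the previous round's
predictions as targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ValidationError
from .relevance import RelevanceMatrix


@dataclass
class PseudoLabelMatrix:
    """N x T soft labels: each row a probability distribution over types."""

    values: np.ndarray
    cell_ids: list[str]
    type_names: list[str]
    source_strategy: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.type_names)):
            raise ValidationError("pseudo-label matrix shape mismatch")
        if (self.values < -1e-9).any() or (self.values > 1 + 1e-9).any():
            raise ValidationError("pseudo-label entries outside [0, 1]")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError("pseudo-label rows must sum to 1")


def normalize_to_simplex(
    R: RelevanceMatrix,
    method: str = "softmax",
    temperature: float = 1.0,
    hard: bool = False,
) -> PseudoLabelMatrix:
    """Map each relevance row onto the probability simplex.

    ``softmax`` (default) exponentiates R / temperature row-wise and handles
    negative scores; ``sum`` divides each nonnegative row by its total, with
    all-zero rows mapped to the uniform distribution. ``hard`` collapses each
    row to a one-hot argmax (ablation only; soft labels are the default
    because hard labels promote overfitting to pseudo-label noise).
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    V = np.asarray(R.values, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValidationError("non-finite relevance entries")
    n, t = V.shape
    if method == "softmax":
        z = V / temperature
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        L = e / e.sum(axis=1, keepdims=True)
    elif method == "sum":
        if (V < 0).any():
            raise ValidationError("method='sum' requires nonnegative relevance")
        totals = V.sum(axis=1)
        zero = totals == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} all-zero relevance row(s) mapped to uniform",
                stacklevel=2,
            )
        L = V / np.where(zero, 1.0, totals)[:, None]
        L[zero] = 1.0 / t
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if hard:
        onehot = np.zeros_like(L)
        onehot[np.arange(n), L.argmax(axis=1)] = 1.0
        L = onehot
    return PseudoLabelMatrix(L, R.cell_ids, R.type_names, R.strategy_tag)


def kl_divergence(
    target: np.ndarray, pred: np.ndarray, epsilon: float = 1e-8
) -> float:
    """Total KL(target || pred) summed over cells and types.

    Terms with target 0 contribute 0; ``epsilon`` floors the prediction
    inside the log so degenerate predictions stay finite.
    """
    P = np.asarray(target, dtype=float)
    Q = np.asarray(pred, dtype=float)
    if P.shape != Q.shape:
        raise ValidationError(f"shape mismatch: {P.shape} vs {Q.shape}")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P / np.maximum(Q, epsilon)), 0.0)
    return float(terms.sum())
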