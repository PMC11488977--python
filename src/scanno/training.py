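"""Pretraining on pseudo-labels, iterative self-training, and the pipeline.

Pretraining minimizes KL(pseudo-labels || predictions) by seeded mini-batch
descent. Self-training then repeatedly freezes the model's own full-data
predictions as the next round's soft targets and continues optimizing the
same parameters (warm start), stopping when the fraction of cells whose
argmax label changes between rounds falls below a threshold.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .datatypes import ExpressionMatrix, MarkerCatalog, PathwayCollection, ValidationError
from .model import LinearSoftmaxModel, PathwayTransformer, TransformerConfig
from .pseudolabels import PseudoLabelMatrix, kl_divergence, normalize_to_simplex
from .relevance import DEFAULT_STRATEGY, compute_relevance

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings for pretraining and self-training.

    ``delta`` is the convergence threshold on the fraction of cells whose
    argmax label changes between self-training rounds. ``sharpen`` raises
    self-training targets to a power before renormalization (1 = off,
    targets are the raw predictions).
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    pretrain_epochs: int = 50
    batch_size: int = 256
    max_rounds: int = 20
    epochs_per_round: int = 5
    delta: float = 1e-3
    sharpen: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pretrain_epochs, self.batch_size, self.max_rounds,
               self.epochs_per_round) < 0:
            raise ValidationError("counts must be nonnegative")
        if not (0 < self.delta < 1):
            raise ValidationError("delta must lie in (0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")


class _Optimizer:
    """Adam or plain SGD over a dict of parameter arrays, updated in place."""

    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig) -> None:
        self.params = params
        self.lr = cfg.learning_rate
        self.kind = cfg.optimizer
        self.t = 0
        if self.kind == "adam":
            self.m = {k: np.zeros_like(v) for k, v in params.items()}
            self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        if self.kind == "sgd":
            for k, g in grads.items():
                self.params[k] -= self.lr * g
            return
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class SelfTrainRound:
    round_index: int
    loss: float
    label_change_fraction: float
    target_checksum: str
    prediction_checksum: str


@dataclass
class AnnotationResult:
    """Full output of the annotation pipeline for one dataset."""

    cell_ids: list[str]
    type_names: list[str]
    probabilities: np.ndarray
    predicted_type: list[str]
    pretrain_loss_history: list[float]
    selftrain_history: list[SelfTrainRound]
    stop_reason: str
    attention_profiles: np.ndarray | None
    pathway_names: list[str] | None
    provenance: dict[str, Any] = field(default_factory=dict)
    model: Any = None


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _full_data_loss(model, X: np.ndarray, targets: np.ndarray) -> float:
    probs, _ = model.forward(X)
    return kl_divergence(targets, probs)


def _run_epochs(
    model,
    X: np.ndarray,
    targets: np.ndarray,
    n_epochs: int,
    cfg: TrainConfig,
    opt: _Optimizer,
    rng: np.random.Generator,
) -> list[float]:
    """Seeded mini-batch optimization; returns full-data KL after each epoch."""
    n = X.shape[0]
    history: list[float] = []
    for _ in range(n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = model.loss_and_grads(X[idx], targets[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/Inf loss at batch starting {start}"
                )
            opt.step(grads)
        history.append(_full_data_loss(model, X, targets))
    return history


def pretrain(
    model,
    X: np.ndarray,
    labels: PseudoLabelMatrix,
    cfg: TrainConfig,
) -> list[float]:
    """Minimize KL(pseudo-labels || predictions); returns the loss history.

    The history holds the full-data KL before training followed by one entry
    per epoch. Deterministic under a fixed seed.
    """
    L = labels.values
    if L.shape[0] != X.shape[0]:
        raise ValidationError("pseudo-label rows not aligned to expression rows")
    rng = np.random.default_rng(cfg.seed)
    opt = _Optimizer(model.params, cfg)
    history = [_full_data_loss(model, X, L)]
    history += _run_epochs(model, X, L, cfg.pretrain_epochs, cfg, opt, rng)
    logger.info("pretrain: loss %.4f -> %.4f over %d epochs",
                history[0], history[-1], cfg.pretrain_epochs)
    return history


def self_train(
    model,
    X: np.ndarray,
    cfg: TrainConfig,
) -> tuple[list[SelfTrainRound], str]:
    """Iterative refinement with the model's own predictions as targets.

    Round t+1 freezes the full-data prediction matrix of round t, trains
    ``epochs_per_round`` epochs minimizing KL against it, and recomputes
    predictions; stops when the argmax-label change fraction drops below
    ``cfg.delta`` or ``cfg.max_rounds`` is reached.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Optimizer(model.params, cfg)
    rounds: list[SelfTrainRound] = []
    stop_reason = "max_rounds"
    probs, _ = model.forward(X)
    prev_argmax = probs.argmax(axis=1)
    for t in range(cfg.max_rounds):
        targets = probs
        if cfg.sharpen != 1.0:
            targets = targets**cfg.sharpen
            targets = targets / targets.sum(axis=1, keepdims=True)
        target_sum = _checksum(targets)
        start_loss = _full_data_loss(model, X, targets)
        epoch_losses = _run_epochs(
            model, X, targets, cfg.epochs_per_round, cfg, opt, rng
        )
        end_loss = epoch_losses[-1] if epoch_losses else start_loss
        if start_loss > 0 and end_loss > 10 * max(start_loss, 1e-12):
            warnings.warn("self-training loss diverged; stopping early",
                          stacklevel=2)
            stop_reason = "diverged"
        probs, _ = model.forward(X)
        new_argmax = probs.argmax(axis=1)
        change = float(np.mean(new_argmax != prev_argmax))
        rounds.append(SelfTrainRound(
            round_index=t,
            loss=end_loss,
            label_change_fraction=change,
            target_checksum=target_sum,
            prediction_checksum=_checksum(probs),
        ))
        logger.info("self-train round %d: loss %.4f, label change %.4f",
                    t, end_loss, change)
        prev_argmax = new_argmax
        if stop_reason == "diverged":
            break
        if change < cfg.delta:
            stop_reason = "converged"
            break
    return rounds, stop_reason


def annotate(
    expr: ExpressionMatrix,
    markers: MarkerCatalog,
    pathways: PathwayCollection,
    strategy: str = DEFAULT_STRATEGY,
    train_cfg: TrainConfig | None = None,
    *,
    embed_dim: int = 100,
    n_heads: int = 4,
    gene_embedding=None,
    pseudo_label_method: str = "softmax",
    pseudo_label_temperature: float = 1.0,
    pseudo_labels: PseudoLabelMatrix | None = None,
    no_self_training: bool = False,
    lr_classifier: bool = False,
    keep_unassigned: bool = False,
) -> AnnotationResult:
    """End-to-end pipeline: relevance -> pseudo-labels -> pretrain -> self-train.

    ``no_self_training`` stops after pretraining; ``lr_classifier`` swaps the
    attention classifier for a multinomial logistic model on the gene vector
    (no attention record in that case). A precomputed ``pseudo_labels``
    matrix overrides the relevance/normalization stages.
    """
    from .io import build_pathway_mask  # local import to avoid a cycle

    cfg = train_cfg or TrainConfig()
    t0 = time.time()

    if pseudo_labels is None:
        R = compute_relevance(expr, markers, strategy, emb=gene_embedding,
                              seed=cfg.seed)
        pseudo_labels = normalize_to_simplex(
            R, method=pseudo_label_method, temperature=pseudo_label_temperature
        )
    L = pseudo_labels.values
    if L.shape[0] != expr.n_cells:
        raise ValidationError("pseudo-labels not aligned to expression matrix")
    type_names = pseudo_labels.type_names

    if lr_classifier:
        model = LinearSoftmaxModel(expr.gene_ids, len(type_names), seed=cfg.seed)
        X = expr.lognorm
        pathway_names = None
    else:
        mask = build_pathway_mask(pathways, expr.gene_ids,
                                  keep_unassigned=keep_unassigned)
        gidx = expr.gene_index()
        X = expr.lognorm[:, [gidx[g] for g in mask.gene_ids]]
        mcfg = TransformerConfig(
            n_types=len(type_names), embed_dim=embed_dim, n_heads=n_heads,
            seed=cfg.seed,
        )
        model = PathwayTransformer(mcfg, mask)
        pathway_names = mask.pathway_names

    pretrain_history = pretrain(model, X, pseudo_labels, cfg)

    if no_self_training:
        rounds: list[SelfTrainRound] = []
        stop_reason = "self_training_disabled"
    else:
        rounds, stop_reason = self_train(model, X, cfg)

    probs, _ = model.forward(X)
    argmax = probs.argmax(axis=1)
    ties = (probs == probs.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("%d cell(s) with tied max probability; lowest type index kept",
                    int(ties.sum()))
    predicted = [type_names[j] for j in argmax]

    attention = None
    if model.supports_attention:
        from .interpret import extract_attention_profiles
        attention = extract_attention_profiles(model, X).values

    return AnnotationResult(
        cell_ids=expr.cell_ids,
        type_names=type_names,
        probabilities=probs,
        predicted_type=predicted,
        pretrain_loss_history=pretrain_history,
        selftrain_history=rounds,
        stop_reason=stop_reason,
        attention_profiles=attention,
        pathway_names=pathway_names,
        provenance=dict(
            strategy=pseudo_labels.source_strategy,
            pseudo_label_method=pseudo_label_method,
            pseudo_label_temperature=pseudo_label_temperature,
            train_config=vars(cfg).copy(),
            embed_dim=embed_dim,
            n_heads=n_heads,
            no_self_training=no_self_training,
            lr_classifier=lr_classifier,
            seconds=round(time.time() - t0, 3),
        ),
        model=model,
    )
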