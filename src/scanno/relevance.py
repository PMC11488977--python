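"""Cell-to-type relevance scoring strategies.

Six strategies produce the raw N x T relevance matrix R from which pseudo-
labels are derived:

``count``
    number of a type's marker genes expressed (> 0) in the cell;
``cos``
    cosine similarity between the cell's expression-weighted mean gene
    embedding and the type's mean marker embedding;
``lr-label`` / ``lr-marker``
    probabilities from a multinomial logistic classifier trained on type
    embeddings (one sample per class) or on individual marker embeddings
    (one sample per marker);
``pseudo-cell``
    probabilities from a classifier trained on synthetic cells sampled
    around each type's embedding direction (von Mises-Fisher directions,
    softmax gene profiles);
``cell-type-specific``
    specificity-weighted mean of z-scored marker expression, where a
    marker's specificity score S down-weights markers shared across types.

The ``cell-type-specific`` strategy is the default pseudo-label source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import vonmises_fisher
from sklearn.linear_model import LogisticRegression

from .datatypes import (
    ExpressionMatrix,
    GeneEmbedding,
    MarkerCatalog,
    ValidationError,
)

STRATEGIES = (
    "count",
    "cos",
    "lr-label",
    "lr-marker",
    "pseudo-cell",
    "cell-type-specific",
)

DEFAULT_STRATEGY = "cell-type-specific"


@dataclass
class RelevanceMatrix:
    """Raw N x T cell-to-type association scores for one strategy."""

    values: np.ndarray
    cell_ids: list[str]
    type_names: list[str]
    strategy_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.type_names)):
            raise ValidationError("relevance matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite relevance scores")


@dataclass
class SpecificityScores:
    """Per-marker cell-type specificity S in [0, 1].

    S rescales the number of types listing the marker: a marker belonging to
    the fewest types scores 1 (uniquely representative), one belonging to the
    most types scores 0.
    """

    marker_gene_ids: list[str]
    scores: np.ndarray
    types_per_marker: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.marker_gene_ids, self.scores.tolist()))


@dataclass
class CellTypeEmbeddings:
    """Cells and types mapped into the shared gene-embedding space."""

    cell_vectors: np.ndarray  # N x d
    type_vectors: np.ndarray  # T x d
    cell_ids: list[str]
    type_names: list[str]


@dataclass
class PseudoCellConfig:
    """Controls pseudo-cell sampling: ``n_per_type`` synthetic cells per type
    with vMF concentration ``kappa`` around the type direction and softmax
    sharpness ``sharpness`` on gene profiles scaled to ``library_size``."""

    n_per_type: int = 500
    kappa: float = 50.0
    sharpness: float = 10.0
    library_size: float = 1000.0


def _markers_present(
    cat: MarkerCatalog, available: set[str], what: str
) -> dict[str, list[str]]:
    present: dict[str, list[str]] = {}
    for t in cat.type_names:
        genes = [g for g in cat.markers[t] if g in available]
        dropped = len(cat.markers[t]) - len(genes)
        if dropped:
            warnings.warn(
                f"{dropped} marker(s) of type {t!r} absent from {what}; dropped",
                stacklevel=3,
            )
        present[t] = genes
    return present


def score_count(expr: ExpressionMatrix, cat: MarkerCatalog) -> RelevanceMatrix:
    """R_ij = number of type-j markers with expression > 0 in cell i."""
    x = expr.dense_counts()
    gidx = expr.gene_index()
    present = _markers_present(cat, set(expr.gene_ids), "expression matrix")
    R = np.zeros((expr.n_cells, cat.n_types))
    for j, t in enumerate(cat.type_names):
        genes = present[t]
        if not genes:
            warnings.warn(f"no markers of type {t!r} present; column set to 0",
                          stacklevel=2)
            continue
        cols = [gidx[g] for g in genes]
        R[:, j] = (x[:, cols] > 0).sum(axis=1)
    return RelevanceMatrix(R, expr.cell_ids, cat.type_names, "count")


def embed_cells_and_types(
    expr: ExpressionMatrix, cat: MarkerCatalog, emb: GeneEmbedding
) -> CellTypeEmbeddings:
    """Expression-weighted cell embeddings and mean-marker type embeddings.

    c_i = (x_i . E) / sum(x_i) over the genes shared between the expression
    matrix and the embedding table; T_j = mean of type-j marker embeddings.
    """
    eidx = emb.gene_index()
    shared = [g for g in expr.gene_ids if g in eidx]
    if not shared:
        raise ValidationError("no genes shared between expression and embedding")
    gidx = expr.gene_index()
    x = expr.dense_counts()[:, [gidx[g] for g in shared]]
    E = emb.vectors[[eidx[g] for g in shared], :]
    totals = x.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) with zero expression over shared genes "
            "get zero embeddings",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, totals)
    cell_vectors = (x @ E) / safe[:, None]
    cell_vectors[zero] = 0.0

    present = _markers_present(cat, set(emb.gene_ids), "gene embedding")
    type_vectors = np.zeros((cat.n_types, emb.dim))
    for j, t in enumerate(cat.type_names):
        genes = present[t]
        if not genes:
            warnings.warn(f"type {t!r} has no embedded markers; zero vector",
                          stacklevel=2)
            continue
        type_vectors[j] = emb.vectors[[eidx[g] for g in genes], :].mean(axis=0)
    return CellTypeEmbeddings(cell_vectors, type_vectors, expr.cell_ids,
                              cat.type_names)


def score_cosine(ce: CellTypeEmbeddings) -> RelevanceMatrix:
    """R_ij = cosine(c_i, T_j); zero-norm vectors score 0."""
    cn = np.linalg.norm(ce.cell_vectors, axis=1)
    tn = np.linalg.norm(ce.type_vectors, axis=1)
    denom = np.outer(np.where(cn == 0, 1.0, cn), np.where(tn == 0, 1.0, tn))
    R = (ce.cell_vectors @ ce.type_vectors.T) / denom
    R[cn == 0, :] = 0.0
    R[:, tn == 0] = 0.0
    return RelevanceMatrix(R, ce.cell_ids, ce.type_names, "cos")


def _fit_lr(X: np.ndarray, y: np.ndarray, seed: int = 0) -> LogisticRegression:
    clf = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
    clf.fit(X, y)
    return clf


def score_lr(
    ce: CellTypeEmbeddings,
    cat: MarkerCatalog,
    emb: GeneEmbedding,
    mode: str = "label",
    seed: int = 0,
) -> RelevanceMatrix:
    """Logistic-regression relevance from external embeddings.

    ``label`` mode trains on one sample per class (the type embedding);
    ``marker`` mode trains on one sample per marker gene. R rows sum to 1.
    """
    if mode not in ("label", "marker"):
        raise ValueError(f"mode must be 'label' or 'marker', got {mode!r}")
    eidx = emb.gene_index()
    if mode == "label":
        keep = [j for j in range(cat.n_types)
                if np.any(ce.type_vectors[j] != 0)]
        X = ce.type_vectors[keep]
        y = np.array(keep)
    else:
        rows, y_list = [], []
        for j, t in enumerate(cat.type_names):
            for g in cat.markers[t]:
                if g in eidx:
                    rows.append(emb.vectors[eidx[g]])
                    y_list.append(j)
        X = np.array(rows)
        y = np.array(y_list)
    if len(np.unique(y)) < 2:
        raise ValidationError("fewer than 2 classes with usable training samples")
    clf = _fit_lr(X, y, seed)
    proba = clf.predict_proba(ce.cell_vectors)
    R = np.zeros((len(ce.cell_ids), cat.n_types))
    R[:, clf.classes_] = proba
    return RelevanceMatrix(R, ce.cell_ids, cat.type_names, f"lr-{mode}")


def generate_pseudocells(
    ce: CellTypeEmbeddings,
    emb: GeneEmbedding,
    cfg: PseudoCellConfig,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample pseudo-cell embedding profiles per type.

    Each type is modeled as a spherical (von Mises-Fisher) distribution on
    the unit sphere centered at its normalized embedding; sampled directions
    are converted to gene profiles via a softmax over gene-embedding
    alignments, scaled to the library size, and projected back into the
    embedding space with expression weighting.
    """
    if cfg.kappa <= 0:
        raise ValidationError("vMF concentration kappa must be > 0")
    rng = np.random.default_rng(seed)
    E = emb.vectors
    profiles, labels = [], []
    for j, mu in enumerate(ce.type_vectors):
        norm = np.linalg.norm(mu)
        if norm == 0:
            warnings.warn(f"type index {j} has a zero embedding; skipped",
                          stacklevel=2)
            continue
        dirs = vonmises_fisher(mu / norm, cfg.kappa).rvs(
            cfg.n_per_type, random_state=rng
        )
        logits = cfg.sharpness * (dirs @ E.T)  # n_pseudo x G'
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        gene_profile = w / w.sum(axis=1, keepdims=True) * cfg.library_size
        cell_emb = (gene_profile @ E) / gene_profile.sum(axis=1, keepdims=True)
        profiles.append(cell_emb)
        labels.append(np.full(len(cell_emb), j))
    return np.vstack(profiles), np.concatenate(labels)


def score_pseudocell(
    ce: CellTypeEmbeddings,
    cat: MarkerCatalog,
    emb: GeneEmbedding,
    cfg: PseudoCellConfig | None = None,
    seed: int = 0,
) -> RelevanceMatrix:
    """Classifier probabilities from training on sampled pseudo-cells."""
    cfg = cfg or PseudoCellConfig()
    X, y = generate_pseudocells(ce, emb, cfg, seed)
    if len(np.unique(y)) < 2:
        raise ValidationError("fewer than 2 types with usable embeddings")
    clf = _fit_lr(X, y, seed)
    proba = clf.predict_proba(ce.cell_vectors)
    R = np.zeros((len(ce.cell_ids), cat.n_types))
    R[:, clf.classes_.astype(int)] = proba
    return RelevanceMatrix(R, ce.cell_ids, cat.type_names, "pseudo-cell")


def compute_specificity(cat: MarkerCatalog) -> SpecificityScores:
    """Min-max rescaled inverse of the number of types listing each marker.

    S = 1 - (|M_m| - min) / (max - min) over the pooled marker list; when all
    pooled markers belong to the same number of types, S = 1 uniformly.
    """
    pool = cat.pooled_markers()
    counts = cat.types_per_marker()
    tpm = np.array([counts[g] for g in pool], dtype=float)
    lo, hi = tpm.min(), tpm.max()
    if hi == lo:
        scores = np.ones_like(tpm)
    else:
        scores = 1.0 - (tpm - lo) / (hi - lo)
    return SpecificityScores(pool, scores, tpm.astype(int))


def score_cell_type_specific(
    expr: ExpressionMatrix,
    cat: MarkerCatalog,
    spec: SpecificityScores | None = None,
) -> RelevanceMatrix:
    """Specificity-weighted mean of z-scored marker expression.

    Per gene, expression is z-scored across cells on the log-normalized
    matrix (population standard deviation; zero-variance genes contribute 0),
    each marker column is multiplied by its specificity S, and R_ij averages
    the weighted scores over the type-j markers present.
    """
    spec = spec if spec is not None else compute_specificity(cat)
    x = expr.lognorm
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    z = np.where(sd > 0, (x - mu) / np.where(sd == 0, 1.0, sd), 0.0)

    gidx = expr.gene_index()
    sdict = spec.as_dict()
    present = _markers_present(cat, set(expr.gene_ids), "expression matrix")
    R = np.zeros((expr.n_cells, cat.n_types))
    for j, t in enumerate(cat.type_names):
        genes = present[t]
        if not genes:
            warnings.warn(f"no markers of type {t!r} present; column set to 0",
                          stacklevel=2)
            continue
        cols = [gidx[g] for g in genes]
        weights = np.array([sdict[g] for g in genes])
        R[:, j] = (z[:, cols] * weights).sum(axis=1) / len(genes)
    return RelevanceMatrix(R, expr.cell_ids, cat.type_names, "cell-type-specific")


def compute_relevance(
    expr: ExpressionMatrix,
    cat: MarkerCatalog,
    strategy: str = DEFAULT_STRATEGY,
    emb: GeneEmbedding | None = None,
    pseudocell_cfg: PseudoCellConfig | None = None,
    seed: int = 0,
) -> RelevanceMatrix:
    """Dispatch to one of the six strategies by name."""
    if strategy not in STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; valid: {', '.join(STRATEGIES)}"
        )
    if strategy == "count":
        return score_count(expr, cat)
    if strategy == "cell-type-specific":
        return score_cell_type_specific(expr, cat)
    if emb is None:
        raise ValidationError(f"strategy {strategy!r} requires a gene embedding")
    ce = embed_cells_and_types(expr, cat, emb)
    if strategy == "cos":
        return score_cosine(ce)
    if strategy in ("lr-label", "lr-marker"):
        return score_lr(ce, cat, emb, mode=strategy.split("-")[1], seed=seed)
    return score_pseudocell(ce, cat, emb, pseudocell_cfg, seed=seed)
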