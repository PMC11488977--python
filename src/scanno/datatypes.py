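"""Core in-memory containers shared by every pipeline stage.

All downstream modules (relevance scoring, the classifier, interpretation)
operate on these validated types only; file parsing lives in :mod:`scanno.io`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: library-size target for normalization; None scales to the median library
#: size (the scanpy default), which adapts to datasets of any sequencing depth
NORM_TARGET: float | None = None


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def normalize_gene_id(gene: str, uppercase: bool = True) -> str:
    """Canonicalize a gene identifier (strip whitespace, uppercase by default).

    Marker lists and GMT gene sets frequently differ from expression matrices
    only in symbol case; applying the same normalization in every reader makes
    the intersection well defined. Idempotent.
    """
    g = gene.strip()
    return g.upper() if uppercase else g


@dataclass
class ExpressionMatrix:
    """Cells x genes count matrix with identifiers and a lazy log-normal view.

    ``counts`` holds raw nonnegative values (dense ndarray or scipy sparse);
    ``lognorm`` scales each cell to :data:`NORM_TARGET` total counts and
    applies log1p, computed on first access and cached.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray | sp.spmatrix
    _lognorm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n, g = self.counts.shape
        if n != len(self.cell_ids):
            raise ValidationError(
                f"counts has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if g != len(self.gene_ids):
            raise ValidationError(
                f"counts has {g} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({x for x in self.gene_ids if self.gene_ids.count(x) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:10]}")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        mn = self.counts.min() if not sp.issparse(self.counts) else self.counts.min()
        if mn < 0:
            raise ValidationError("negative entries in count matrix")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def dense_counts(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    @property
    def lognorm(self) -> np.ndarray:
        """Log-normalized expression: per-cell library scaling, then log1p.

        Each cell is scaled to the median library size (or :data:`NORM_TARGET`
        when that is set), so the transform adapts to the dataset's depth
        instead of inflating shallow libraries into the flat region of the
        logarithm.
        """
        if self._lognorm is None:
            x = self.dense_counts()
            totals = x.sum(axis=1, keepdims=True)
            target = NORM_TARGET if NORM_TARGET is not None else np.median(totals)
            if target <= 0:
                target = 1.0
            totals[totals == 0] = 1.0
            self._lognorm = np.log1p(x / totals * target)
        return self._lognorm

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class MarkerCatalog:
    """Ordered cell types, each with its ordered, duplicate-free marker list."""

    type_names: list[str]
    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(self.type_names) < 2:
            raise ValidationError("a marker catalog needs at least 2 cell types")
        if len(set(self.type_names)) != len(self.type_names):
            raise ValidationError("duplicate cell type names")
        for t in self.type_names:
            genes = self.markers.get(t)
            if not genes:
                raise ValidationError(f"cell type {t!r} has an empty marker list")
            if len(set(genes)) != len(genes):
                seen: set[str] = set()
                deduped = [g for g in genes if not (g in seen or seen.add(g))]
                warnings.warn(
                    f"duplicate markers for type {t!r} removed", stacklevel=2
                )
                self.markers[t] = deduped

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def pooled_markers(self) -> list[str]:
        """All markers pooled across types, first-appearance order, unique."""
        seen: set[str] = set()
        pool: list[str] = []
        for t in self.type_names:
            for g in self.markers[t]:
                if g not in seen:
                    seen.add(g)
                    pool.append(g)
        return pool

    def types_per_marker(self) -> dict[str, int]:
        """For each pooled marker, the number of cell types listing it."""
        counts: dict[str, int] = {}
        for t in self.type_names:
            for g in set(self.markers[t]):
                counts[g] = counts.get(g, 0) + 1
        return counts


@dataclass
class PathwayCollection:
    """Named gene sets (pathways), as parsed from a GMT file."""

    pathway_names: list[str]
    member_genes: dict[str, set[str]]

    def __post_init__(self) -> None:
        if len(self.pathway_names) < 1:
            raise ValidationError("at least one pathway required")
        if len(set(self.pathway_names)) != len(self.pathway_names):
            raise ValidationError("duplicate pathway names")
        for p in self.pathway_names:
            if p not in self.member_genes:
                raise ValidationError(f"pathway {p!r} has no member set")

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_names)


@dataclass
class GeneEmbedding:
    """Pretrained per-gene vectors used by the embedding-based strategies."""

    gene_ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.gene_ids):
            raise ValidationError("one vector per gene required")
        if self.vectors.shape[1] < 2:
            raise ValidationError("embedding dimension must be >= 2")
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("non-finite entries in gene embedding")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in embedding")

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}
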