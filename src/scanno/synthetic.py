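"""Seeded synthetic scRNA-seq generator with planted structure.

Counts follow a negative-binomial (gamma-Poisson) model with element-wise
dropout; each planted cell type overexpresses its marker genes by a
configurable fold-change. Pathways are built so that each type has one
enriched pathway holding most of its markers plus background gene sets, and
a type-structured gene embedding places marker vectors near their type
centroid. Every pipeline stage can therefore run end to end with no
external data.

The generator emulates the first-order statistical structure marker-based
annotation relies on (type-specific overexpression, shared markers, pathway
grouping); it does not model batch effects, doublets, or realistic
gene-level mean-variance trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    ExpressionMatrix,
    GeneEmbedding,
    MarkerCatalog,
    PathwayCollection,
    ValidationError,
)
from .pseudolabels import PseudoLabelMatrix


@dataclass
class SimConfig:
    """Generator settings.

    ``dispersion`` is the alpha in Var = mu + alpha * mu^2; ``fold_change``
    multiplies the baseline mean for a marker inside its own type;
    ``pathway_marker_fraction`` of each type's markers land in that type's
    enriched pathway (the rest scatter into background sets);
    ``marker_contamination`` shares that fraction of each type's markers
    with the next type (listed and overexpressed in both), making the
    specificity score informative.
    """

    n_cells: int = 1000
    n_genes: int = 300
    n_types: int = 5
    markers_per_type: int = 10
    fold_change: float = 4.0
    nb_mean: float = 2.0
    dispersion: float = 0.5
    proportions: tuple[float, ...] | None = None
    n_pathways: int = 20
    pathway_marker_fraction: float = 0.8
    marker_contamination: float = 0.0
    dropout: float = 0.3
    embed_dim: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValidationError(
                "markers_per_type * n_types exceeds n_genes"
            )
        if self.fold_change < 1.0:
            raise ValidationError("fold_change must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must lie in [0, 1)")
        if self.n_pathways < self.n_types:
            raise ValidationError("need at least one pathway per type")
        if self.proportions is not None:
            if len(self.proportions) != self.n_types:
                raise ValidationError("proportions length != n_types")
            if not np.isclose(sum(self.proportions), 1.0):
                raise ValidationError("proportions must sum to 1")


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    markers: MarkerCatalog
    pathways: PathwayCollection
    embedding: GeneEmbedding
    true_labels: list[str]
    config: SimConfig
    enriched_pathway: dict[str, str] = field(default_factory=dict)


def generate(cfg: SimConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset; bit-identical under a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    T, G, N = cfg.n_types, cfg.n_genes, cfg.n_cells
    mpt = cfg.markers_per_type
    type_names = [f"type_{j}" for j in range(T)]
    gene_ids = [f"G{i:04d}" for i in range(G)]

    # planted markers: contiguous blocks at the front of the gene list
    owner = {}  # gene index -> owning type index
    markers: dict[str, list[str]] = {t: [] for t in type_names}
    for j in range(T):
        for g in range(j * mpt, (j + 1) * mpt):
            owner[g] = j
            markers[type_names[j]].append(gene_ids[g])

    # contamination: share the first markers of each type with the next type
    shared: dict[int, int] = {}  # gene index -> second type index
    n_shared = int(round(cfg.marker_contamination * mpt))
    for j in range(T):
        nxt = (j + 1) % T
        for g in range(j * mpt, j * mpt + n_shared):
            shared[g] = nxt
            markers[type_names[nxt]].append(gene_ids[g])

    props = (np.full(T, 1.0 / T) if cfg.proportions is None
             else np.asarray(cfg.proportions))
    labels_idx = rng.choice(T, size=N, p=props)
    true_labels = [type_names[j] for j in labels_idx]

    # per cell x gene mean matrix: baseline, markers inflated in their type(s)
    mean = np.full((N, G), cfg.nb_mean)
    for g, j in owner.items():
        mean[labels_idx == j, g] *= cfg.fold_change
    for g, j in shared.items():
        mean[labels_idx == j, g] *= cfg.fold_change

    # gamma-Poisson draw (Var = mu + alpha mu^2), then dropout
    alpha = cfg.dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(float)
    if cfg.dropout > 0:
        counts *= rng.random((N, G)) >= cfg.dropout

    expr = ExpressionMatrix(
        cell_ids=[f"cell_{i:05d}" for i in range(N)],
        gene_ids=gene_ids,
        counts=counts,
    )

    if cfg.fold_change > 1.0:
        _check_marker_inflation(counts, labels_idx, owner, shared, type_names)

    pathways, enriched = _build_pathways(cfg, gene_ids, markers, type_names, rng)
    embedding = _build_embedding(cfg, gene_ids, owner, rng)

    return SyntheticDataset(
        expression=expr,
        markers=MarkerCatalog(type_names=type_names, markers=markers),
        pathways=pathways,
        embedding=embedding,
        true_labels=true_labels,
        config=cfg,
        enriched_pathway=enriched,
    )


def _check_marker_inflation(counts, labels_idx, owner, shared, type_names):
    """Every marker's mean in a type listing it must exceed its mean elsewhere."""
    for g, j in owner.items():
        listing = {j} | ({shared[g]} if g in shared else set())
        in_mask = np.isin(labels_idx, list(listing))
        if counts[in_mask, g].mean() <= counts[~in_mask, g].mean():
            raise ValidationError(
                f"planted marker G{g:04d} of {type_names[j]} not overexpressed; "
                "increase n_cells or fold_change"
            )


def _build_pathways(cfg, gene_ids, markers, type_names, rng):
    G, T, mpt = cfg.n_genes, cfg.n_types, cfg.markers_per_type
    n_marker_genes = T * mpt
    non_marker = list(range(n_marker_genes, G))
    names: list[str] = []
    members: dict[str, set[str]] = {}
    enriched: dict[str, str] = {}
    leftover: list[str] = []
    bg_size = max(5, (G - n_marker_genes) // max(cfg.n_pathways - T, 1))

    for j, t in enumerate(type_names):
        n_in = int(round(cfg.pathway_marker_fraction * mpt))
        own = markers[t][:mpt]  # the type's own block, before contamination adds
        chosen = own[:n_in]
        leftover.extend(own[n_in:])
        pad = rng.choice(non_marker, size=min(5, len(non_marker)), replace=False)
        name = f"PW_TYPE_{j}"
        names.append(name)
        members[name] = set(chosen) | {gene_ids[g] for g in pad}
        enriched[t] = name

    for b in range(cfg.n_pathways - T):
        pick = rng.choice(non_marker, size=min(bg_size, len(non_marker)),
                          replace=False)
        name = f"PW_BG_{b}"
        names.append(name)
        members[name] = {gene_ids[g] for g in pick}
    # scatter markers not covered by their type pathway into background sets
    bg_names = [n for n in names if n.startswith("PW_BG_")]
    if bg_names:
        for i, g in enumerate(leftover):
            members[bg_names[i % len(bg_names)]].add(g)
    return PathwayCollection(pathway_names=names, member_genes=members), enriched


def _build_embedding(cfg, gene_ids, owner, rng):
    d = cfg.embed_dim
    centroids = rng.normal(size=(cfg.n_types, d))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    vectors = rng.normal(scale=0.5, size=(len(gene_ids), d))
    for g, j in owner.items():
        vectors[g] = centroids[j] + rng.normal(scale=0.15, size=d)
    return GeneEmbedding(gene_ids=list(gene_ids), vectors=vectors)


def corrupt_pseudolabels(
    L: PseudoLabelMatrix, noise_fraction: float, seed: int = 0
) -> PseudoLabelMatrix:
    """Mix each pseudo-label row with the uniform distribution.

    Returns (1 - noise) * L + noise * 1/T; rows remain on the simplex. The
    mixing is deterministic; ``seed`` is accepted for interface symmetry
    with the stochastic generators.
    """
    if not (0 <= noise_fraction <= 1):
        raise ValidationError("noise_fraction must lie in [0, 1]")
    T = len(L.type_names)
    values = (1 - noise_fraction) * L.values + noise_fraction / T
    return PseudoLabelMatrix(
        values, L.cell_ids, L.type_names,
        f"{L.source_strategy}+noise{noise_fraction:g}",
    )


def write_fixture(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the on-disk dialects the readers consume.

    Emits matrix.mtx + genes.tsv + barcodes.tsv, markers.csv, pathways.gmt,
    embedding.tsv, and truth.csv under ``outdir``.
    """
    from . import io as io_mod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mtx = outdir / "matrix.mtx"
    scipy.io.mmwrite(mtx, sp.csr_matrix(ds.expression.dense_counts()))
    (outdir / "genes.tsv").write_text(
        "".join(g + "\n" for g in ds.expression.gene_ids)
    )
    (outdir / "barcodes.tsv").write_text(
        "".join(c + "\n" for c in ds.expression.cell_ids)
    )
    paths["expression"] = outdir

    markers_csv = outdir / "markers.csv"
    with open(markers_csv, "w") as fh:
        fh.write("cell_type,gene\n")
        for t in ds.markers.type_names:
            for g in ds.markers.markers[t]:
                fh.write(f"{t},{g}\n")
    paths["markers"] = markers_csv

    gmt = outdir / "pathways.gmt"
    io_mod.write_gmt(ds.pathways, gmt)
    paths["pathways"] = gmt

    emb = outdir / "embedding.tsv"
    io_mod.write_gene_embedding(ds.embedding, emb)
    paths["embedding"] = emb

    truth = outdir / "truth.csv"
    with open(truth, "w") as fh:
        fh.write("cell_id,true_type\n")
        for c, t in zip(ds.expression.cell_ids, ds.true_labels):
            fh.write(f"{c},{t}\n")
    paths["truth"] = truth
    return paths
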