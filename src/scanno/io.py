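"""Readers and writers for the on-disk formats the pipeline touches.

Expression matrices arrive as Matrix Market triplet directories
(matrix.mtx + genes.tsv + barcodes.tsv), dense CSV (cells in rows), or h5ad.
Marker catalogs are two-column CSV or GMT; pathway gene sets are GMT.
All gene identifiers pass through the same case normalization so that
intersections across files are well defined.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    ExpressionMatrix,
    GeneEmbedding,
    MarkerCatalog,
    PathwayCollection,
    ValidationError,
    normalize_gene_id,
)
from .model import PathwayMask

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when a file cannot be parsed as its declared format."""


def _read_id_column(path: Path) -> list[str]:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def read_expression(
    path: str | Path,
    fmt: str = "mtx_dir",
    *,
    uppercase_genes: bool = True,
    orientation: str = "auto",
) -> ExpressionMatrix:
    """Read an expression matrix, returned oriented cells x genes.

    Parameters
    ----------
    path
        Directory (``mtx_dir``) or file (``csv``, ``h5ad``).
    fmt
        One of ``{"mtx_dir", "csv", "h5ad"}``.
    orientation
        For ``mtx_dir``: ``auto`` detects via companion-file lengths; a square
        matrix with equal companions requires ``cells-rows`` or ``genes-rows``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if fmt == "mtx_dir":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        barcodes_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise FormatError(f"missing companion file {f.name} in {path}")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:  # malformed header / body
            raise FormatError(f"cannot parse {mtx}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        genes = [normalize_gene_id(g, uppercase_genes) for g in _read_id_column(genes_f)]
        barcodes = _read_id_column(barcodes_f)
        r, c = mat.shape
        if orientation == "cells-rows":
            pass
        elif orientation == "genes-rows":
            mat = mat.T.tocsr()
        elif (r, c) == (len(barcodes), len(genes)) and (r, c) != (len(genes), len(barcodes)):
            pass
        elif (r, c) == (len(genes), len(barcodes)) and (r, c) != (len(barcodes), len(genes)):
            mat = mat.T.tocsr()
        elif (r, c) == (len(barcodes), len(genes)):  # square and consistent both ways
            raise FormatError(
                "square matrix with equal-length companions: pass orientation="
                "'cells-rows' or 'genes-rows' explicitly"
            )
        else:
            raise FormatError(
                f"matrix shape {mat.shape} matches neither companion lengths "
                f"({len(barcodes)} barcodes, {len(genes)} genes)"
            )
        return ExpressionMatrix(cell_ids=barcodes, gene_ids=genes, counts=mat)

    if fmt == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"{path} has no gene columns")
        genes = [normalize_gene_id(g, uppercase_genes) for g in df.columns]
        return ExpressionMatrix(
            cell_ids=[str(i) for i in df.index],
            gene_ids=genes,
            counts=df.to_numpy(dtype=float),
        )

    if fmt == "h5ad":
        try:
            import anndata
        except ImportError as exc:  # pragma: no cover - anndata is a hard dep
            raise FormatError("h5ad support requires anndata") from exc
        ad = anndata.read_h5ad(path)
        x = ad.X
        if sp.issparse(x):
            x = sp.csr_matrix(x)
        else:
            x = np.asarray(x, dtype=float)
        genes = [normalize_gene_id(g, uppercase_genes) for g in ad.var_names]
        return ExpressionMatrix(
            cell_ids=[str(c) for c in ad.obs_names], gene_ids=genes, counts=x
        )

    raise ValueError(f"unknown expression format {fmt!r}")


def read_markers(
    path: str | Path, fmt: str = "csv", *, uppercase_genes: bool = True
) -> MarkerCatalog:
    """Read a marker catalog mapping cell types to marker gene lists.

    CSV requires columns ``cell_type`` and ``gene``; GMT rows are
    ``type<TAB>description<TAB>gene...``. Types appear in file order;
    duplicate markers within a type are dropped with a warning.
    """
    path = Path(path)
    type_names: list[str] = []
    markers: dict[str, list[str]] = {}

    if fmt == "csv":
        df = pd.read_csv(path)
        missing = {"cell_type", "gene"} - set(df.columns)
        if missing:
            raise FormatError(f"marker CSV missing columns {sorted(missing)}")
        for _, row in df.iterrows():
            t = str(row["cell_type"])
            g = normalize_gene_id(str(row["gene"]), uppercase_genes)
            if t not in markers:
                type_names.append(t)
                markers[t] = []
            if g in markers[t]:
                warnings.warn(f"duplicate marker ({t},{g}) ignored", stacklevel=2)
            else:
                markers[t].append(g)
    elif fmt == "gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: GMT row needs >=3 fields"
                    )
                t = fields[0]
                genes = [
                    normalize_gene_id(g, uppercase_genes)
                    for g in fields[2:]
                    if g.strip()
                ]
                type_names.append(t)
                markers[t] = list(dict.fromkeys(genes))
    else:
        raise ValueError(f"unknown marker format {fmt!r}")

    return MarkerCatalog(type_names=type_names, markers=markers)


def read_gmt(path: str | Path, *, uppercase_genes: bool = True) -> PathwayCollection:
    """Parse a GMT file (name, description, member genes; tab-separated).

    The description field is discarded; duplicate genes within a set collapse.
    """
    path = Path(path)
    names: list[str] = []
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT row needs >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            genes = [
                normalize_gene_id(g, uppercase_genes) for g in fields[2:] if g.strip()
            ]
            if name in members:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            names.append(name)
            members[name] = set(genes)
    if not names:
        raise FormatError(f"{path}: empty GMT file")
    return PathwayCollection(pathway_names=names, member_genes=members)


def write_gmt(pc: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in pc.pathway_names:
            genes = sorted(pc.member_genes[name])
            fh.write("\t".join([name, "na", *genes]) + "\n")


def build_pathway_mask(
    pc: PathwayCollection,
    genes: list[str],
    *,
    keep_unassigned: bool = False,
) -> PathwayMask:
    """Build the k x G binary pathway-membership mask over a gene list.

    Genes belonging to no pathway are dropped from the model gene list by
    default, or pooled into a synthetic ``UNASSIGNED`` pathway row when
    ``keep_unassigned`` is set. Pathways with zero overlap are dropped with a
    warning.
    """
    if not genes:
        raise ValidationError("gene list is empty")
    gene_set = set(genes)
    kept_names: list[str] = []
    rows: list[set[str]] = []
    for name in pc.pathway_names:
        overlap = pc.member_genes[name] & gene_set
        if overlap:
            kept_names.append(name)
            rows.append(overlap)
        else:
            warnings.warn(f"pathway {name!r} has no overlap with gene list; dropped",
                          stacklevel=2)
    if not kept_names:
        raise ValidationError("all pathways empty after intersecting with gene list")

    assigned = set().union(*rows)
    if keep_unassigned:
        unassigned = gene_set - assigned
        if unassigned:
            kept_names.append("UNASSIGNED")
            rows.append(unassigned)
        model_genes = [g for g in genes]
    else:
        model_genes = [g for g in genes if g in assigned]

    mask = np.zeros((len(kept_names), len(model_genes)), dtype=float)
    gidx = {g: i for i, g in enumerate(model_genes)}
    for r, members in enumerate(rows):
        for g in members:
            mask[r, gidx[g]] = 1.0
    return PathwayMask(matrix=mask, pathway_names=kept_names, gene_ids=model_genes)


def read_gene_embedding(
    path: str | Path, *, uppercase_genes: bool = True
) -> GeneEmbedding:
    """Read a TSV of gene id followed by d float coordinates per row."""
    path = Path(path)
    genes: list[str] = []
    vecs: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: need gene id + >=2 floats")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {width})"
                )
            genes.append(normalize_gene_id(fields[0], uppercase_genes))
            try:
                vecs.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    if not genes:
        raise FormatError(f"{path}: empty embedding table")
    return GeneEmbedding(gene_ids=genes, vectors=np.array(vecs))


def write_gene_embedding(emb: GeneEmbedding, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g, v in zip(emb.gene_ids, emb.vectors):
            fh.write("\t".join([g, *(repr(float(x)) for x in v)]) + "\n")


def write_predictions(
    cell_ids: list[str],
    type_names: list[str],
    probabilities: np.ndarray,
    path: str | Path,
) -> None:
    """Write per-cell predictions: cell_id, argmax type, one column per type."""
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.shape != (len(cell_ids), len(type_names)):
        raise ValidationError("probability matrix shape mismatch")
    pred = [type_names[j] for j in probabilities.argmax(axis=1)]
    df = pd.DataFrame(probabilities, columns=type_names)
    df.insert(0, "predicted_type", pred)
    df.insert(0, "cell_id", cell_ids)
    df.to_csv(path, index=False, float_format="%.10g")


def write_attention(
    cell_ids: list[str],
    pathway_names: list[str],
    attention: np.ndarray,
    path: str | Path,
) -> None:
    """Write the cells x pathways CLS-attention profile matrix as CSV."""
    attention = np.asarray(attention, dtype=float)
    if attention.shape != (len(cell_ids), len(pathway_names)):
        raise ValidationError("attention matrix shape mismatch")
    df = pd.DataFrame(attention, index=cell_ids, columns=pathway_names)
    df.index.name = "cell_id"
    df.to_csv(path, float_format="%.17g")


def read_attention(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return list(df.index.astype(str)), list(df.columns), df.to_numpy(dtype=float)
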