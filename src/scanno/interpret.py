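"""Attention-based interpretation.

The CLS row of the attention matrix, averaged over heads and restricted to
pathway columns, gives each cell a k-dimensional pathway-attention profile.
Profiles are clustered (scale to a fixed total, log1p, PCA, kNN graph,
Louvain), and per-cluster signature pathways are ranked by a one-vs-rest
Wilcoxon rank-sum test with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, tiecorrect, rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError


@dataclass
class AttentionProfileMatrix:
    """N x k head-averaged CLS-to-pathway attention weights."""

    values: np.ndarray
    cell_ids: list[str]
    pathway_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.pathway_names)):
            raise ValidationError("attention profile shape mismatch")
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise ValidationError("attention profiles must be finite and >= 0")


@dataclass
class InterpretConfig:
    """Clustering settings: profile scaling total, PCA size, kNN size,
    Louvain resolution, and the seed for the (randomized) Louvain pass."""

    total_scaling: float = 1e4
    n_components: int = 50
    n_neighbors: int = 15
    resolution: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.total_scaling, self.n_components, self.n_neighbors,
               self.resolution) <= 0:
            raise ValidationError("all interpret settings must be positive")


def extract_attention_profiles(model, X: np.ndarray) -> AttentionProfileMatrix:
    """Head-averaged CLS-to-pathway attention for every cell (evaluation mode)."""
    if not getattr(model, "supports_attention", False):
        raise ValidationError(
            "model carries no attention (logistic-regression ablation?)"
        )
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, A = model.forward(X, return_attention=True)
    profiles = A.mean(axis=1)[:, 0, 1:]  # average heads, CLS row, drop CLS col
    cell_ids = [str(i) for i in range(X.shape[0])]
    return AttentionProfileMatrix(profiles, cell_ids, model.mask.pathway_names)


def cluster_attention(
    profiles: AttentionProfileMatrix, cfg: InterpretConfig | None = None
) -> np.ndarray:
    """Louvain subclusters of attention profiles.

    Profiles are scaled per cell to ``total_scaling``, log1p-transformed,
    reduced by PCA, linked by a symmetrized kNN graph, and partitioned by
    the Louvain algorithm at the configured resolution. Labels are 0-based
    and contiguous, ordered by decreasing cluster size.
    """
    cfg = cfg or InterpretConfig()
    V = profiles.values
    n, k = V.shape
    if n < cfg.n_neighbors + 1:
        raise ValidationError(
            f"need at least n_neighbors+1={cfg.n_neighbors + 1} cells, got {n}"
        )
    if np.allclose(V, V[0]):
        warnings.warn("all attention profiles identical; single cluster",
                      stacklevel=2)
        return np.zeros(n, dtype=int)

    totals = V.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    Xs = np.log1p(V / totals * cfg.total_scaling)
    n_comp = min(cfg.n_components, k, n - 1)
    coords = PCA(n_components=n_comp, random_state=cfg.seed).fit_transform(Xs)

    nn = NearestNeighbors(n_neighbors=cfg.n_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {tuple(sorted((i, j))) for i, row in enumerate(idx) for j in row[1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges))

    random.seed(cfg.seed)  # igraph draws from Python's random module
    membership = np.array(
        graph.community_multilevel(resolution=cfg.resolution).membership
    )
    # relabel contiguously by decreasing size
    order = pd.Series(membership).value_counts().index.to_list()
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in membership], dtype=int)


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal-approximation z for the Wilcoxon rank-sum test."""
    n1, n2 = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    expected = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(tiecorrect(ranks) * n1 * n2 * (n1 + n2 + 1) / 12.0)
    if sd == 0:
        return 0.0
    return float((r1 - expected) / sd)


def signature_attentions(
    profiles: AttentionProfileMatrix,
    labels: np.ndarray,
    *,
    total_scaling: float = 1e4,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Rank pathways per cluster by one-vs-rest Wilcoxon rank-sum.

    Profiles are scaled and log1p-transformed as for clustering; for each
    cluster, every pathway is tested one-vs-rest with the alternative that
    the cluster's attention is greater. Returns a tidy table with columns
    cluster, pathway, statistic, pvalue, qvalue (Benjamini-Hochberg within
    cluster), rank — ranked by descending statistic, ties broken by pathway
    name for determinism.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 clusters for signature testing")
    V = profiles.values
    totals = V.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    Xs = np.log1p(V / totals * total_scaling)

    records = []
    for c in uniq:
        in_c = labels == c
        if in_c.sum() < min_cluster_size:
            warnings.warn(f"cluster {c} below minimum size; skipped", stacklevel=2)
            continue
        stats, pvals = [], []
        exact_ok = in_c.sum() <= 10 and (~in_c).sum() <= 10
        for g, name in enumerate(profiles.pathway_names):
            x, y = Xs[in_c, g], Xs[~in_c, g]
            method = "exact" if exact_ok and len(np.unique(Xs[:, g])) == len(Xs) \
                else "asymptotic"
            res = mannwhitneyu(x, y, alternative="greater", method=method)
            stats.append(_ranksum_z(x, y))
            pvals.append(float(res.pvalue))
        qvals = multipletests(pvals, method="fdr_bh")[1]
        df = pd.DataFrame({
            "cluster": c,
            "pathway": profiles.pathway_names,
            "statistic": stats,
            "pvalue": pvals,
            "qvalue": qvals,
        })
        df = df.sort_values(
            ["statistic", "pathway"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        records.append(df)
    if not records:
        raise ValidationError("no cluster met the minimum size")
    return pd.concat(records, ignore_index=True)
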