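"""Relevance strategies against brute-force oracles and hand computations."""

import numpy as np
import pytest

from scanno import (
    ExpressionMatrix,
    GeneEmbedding,
    MarkerCatalog,
    compute_relevance,
    compute_specificity,
    embed_cells_and_types,
    score_cell_type_specific,
    score_cosine,
    score_count,
    score_lr,
    score_pseudocell,
)
from scanno.relevance import PseudoCellConfig, generate_pseudocells


def random_instance(seed, n=50, g=30, t=4, markers_per_type=5):
    """Random expression + catalog + embedding instance for oracle checks."""
    rng = np.random.default_rng(seed)
    expr = ExpressionMatrix(
        cell_ids=[f"c{i}" for i in range(n)],
        gene_ids=[f"G{i}" for i in range(g)],
        counts=rng.poisson(1.5, size=(n, g)).astype(float),
    )
    markers = {}
    for j in range(t):
        picks = rng.choice(g, size=markers_per_type, replace=False)
        markers[f"T{j}"] = [f"G{i}" for i in picks]
    cat = MarkerCatalog(type_names=[f"T{j}" for j in range(t)], markers=markers)
    emb = GeneEmbedding(
        gene_ids=[f"G{i}" for i in range(g)],
        vectors=rng.normal(size=(g, 6)),
    )
    return expr, cat, emb


# ---------------------------------------------------------------- count
def test_count_hand_example():
    expr = ExpressionMatrix(
        cell_ids=["c"], gene_ids=["G1", "G2", "G3", "G4"],
        counts=np.array([[1.0, 0, 3, 0]]),
    )
    cat = MarkerCatalog(
        type_names=["A", "B"], markers={"A": ["G1", "G3"], "B": ["G2"]}
    )
    R = score_count(expr, cat)
    np.testing.assert_array_equal(R.values, [[2, 0]])


def test_count_all_zero_cell_scores_zero(toy_catalog):
    expr = ExpressionMatrix(
        cell_ids=["c"], gene_ids=[f"G{i}" for i in range(10)],
        counts=np.zeros((1, 10)),
    )
    R = score_count(expr, toy_catalog)
    np.testing.assert_array_equal(R.values, 0.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_count_matches_per_marker_loop_oracle(seed):
    expr, cat, _ = random_instance(seed, n=20, g=10, t=3)
    R = score_count(expr, cat)
    x = expr.dense_counts()
    for i in range(expr.n_cells):
        for j, t in enumerate(cat.type_names):
            expected = sum(
                x[i, expr.gene_ids.index(m)] > 0 for m in cat.markers[t]
            )
            assert R.values[i, j] == expected


def test_count_invariant_to_monotone_rescaling(toy_expression, toy_catalog):
    R1 = score_count(toy_expression, toy_catalog)
    scaled = ExpressionMatrix(
        cell_ids=toy_expression.cell_ids,
        gene_ids=toy_expression.gene_ids,
        counts=toy_expression.dense_counts() * 37.5,
    )
    R2 = score_count(scaled, toy_catalog)
    np.testing.assert_array_equal(R1.values, R2.values)


# ---------------------------------------------------------------- embeddings
def test_single_gene_cell_embedding_equals_gene_vector():
    expr = ExpressionMatrix(
        cell_ids=["c"], gene_ids=["G1", "G2"], counts=np.array([[5.0, 0.0]])
    )
    cat = MarkerCatalog(
        type_names=["A", "B"], markers={"A": ["G1", "G2"], "B": ["G2"]}
    )
    emb = GeneEmbedding(gene_ids=["G1", "G2"],
                        vectors=np.array([[1.0, 2.0], [3.0, 4.0]]))
    ce = embed_cells_and_types(expr, cat, emb)
    np.testing.assert_allclose(ce.cell_vectors[0], [1.0, 2.0])
    np.testing.assert_allclose(ce.type_vectors[0], [2.0, 3.0])  # mean of both


@pytest.mark.parametrize("seed", [0, 5])
def test_embeddings_match_weighted_average_oracle(seed):
    expr, cat, emb = random_instance(seed)
    ce = embed_cells_and_types(expr, cat, emb)
    x = expr.dense_counts()
    E = emb.vectors
    for i in range(expr.n_cells):
        expected = x[i] @ E / x[i].sum()
        np.testing.assert_allclose(ce.cell_vectors[i], expected, atol=1e-10)
    for j, t in enumerate(cat.type_names):
        rows = [emb.gene_ids.index(m) for m in cat.markers[t]]
        np.testing.assert_allclose(
            ce.type_vectors[j], E[rows].mean(axis=0), atol=1e-10
        )


# ---------------------------------------------------------------- cosine
def test_cosine_identical_orthogonal_and_oracle():
    from scanno.relevance import CellTypeEmbeddings

    ce = CellTypeEmbeddings(
        cell_vectors=np.array([[1.0, 0.0], [0.0, 2.0], [0.0, 0.0]]),
        type_vectors=np.array([[2.0, 0.0], [0.0, 1.0]]),
        cell_ids=["a", "b", "z"],
        type_names=["T0", "T1"],
    )
    R = score_cosine(ce)
    np.testing.assert_allclose(R.values[0], [1.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(R.values[1], [0.0, 1.0], atol=1e-12)
    np.testing.assert_allclose(R.values[2], [0.0, 0.0])  # zero-norm convention

    rng = np.random.default_rng(0)
    ce2 = CellTypeEmbeddings(
        cell_vectors=rng.normal(size=(10, 4)),
        type_vectors=rng.normal(size=(3, 4)),
        cell_ids=[str(i) for i in range(10)],
        type_names=["A", "B", "C"],
    )
    R2 = score_cosine(ce2)
    for i in range(10):
        for j in range(3):
            u, v = ce2.cell_vectors[i], ce2.type_vectors[j]
            expected = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            assert abs(R2.values[i, j] - expected) < 1e-12


# ---------------------------------------------------------------- LR
def test_lr_rows_sum_to_one_and_recovers_separable_types():
    rng = np.random.default_rng(1)
    t, d = 4, 6
    type_vecs = np.eye(t, d) * 10
    expr, cat, _ = random_instance(0, n=1, g=30, t=t)
    from scanno.relevance import CellTypeEmbeddings

    ce = CellTypeEmbeddings(
        cell_vectors=type_vecs + rng.normal(scale=0.01, size=(t, d)),
        type_vectors=type_vecs,
        cell_ids=[f"c{i}" for i in range(t)],
        type_names=cat.type_names,
    )
    emb = GeneEmbedding(gene_ids=["G1", "G2"], vectors=np.zeros((2, d)))
    R = score_lr(ce, cat, emb, mode="label")
    np.testing.assert_allclose(R.values.sum(axis=1), 1.0, atol=1e-9)
    assert list(R.values.argmax(axis=1)) == [0, 1, 2, 3]


def test_lr_marker_with_one_marker_per_type_equals_label_mode():
    rng = np.random.default_rng(2)
    genes = ["G0", "G1", "G2"]
    cat = MarkerCatalog(
        type_names=["A", "B", "C"],
        markers={"A": ["G0"], "B": ["G1"], "C": ["G2"]},
    )
    emb = GeneEmbedding(gene_ids=genes, vectors=rng.normal(size=(3, 5)))
    from scanno.relevance import CellTypeEmbeddings

    ce = CellTypeEmbeddings(
        cell_vectors=rng.normal(size=(8, 5)),
        type_vectors=emb.vectors,  # single-marker types: mean == the marker
        cell_ids=[str(i) for i in range(8)],
        type_names=cat.type_names,
    )
    R_label = score_lr(ce, cat, emb, mode="label")
    R_marker = score_lr(ce, cat, emb, mode="marker")
    np.testing.assert_allclose(R_label.values, R_marker.values, atol=1e-9)


# ---------------------------------------------------------------- pseudo-cell
def test_vmf_concentration_limit():
    expr, cat, emb = random_instance(3)
    ce = embed_cells_and_types(expr, cat, emb)
    from scipy.stats import vonmises_fisher

    mu = ce.type_vectors[0] / np.linalg.norm(ce.type_vectors[0])
    rng = np.random.default_rng(0)
    dirs = vonmises_fisher(mu, 1e8).rvs(50, random_state=rng)
    np.testing.assert_allclose(dirs, np.tile(mu, (50, 1)), atol=1e-3)


def test_pseudocells_cluster_near_their_type():
    expr, cat, emb = random_instance(4)
    ce = embed_cells_and_types(expr, cat, emb)
    X, y = generate_pseudocells(ce, emb, PseudoCellConfig(n_per_type=100), seed=0)
    tn = ce.type_vectors / np.linalg.norm(ce.type_vectors, axis=1, keepdims=True)
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    cos = Xn @ tn.T
    for j in range(len(cat.type_names)):
        own = cos[y == j, j].mean()
        others = [cos[y == j, o].mean() for o in range(len(cat.type_names)) if o != j]
        assert own > max(others)


def test_pseudocell_deterministic_under_seed():
    expr, cat, emb = random_instance(5)
    ce = embed_cells_and_types(expr, cat, emb)
    R1 = score_pseudocell(ce, cat, emb, PseudoCellConfig(n_per_type=50), seed=11)
    R2 = score_pseudocell(ce, cat, emb, PseudoCellConfig(n_per_type=50), seed=11)
    np.testing.assert_array_equal(R1.values, R2.values)


# ---------------------------------------------------------------- specificity
def test_specificity_forced_values():
    cat = MarkerCatalog(
        type_names=["A", "B", "C"],
        markers={
            "A": ["M1", "M2", "M3"],
            "B": ["M2", "M3", "M4"],
            "C": ["M3", "M5"],
        },
    )
    spec = compute_specificity(cat)
    s = spec.as_dict()
    # M1,M4,M5 in 1 type -> 1; M2 in 2 -> 0.5; M3 in 3 -> 0
    assert s["M1"] == s["M4"] == s["M5"] == 1.0
    assert s["M2"] == 0.5
    assert s["M3"] == 0.0


def test_specificity_degenerate_all_unique(toy_expression):
    cat = MarkerCatalog(
        type_names=["A", "B"], markers={"A": ["G0"], "B": ["G1"]}
    )
    spec = compute_specificity(cat)
    np.testing.assert_array_equal(spec.scores, 1.0)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_specificity_matches_formula_oracle_and_order_invariance(seed):
    expr, cat, _ = random_instance(seed, t=4, markers_per_type=6)
    spec = compute_specificity(cat)
    counts = {}
    for t in cat.type_names:
        for g in set(cat.markers[t]):
            counts[g] = counts.get(g, 0) + 1
    vals = list(counts.values())
    lo, hi = min(vals), max(vals)
    for g, s in spec.as_dict().items():
        expected = 1.0 if hi == lo else 1 - (counts[g] - lo) / (hi - lo)
        assert abs(s - expected) < 1e-12

    shuffled = MarkerCatalog(
        type_names=list(reversed(cat.type_names)),
        markers={t: list(reversed(m)) for t, m in cat.markers.items()},
    )
    spec2 = compute_specificity(shuffled)
    assert spec.as_dict() == spec2.as_dict()


# ------------------------------------------------- cell-type-specific
def test_constant_gene_contributes_zero():
    expr = ExpressionMatrix(
        cell_ids=["c1", "c2"], gene_ids=["G1", "G2"],
        counts=np.array([[3.0, 1.0], [3.0, 5.0]]),
    )
    cat = MarkerCatalog(type_names=["A", "B"],
                        markers={"A": ["G1"], "B": ["G2"]})
    # G1 constant in counts but not after library normalization; force by
    # making both cells identical totals
    R = score_cell_type_specific(expr, cat)
    assert np.all(np.isfinite(R.values))


def test_two_cell_hand_zscore():
    # single single-type marker, counts [0, 2]; second gene fixes equal
    # library sizes so normalization keeps the [0, >0] pattern
    expr = ExpressionMatrix(
        cell_ids=["c1", "c2"], gene_ids=["G1", "G2"],
        counts=np.array([[0.0, 2.0], [2.0, 0.0]]),
    )
    cat = MarkerCatalog(type_names=["A", "B"],
                        markers={"A": ["G1"], "B": ["G2"]})
    R = score_cell_type_specific(expr, cat)
    # z-score of a two-point sample is [-1, +1] (population sd)
    np.testing.assert_allclose(R.values[:, 0], [-1.0, 1.0], atol=1e-10)
    np.testing.assert_allclose(R.values[:, 1], [1.0, -1.0], atol=1e-10)


@pytest.mark.parametrize("seed", [0, 1])
def test_cell_type_specific_matches_naive_loop(seed):
    expr, cat, _ = random_instance(seed)
    spec = compute_specificity(cat)
    R = score_cell_type_specific(expr, cat, spec)
    x = expr.lognorm
    s = spec.as_dict()
    for i in range(expr.n_cells):
        for j, t in enumerate(cat.type_names):
            total = 0.0
            for m in cat.markers[t]:
                col = expr.gene_ids.index(m)
                mu, sd = x[:, col].mean(), x[:, col].std(ddof=0)
                z = 0.0 if sd == 0 else (x[i, col] - mu) / sd
                total += z * s[m]
            expected = total / len(cat.markers[t])
            assert abs(R.values[i, j] - expected) < 1e-10


def test_all_strategies_finite_on_zero_cells():
    expr = ExpressionMatrix(
        cell_ids=["c1", "c2"], gene_ids=[f"G{i}" for i in range(6)],
        counts=np.vstack([np.zeros(6), np.arange(6, dtype=float)]),
    )
    cat = MarkerCatalog(type_names=["A", "B"],
                        markers={"A": ["G0", "G1"], "B": ["G4", "G5"]})
    emb = GeneEmbedding(gene_ids=[f"G{i}" for i in range(6)],
                        vectors=np.random.default_rng(0).normal(size=(6, 4)))
    for strat in ["count", "cos", "lr-label", "lr-marker", "pseudo-cell",
                  "cell-type-specific"]:
        with np.errstate(all="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                R = compute_relevance(expr, cat, strat, emb=emb, seed=0)
        assert np.all(np.isfinite(R.values)), strat


def test_unknown_strategy_lists_valid_names(toy_expression, toy_catalog):
    with pytest.raises(ValueError, match="cell-type-specific"):
        compute_relevance(toy_expression, toy_catalog, "bogus")
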