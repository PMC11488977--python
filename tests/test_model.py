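"""The masked attention classifier: exactness, mask faithfulness, gradients."""

import numpy as np
import pytest

from scanno import (
    LinearSoftmaxModel,
    PathwayMask,
    PathwayTransformer,
    TransformerConfig,
    init_params,
)
from scanno.datatypes import ValidationError


@pytest.fixture()
def tiny_model():
    mask = PathwayMask(
        matrix=np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]]),
        pathway_names=["p1", "p2"],
        gene_ids=["G1", "G2", "G3"],
    )
    cfg = TransformerConfig(n_types=2, embed_dim=2, n_heads=1, seed=0)
    return PathwayTransformer(cfg, mask)


def test_init_reproducible_and_masked_zero(tiny_model):
    p1 = init_params(tiny_model.cfg, tiny_model.mask, seed=5)
    p2 = init_params(tiny_model.cfg, tiny_model.mask, seed=5)
    for k in p1:
        np.testing.assert_array_equal(p1[k], p2[k])
    p3 = init_params(tiny_model.cfg, tiny_model.mask, seed=6)
    assert any(not np.array_equal(p1[k], p3[k]) for k in p1)
    # masked positions zero: gene G3 not in p1, gene G1 not in p2
    assert np.all(p1["W_embed"][0, 2, :] == 0)
    assert np.all(p1["W_embed"][1, 0, :] == 0)


def test_embed_dim_not_divisible_is_error():
    with pytest.raises(ValidationError):
        TransformerConfig(n_types=2, embed_dim=10, n_heads=3)


def test_mask_rejects_nonbinary_and_empty_rows():
    with pytest.raises(ValidationError):
        PathwayMask(np.array([[0.5]]), ["p"], ["g"])
    with pytest.raises(ValidationError, match="all-zero"):
        PathwayMask(np.array([[1.0, 0.0], [0.0, 0.0]]), ["p", "q"], ["a", "b"])


def test_embed_tokens_zero_input_and_mask_faithfulness(tiny_model):
    I0 = tiny_model.embed_tokens(np.zeros(3))
    np.testing.assert_array_equal(I0[1:], 0.0)
    np.testing.assert_array_equal(I0[0], tiny_model.params["CLS"])

    x = np.array([1.0, 2.0, 3.0])
    I1 = tiny_model.embed_tokens(x)
    # perturbing G3 (masked out of pathway p1) leaves token p1 bit-identical
    x2 = x.copy()
    x2[2] = 99.0
    I2 = tiny_model.embed_tokens(x2)
    np.testing.assert_array_equal(I1[1], I2[1])
    assert not np.array_equal(I1[2], I2[2])


def test_single_gene_pathway_token_is_weight_times_expression():
    mask = PathwayMask(np.array([[0.0, 1.0]]), ["p"], ["G1", "G2"])
    cfg = TransformerConfig(n_types=2, embed_dim=2, n_heads=1, seed=1)
    model = PathwayTransformer(cfg, mask)
    x = np.array([5.0, 3.0])
    I = model.embed_tokens(x)
    np.testing.assert_allclose(I[1], model.params["W_embed"][0, 1, :] * 3.0,
                               atol=1e-12)


def test_forward_rows_stochastic(tiny_model):
    rng = np.random.default_rng(0)
    X = rng.random((7, 3)) * 3
    probs, A = tiny_model.forward(X, return_attention=True)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-5)
    assert A.shape == (7, 1, 3, 3)


def test_hand_worked_forward_pass():
    """One head, two pathways, m=2: compare against explicit matrix algebra."""
    mask = PathwayMask(
        matrix=np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]]),
        pathway_names=["p1", "p2"],
        gene_ids=["G1", "G2", "G3"],
    )
    cfg = TransformerConfig(n_types=2, embed_dim=2, n_heads=1, seed=0)
    model = PathwayTransformer(cfg, mask)
    model.params = {
        "W_embed": np.array([
            [[0.1, -0.2], [0.3, 0.4], [9.0, 9.0]],   # G3 masked in p1
            [[9.0, 9.0], [-0.5, 0.2], [0.6, -0.1]],  # G1 masked in p2
        ]),
        "CLS": np.array([0.2, -0.1]),
        "Wq": np.array([[0.5, -0.3], [0.2, 0.7]]),
        "Wk": np.array([[-0.4, 0.6], [0.1, 0.3]]),
        "Wv": np.array([[0.9, 0.0], [-0.2, 0.5]]),
        "Wp": np.array([[1.0, -1.0], [0.5, 2.0]]),
        "bp": np.array([0.1, -0.1]),
    }
    x = np.array([1.0, 2.0, 3.0])

    # --- independent hand computation, plain formulas only ---
    t1 = 1.0 * np.array([0.1, -0.2]) + 2.0 * np.array([0.3, 0.4])
    t2 = 2.0 * np.array([-0.5, 0.2]) + 3.0 * np.array([0.6, -0.1])
    I = np.vstack([[0.2, -0.1], t1, t2])
    Q = I @ model.params["Wq"]
    K = I @ model.params["Wk"]
    V = I @ model.params["Wv"]
    scores = Q @ K.T / np.sqrt(2.0)
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    A = e / e.sum(axis=1, keepdims=True)
    O = A @ V
    logits = model.params["Wp"] @ O[0] + model.params["bp"]
    expect = np.exp(logits - logits.max())
    expect = expect / expect.sum()

    probs, Arec = model.forward(x[None, :], return_attention=True)
    np.testing.assert_allclose(probs[0], expect, atol=1e-8)
    np.testing.assert_allclose(Arec[0, 0], A, atol=1e-8)
    np.testing.assert_allclose(model.embed_tokens(x), I, atol=1e-12)


def test_gene_permutation_invariance(small_dataset):
    from scanno.io import build_pathway_mask

    mask = build_pathway_mask(small_dataset.pathways,
                              small_dataset.expression.gene_ids)
    cfg = TransformerConfig(n_types=3, embed_dim=8, n_heads=2, seed=0)
    model = PathwayTransformer(cfg, mask)
    gidx = small_dataset.expression.gene_index()
    X = small_dataset.expression.lognorm[:10, [gidx[g] for g in mask.gene_ids]]
    probs, _ = model.forward(X)

    rng = np.random.default_rng(4)
    perm = rng.permutation(len(mask.gene_ids))
    mask_p = PathwayMask(mask.matrix[:, perm], mask.pathway_names,
                         [mask.gene_ids[i] for i in perm])
    model_p = PathwayTransformer(cfg, mask_p,
                                 params={k: v.copy() for k, v in
                                         model.params.items()})
    model_p.params["W_embed"] = model.params["W_embed"][:, perm, :]
    probs_p, _ = model_p.forward(X[:, perm])
    np.testing.assert_allclose(probs, probs_p, atol=1e-8)


def test_gradients_match_finite_differences(tiny_model):
    """Exact backprop vs central finite differences on every parameter."""
    rng = np.random.default_rng(1)
    X = rng.random((4, 3))
    L = rng.dirichlet(np.ones(2), size=4)
    _, grads = tiny_model.loss_and_grads(X, L)
    h = 1e-6
    for name, g in grads.items():
        p = tiny_model.params[name]
        flat_idx = [0, p.size // 2, p.size - 1]
        for fi in flat_idx:
            idx = np.unravel_index(fi, p.shape)
            orig = p[idx]
            p[idx] = orig + h
            lp, _ = tiny_model.loss_and_grads(X, L)
            p[idx] = orig - h
            lm, _ = tiny_model.loss_and_grads(X, L)
            p[idx] = orig
            numeric = (lp - lm) / (2 * h)
            assert g[idx] == pytest.approx(numeric, abs=1e-4), (name, idx)


def test_masked_gradient_identically_zero(tiny_model):
    rng = np.random.default_rng(2)
    X = rng.random((6, 3))
    L = rng.dirichlet(np.ones(2), size=6)
    _, grads = tiny_model.loss_and_grads(X, L)
    off = 1 - tiny_model.mask.matrix[:, :, None]
    np.testing.assert_array_equal(grads["W_embed"] * off, 0.0)


def test_checkpoint_roundtrip(tmp_path, tiny_model):
    path = str(tmp_path / "model.npz")
    tiny_model.save(path)
    loaded = PathwayTransformer.load(path)
    rng = np.random.default_rng(3)
    X = rng.random((3, 3))
    np.testing.assert_array_equal(tiny_model.forward(X)[0],
                                  loaded.forward(X)[0])


def test_linear_model_interface():
    m = LinearSoftmaxModel(["G1", "G2"], 3, seed=0)
    X = np.random.default_rng(0).random((5, 2))
    probs, att = m.forward(X)
    assert att is None and not m.supports_attention
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    L = np.full((5, 3), 1 / 3)
    loss, grads = m.loss_and_grads(X, L)
    assert np.isfinite(loss) and set(grads) == {"W", "b"}
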