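"""Pathway-masked attention classifier.

The classifier embeds each cell's log-normalized expression vector into one
token per pathway through a masked linear map (only a pathway's member genes
may contribute to its token), prepends a trainable CLS token, applies a single
multi-head self-attention layer, and maps the CLS output through a linear
softmax head to cell-type probabilities. The CLS row of the attention matrix
is the interpretable link between a cell and the pathways.

Implemented in NumPy with explicit gradients: the model is a single attention
layer over tens of tokens, so exact hand-derived backpropagation is simple,
fast on one CPU thread, and bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ValidationError


@dataclass
class PathwayMask:
    """k x G binary gene-set membership matrix constraining the embedding."""

    matrix: np.ndarray
    pathway_names: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k, g = self.matrix.shape
        if k != len(self.pathway_names) or g != len(self.gene_ids):
            raise ValidationError("mask shape does not match name lists")
        if not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValidationError("mask entries must be 0 or 1")
        if (self.matrix.sum(axis=1) == 0).any():
            empty = [
                self.pathway_names[i]
                for i in np.flatnonzero(self.matrix.sum(axis=1) == 0)
            ]
            raise ValidationError(f"all-zero pathway rows: {empty}")

    @property
    def n_pathways(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_genes(self) -> int:
        return int(self.matrix.shape[1])


@dataclass
class TransformerConfig:
    """Architecture hyperparameters.

    ``embed_dim`` is the token dimension m (the masked gene->token map is a
    single k x G x m tensor, equivalent to m independent masked linear maps);
    ``n_heads`` splits m into n_heads subspaces of d_k = m / n_heads.

    ``attn_init_gain`` multiplies the scaled-uniform initialization of the
    query/key projections. At unit gain the initial CLS-attention logits have
    spread well below 1, attention starts essentially uniform, and the
    gradient path through the attention weights is tiny, so training pushes
    class information through the values and the learned attention stays
    uninformative; a gain of a few puts the initial logit spread at order 1,
    inside the sensitive regime of the softmax, letting attention itself
    specialize. Very large gains saturate the softmax and stall it.
    """

    n_types: int
    embed_dim: int = 100
    n_heads: int = 4
    attn_init_gain: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim <= 0 or self.n_heads <= 0 or self.n_types <= 0:
            raise ValidationError("all sizes must be positive")
        if self.attn_init_gain <= 0:
            raise ValidationError("attn_init_gain must be positive")
        if self.embed_dim % self.n_heads != 0:
            raise ValidationError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )

    @property
    def d_k(self) -> int:
        return self.embed_dim // self.n_heads


@dataclass
class AttentionRecord:
    """Per-cell attention: one (1+k) x (1+k) row-stochastic matrix per head."""

    heads: np.ndarray  # (n_heads, 1+k, 1+k)
    pathway_names: list[str]

    @property
    def cls_to_pathway(self) -> np.ndarray:
        """Head-averaged CLS row restricted to the pathway columns."""
        return self.heads.mean(axis=0)[0, 1:]


def init_params(
    cfg: TransformerConfig, mask: PathwayMask, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Scaled-uniform initialization; masked embedding positions exactly zero."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k, g, m = mask.n_pathways, mask.n_genes, cfg.embed_dim

    def u(shape, fan_in, fan_out):
        a = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-a, a, size=shape)

    params = {
        "W_embed": u((k, g, m), g, m) * mask.matrix[:, :, None],
        "CLS": u((m,), m, m),
        "Wq": cfg.attn_init_gain * u((m, m), m, m),
        "Wk": cfg.attn_init_gain * u((m, m), m, m),
        "Wv": u((m, m), m, m),
        "Wp": u((cfg.n_types, m), m, cfg.n_types),
        "bp": np.zeros(cfg.n_types),
    }
    return params


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class PathwayTransformer:
    """Masked token embedding + CLS + one multi-head attention + softmax head.

    Queries and keys are projected per head; the value projection is a single
    full-width map, and every head's (1+k) x (1+k) attention matrix weights
    the same value matrix, with head outputs averaged. The CLS output row is
    therefore (head-averaged CLS attention row) @ V — the same head-averaged
    attention profile that the interpretation module reads is the direct
    mixing weight of the classifier input. No residual connections, layer
    normalization, or feed-forward sublayer: the architecture is exactly
    embedding -> attention -> CLS head.
    """

    supports_attention = True

    def __init__(
        self,
        cfg: TransformerConfig,
        mask: PathwayMask,
        params: dict[str, np.ndarray] | None = None,
    ) -> None:
        if cfg.n_types < 2:
            raise ValidationError("need at least 2 cell types")
        self.cfg = cfg
        self.mask = mask
        self.params = params if params is not None else init_params(cfg, mask)

    @property
    def gene_ids(self) -> list[str]:
        return self.mask.gene_ids

    @property
    def n_types(self) -> int:
        return self.cfg.n_types

    # ------------------------------------------------------------------ #
    def masked_embedding(self) -> np.ndarray:
        """Effective embedding tensor W' = W (Hadamard) M, broadcast over m."""
        return self.params["W_embed"] * self.mask.matrix[:, :, None]

    def embed_tokens(self, x: np.ndarray) -> np.ndarray:
        """Token matrix I ((1+k) x m) for a single cell vector x (length G)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.mask.n_genes,):
            raise ValidationError(
                f"expected expression vector of length {self.mask.n_genes}, "
                f"got shape {x.shape}"
            )
        tokens = np.einsum("g,pgm->pm", x, self.masked_embedding())
        return np.vstack([self.params["CLS"][None, :], tokens])

    def _forward_internals(self, X: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        cfg = self.cfg
        B = X.shape[0]
        n, d = cfg.n_heads, cfg.d_k
        tokens = np.einsum("bg,pgm->bpm", X, self.masked_embedding())
        I = np.concatenate(
            [np.broadcast_to(p["CLS"], (B, 1, cfg.embed_dim)), tokens], axis=1
        )
        S = I.shape[1]

        def heads(M: np.ndarray) -> np.ndarray:
            return M.reshape(B, S, n, d).transpose(0, 2, 1, 3)

        Q, K = I @ p["Wq"], I @ p["Wk"]
        V = I @ p["Wv"]  # single value projection, not split across heads
        Qh, Kh = heads(Q), heads(K)
        scores = Qh @ Kh.transpose(0, 1, 3, 2) / np.sqrt(d)
        A = _softmax(scores, axis=-1)
        # each head's full attention matrix weights the same V; heads average
        Abar = A.mean(axis=1)
        O = Abar @ V
        cls_out = O[:, 0, :]
        logits = cls_out @ p["Wp"].T + p["bp"]
        probs = _softmax(logits, axis=-1)
        if not np.all(np.isfinite(probs)):
            bad = int(np.flatnonzero(~np.isfinite(probs).all(axis=1))[0])
            raise FloatingPointError(f"non-finite activations at batch index {bad}")
        return dict(I=I, Qh=Qh, Kh=Kh, V=V, A=A, Abar=Abar, cls_out=cls_out,
                    probs=probs)

    def forward(
        self, X: np.ndarray, return_attention: bool = False
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Type probabilities (B x T) and, optionally, attention (B x n x S x S)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mask.n_genes:
            raise ValidationError("expression width does not match mask gene list")
        out = self._forward_internals(X)
        return out["probs"], (out["A"] if return_attention else None)

    def attention_records(self, X: np.ndarray) -> list[AttentionRecord]:
        _, A = self.forward(X, return_attention=True)
        return [AttentionRecord(heads=a, pathway_names=self.mask.pathway_names)
                for a in A]

    # ------------------------------------------------------------------ #
    def loss_and_grads(
        self, X: np.ndarray, targets: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean-per-cell KL(targets || predictions) and exact gradients.

        Gradients of masked embedding positions are identically zero by
        construction (the mask multiplies the backward pass as it does the
        forward one).
        """
        X = np.asarray(X, dtype=float)
        L = np.asarray(targets, dtype=float)
        if L.shape != (X.shape[0], self.cfg.n_types):
            raise ValidationError("target shape mismatch")
        p = self.params
        cfg = self.cfg
        B = X.shape[0]
        n, d, m = cfg.n_heads, cfg.d_k, cfg.embed_dim

        f = self._forward_internals(X)
        probs = f["probs"]
        eps = 1e-12
        loss = float(
            np.sum(np.where(L > 0, L * np.log((L + eps) / (probs + eps)), 0.0)) / B
        )

        dlogits = (probs - L) / B  # KL + softmax cancels to this
        dWp = dlogits.T @ f["cls_out"]
        dbp = dlogits.sum(axis=0)
        dcls_out = dlogits @ p["Wp"]

        S = f["I"].shape[1]
        dO = np.zeros((B, S, m))
        dO[:, 0, :] = dcls_out

        A, V, Abar, Qh, Kh = f["A"], f["V"], f["Abar"], f["Qh"], f["Kh"]
        dAbar = dO @ V.transpose(0, 2, 1)
        dV = Abar.transpose(0, 2, 1) @ dO
        dA = np.broadcast_to(dAbar[:, None, :, :] / n, A.shape)
        dscores = (dA - (dA * A).sum(axis=-1, keepdims=True)) * A / np.sqrt(d)
        dQh = dscores @ Kh
        dKh = dscores.transpose(0, 1, 3, 2) @ Qh

        def unheads(Mh: np.ndarray) -> np.ndarray:
            return Mh.transpose(0, 2, 1, 3).reshape(B, S, m)

        dQ, dK = unheads(dQh), unheads(dKh)
        I = f["I"]
        dWq = np.einsum("bsm,bsn->mn", I, dQ)
        dWk = np.einsum("bsm,bsn->mn", I, dK)
        dWv = np.einsum("bsm,bsn->mn", I, dV)
        dI = dQ @ p["Wq"].T + dK @ p["Wk"].T + dV @ p["Wv"].T
        dCLS = dI[:, 0, :].sum(axis=0)
        dW_embed = (
            np.einsum("bg,bpm->pgm", X, dI[:, 1:, :]) * self.mask.matrix[:, :, None]
        )
        grads = {
            "W_embed": dW_embed,
            "CLS": dCLS,
            "Wq": dWq,
            "Wk": dWk,
            "Wv": dWv,
            "Wp": dWp,
            "bp": dbp,
        }
        return loss, grads

    # ------------------------------------------------------------------ #
    def save(self, path: str) -> None:
        """Serialize config, gene/pathway order, mask and weights to one file."""
        meta = dict(
            n_types=self.cfg.n_types,
            embed_dim=self.cfg.embed_dim,
            n_heads=self.cfg.n_heads,
            attn_init_gain=self.cfg.attn_init_gain,
            seed=self.cfg.seed,
            pathway_names=self.mask.pathway_names,
            gene_ids=self.mask.gene_ids,
        )
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            mask=self.mask.matrix,
            **{f"param_{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path: str) -> "PathwayTransformer":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            mask = PathwayMask(
                matrix=z["mask"],
                pathway_names=list(meta["pathway_names"]),
                gene_ids=list(meta["gene_ids"]),
            )
            cfg = TransformerConfig(
                n_types=meta["n_types"],
                embed_dim=meta["embed_dim"],
                n_heads=meta["n_heads"],
                attn_init_gain=meta.get("attn_init_gain", 4.0),
                seed=meta["seed"],
            )
            params = {
                k[len("param_"):]: z[k] for k in z.files if k.startswith("param_")
            }
        model = cls(cfg, mask, params=params)
        if not np.allclose(
            model.params["W_embed"] * (1 - mask.matrix[:, :, None]), 0.0
        ):
            raise ValidationError("checkpoint weights violate the pathway mask")
        return model


class LinearSoftmaxModel:
    """Multinomial logistic model on the gene vector (classifier ablation).

    Shares the trainer interface of :class:`PathwayTransformer` so the same
    pretraining and self-training loops apply; carries no attention.
    """

    supports_attention = False

    def __init__(self, gene_ids: list[str], n_types: int, seed: int = 0) -> None:
        if n_types < 2:
            raise ValidationError("need at least 2 cell types")
        self._gene_ids = gene_ids
        self._n_types = n_types
        rng = np.random.default_rng(seed)
        a = np.sqrt(6.0 / (len(gene_ids) + n_types))
        self.params = {
            "W": rng.uniform(-a, a, size=(n_types, len(gene_ids))),
            "b": np.zeros(n_types),
        }

    @property
    def gene_ids(self) -> list[str]:
        return self._gene_ids

    @property
    def n_types(self) -> int:
        return self._n_types

    def forward(
        self, X: np.ndarray, return_attention: bool = False
    ) -> tuple[np.ndarray, None]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        probs = _softmax(X @ self.params["W"].T + self.params["b"], axis=-1)
        return probs, None

    def loss_and_grads(
        self, X: np.ndarray, targets: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        X = np.asarray(X, dtype=float)
        L = np.asarray(targets, dtype=float)
        B = X.shape[0]
        probs, _ = self.forward(X)
        eps = 1e-12
        loss = float(
            np.sum(np.where(L > 0, L * np.log((L + eps) / (probs + eps)), 0.0)) / B
        )
        dlogits = (probs - L) / B
        return loss, {"W": dlogits.T @ X, "b": dlogits.sum(axis=0)}
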