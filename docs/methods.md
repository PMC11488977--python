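# Methods

## Problem

Given a cells × genes scRNA-seq count matrix, a catalog of marker genes per
candidate cell type, and a collection of pathway gene sets, `scanno` assigns
each cell a probability distribution over the candidate types and an
interpretable attention profile over pathways. No labeled reference data are
used: supervision comes entirely from the marker catalog, converted into
per-cell soft pseudo-labels, and from the model's own predictions during
self-training.

## Pipeline

1. **Relevance scoring.** A raw N × T relevance matrix R is computed from the
   expression matrix and the marker catalog by one of six strategies
   (`count`, `cos`, `lr-label`, `lr-marker`, `pseudo-cell`,
   `cell-type-specific`; see below). The default is `cell-type-specific`.
2. **Pseudo-labels.** Each row of R is mapped onto the probability simplex,
   by a row-wise softmax by default (temperature 1). A linear
   sum-normalization is available for strategies with nonnegative scores.
   Soft labels are kept soft: collapsing to one-hot argmax labels is exposed
   only as an ablation, since hard labels make the classifier overfit
   pseudo-label noise.
3. **Pretraining.** A pathway-masked attention classifier is trained to
   minimize the KL divergence KL(L ‖ Y) between pseudo-labels L and
   predictions Y, by seeded mini-batch Adam.
4. **Self-training.** The model's full-data predictions at round t are
   frozen and used as the targets of round t+1 (same KL objective, warm
   start). Rounds stop when the fraction of cells whose argmax label changes
   falls below δ (default 0.001) or after `max_rounds` (default 20).
5. **Interpretation.** The CLS row of the attention matrix, averaged over
   heads and restricted to pathway columns, is each cell's attention
   profile. Profiles are scaled to a fixed total (1e4), log1p-transformed,
   reduced by PCA, connected by a kNN graph, and partitioned by Louvain at
   resolution 0.3. Signature pathways per cluster are ranked by one-vs-rest
   Wilcoxon rank-sum with Benjamini–Hochberg correction.

## Relevance strategies

- **count**: R_ij = number of type-j markers with expression > 0 in cell i.
  Depends only on the zero pattern, hence invariant to library size.
- **cos**: with a pretrained gene-embedding table E, the cell embedding is
  the expression-weighted mean c_i = (x_i·E)/Σx_i and the type embedding the
  mean of its marker embeddings; R_ij = cosine(c_i, T_j). Zero vectors score
  0 by convention.
- **lr-label / lr-marker**: a multinomial logistic classifier (L2 penalty
  C = 1, ≤1000 iterations) trained on type embeddings (one sample per class)
  or on individual marker embeddings (one per marker); R is the predicted
  probability matrix.
- **pseudo-cell**: each type is modeled as a von Mises–Fisher distribution
  on the embedding unit sphere centered at its normalized type embedding
  (concentration κ = 50). Sampled directions are converted to gene profiles
  by a softmax over gene–direction alignments (sharpness λ = 10), scaled to
  a nominal library size, and embedded with the same expression-weighted
  mean used for real cells; a logistic classifier trained on these
  pseudo-cells scores the real cells. Fully seeded.
- **cell-type-specific** (default): markers are pooled and each receives a
  specificity score S = 1 − (n_types(m) − min)/(max − min), so a marker
  unique to one type scores 1 and the most promiscuous marker scores 0
  (all-equal counts degenerate to S = 1 uniformly). Expression is z-scored
  per gene across cells on the log-normalized matrix (population standard
  deviation, ddof = 0; zero-variance genes contribute 0), each marker column
  is weighted by its S, and R_ij is the mean over type-j markers.

## Normalization

All model inputs and the z-scores of the `cell-type-specific` strategy use
log-normalized expression: each cell is scaled to the **median library
size** of the dataset and log1p-transformed. Scaling to the median (rather
than a fixed constant such as 1e4) keeps the transform in the informative
range of the logarithm regardless of sequencing depth; with a fixed large
target, shallow libraries are multiplied far into the flat region of log1p,
which measurably collapses both class separability and cluster structure on
shallow data. Attention profiles, by contrast, are scaled to a fixed 1e4
before log1p when clustered, since their rows are probabilities with
near-identical totals and the constant only sets the log offset.

## Classifier

The classifier is a single-attention-layer network over pathway tokens:

- **Masked embedding.** A k × G × m weight tensor W, multiplied elementwise
  by the k × G binary pathway-membership mask broadcast over m, maps the
  cell's log-normalized expression to one m-dimensional token per pathway
  (t_p = Σ_g W′[p,g,:] x_g). Only member genes can ever contribute to a
  pathway's token: masked weights are zero at initialization and their
  gradients are identically zero, so the constraint holds exactly at every
  step. This single tensor is mathematically identical to m independent
  masked linear maps.
- **CLS token.** A trainable m-vector prepended to the k pathway tokens.
- **Multi-head self-attention.** Q and K are linear projections of the
  (1+k) × m token matrix split into n heads of dimension d_k = m/n, giving
  per-head attention A_h = row-softmax(Q_h K_hᵀ/√d_k). The value projection
  V is a single full-width map (not split per head); each head's full
  attention matrix weights the same V and head outputs are averaged:
  O = (mean_h A_h)·V. The CLS output row is therefore exactly the
  head-averaged CLS attention row times V, so the attention profile used
  for interpretation is the direct mixing weight of the classifier input.
  There is no residual connection, layer normalization, or feed-forward
  sublayer — the architecture is exactly embedding → attention → head.
- **Prediction head.** The CLS row of O through a single linear map to T
  logits, then softmax.

Defaults: m = 100, n = 4 heads. Initialization is scaled-uniform
(Glorot-style ranges) with one deliberate exception: the query and key
projections are initialized with a gain of 4. With unit-gain initialization
at these widths the CLS-attention logits have spread ≈ 0.1, i.e. attention
starts out essentially uniform and the gradient path through the attention
weights is vanishingly small, so training drives class information through
the value vectors and the learned attention stays uninformative. A gain of
~4 puts the initial CLS-attention logit spread at order 1 — inside the
sensitive regime of the softmax — which lets the attention weights
themselves specialize to pathways during training; much larger gains
saturate the softmax at initialization and stall it. The gain is a config
field (`attn_init_gain`).

The model and its training loop are implemented directly in NumPy with
exact hand-derived gradients (verified against central finite differences
in the test suite). With one attention layer over tens of tokens this is
fast on a single CPU thread and bit-reproducible under a fixed seed.

The logistic-regression ablation replaces the network with a linear softmax
model on the full gene vector, trained by the same KL objective and loops,
so the self-training comparison isolates the classifier architecture.

## Training

Adam (lr 1e-3, batch 256) by default; plain SGD is available and is what
the monotone-descent property test uses (full batch, lr 1e-4). The reported
loss is the total KL over all cells; the optimizer minimizes the per-cell
mean of the same quantity. Pretraining runs 50 epochs. Self-training reuses
the same optimizer state and parameters (warm start), freezes targets once
per round, and records per-round loss and argmax-label change fraction. A
round whose loss exceeds 10× its starting loss aborts with a warning.
Target sharpening (raising targets to a power before renormalization) is an
experimental flag, default off — targets are the raw predictions.

## Synthetic data

The generator plants T cell types in an N × G negative-binomial count
matrix (gamma–Poisson with Var = μ + αμ², baseline μ = 2, α = 0.5) with
element-wise dropout (p = 0.3). Each type owns a block of marker genes whose
mean is multiplied by the fold-change (default 4) in cells of that type.
Each type gets one enriched pathway containing 80% of its markers plus a
few background genes; remaining pathways are random background sets, and
leftover markers scatter among them. The gene embedding places marker
vectors near a per-type centroid on the unit sphere. An optional
contamination fraction lists (and overexpresses) part of each type's
markers in the next type as well, which is what makes the specificity score
S informative. Generation validates post hoc that every planted marker is
overexpressed in the types that list it.

The generator reproduces the first-order structure that marker-based
annotation relies on — type-specific overexpression, shared markers,
pathway grouping, embedding geometry — but not batch effects, doublets,
realistic mean–variance trends across genes, or unequal library depth
between types. Passing results on it demonstrate correctness of the
machinery and the qualitative behaviour of the method, not performance on
real tissue.

## Numerical choices and edge cases

- Softmax computations subtract the row maximum; KL floors predictions at
  1e-8 (configurable) inside the logarithm; 0·log 0 terms are 0.
- Argmax ties resolve to the lowest type index and are logged.
- Cosine of a zero vector is 0; a cell with zero expression over the genes
  shared with the embedding gets a zero embedding and a warning.
- Genes absent from every pathway are dropped from the model's gene list by
  default (or pooled into an `UNASSIGNED` pathway row on request); pathways
  with no overlap with the data are dropped with a warning.
- The rank-sum test uses the tie-corrected normal approximation, switching
  to the exact distribution when both groups have ≤ 10 observations and no
  ties; ranking ties break by pathway name so tables are deterministic.
- NMI uses arithmetic-mean normalization and is defined as 0 when exactly
  one partition is a single cluster; per-class precision/recall fall back to
  0 when a class is never predicted (or never occurs), keeping macro
  averages computable on unbalanced data.
- Louvain runs on the symmetrized unweighted kNN graph of the PCA
  coordinates via igraph's multilevel algorithm, seeded through Python's
  `random` module, with cluster labels relabeled by decreasing size.

## Problem sizes

The standard synthetic instance used throughout the documentation and the
acceptance script is 1000 cells × 300 genes, 5 types × 10 markers, 20
pathways, fold-change 4, with the classifier at m = 32 — small enough that
the full pipeline (relevance → pretraining → self-training →
interpretation) completes in about a minute on one CPU core while leaving
every stage's behaviour measurable. Robustness comparisons (self-training
benefit under 30% pseudo-label noise; classifier ablation) run at 500 cells
over 5 seeds.

## Known limitations

- The attention interpretation is correlational: a pathway ranked as a
  cluster signature is one the trained model attends to, not a validated
  biological association.
- Self-training amplifies the model's systematic component; if pseudo-labels
  are systematically wrong for a type (not merely noisy), self-training can
  entrench the error rather than fix it.
- The pseudo-cell strategy depends strongly on the quality of the supplied
  gene embedding; with an uninformative embedding its scores are close to
  uniform.
- h5ad input is supported read-only and only for matrices that fit in
  memory once densified.
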