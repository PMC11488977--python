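# scanno

Marker-based cell type annotation for scRNA-seq with pseudo-label
self-training and an interpretable pathway-masked attention classifier.

## Who this is for

Single-cell analysts who have a cells × genes count matrix and a catalog of
marker genes per candidate cell type — but no labeled reference dataset —
and who want per-cell type probabilities plus an interpretable account of
*which pathways* the classifier attends to for each cell.

## Method

Annotation proceeds in two stages:

**1. Pseudo-labels from markers.** A relevance matrix R ∈ ℝ^{N×T} scores
every cell against every candidate type. The default *cell-type-specific*
strategy pools all markers, gives each marker m a specificity score

    S(m) = 1 − (n_types(m) − min) / (max − min),

z-scores expression per gene across cells on the log-normalized matrix,
weights each marker column by S, and averages over each type's markers:
R_ij = (1/n_j) Σ_k S(m_jk)·z_i(m_jk). Five alternative strategies (marker
count, cosine / logistic-regression / pseudo-cell scoring on a pretrained
gene embedding) are available. Each row of R is softmax-normalized into a
soft pseudo-label l_i on the probability simplex.

**2. A self-trained attention classifier.** Each cell is embedded into one
token per pathway through a mask-constrained linear map (only a pathway's
member genes can contribute to its token, enforced exactly), a trainable
CLS token is prepended, and a single multi-head self-attention layer
produces per-head attention A_h = softmax(Q_h K_hᵀ/√d_k); the head-averaged
attention applied to the value matrix yields the CLS output, which a linear
softmax head maps to type probabilities y_i. The model is pretrained by
minimizing KL(L‖Y) = Σ_i Σ_j l_ij log(l_ij/y_ij) against the pseudo-labels,
then refined by self-training: the round-t predictions Y^(t) become the
round-(t+1) targets, KL(Y^(t)‖Y^(t+1)), until the fraction of cells whose
argmax label changes drops below δ. The CLS row of the attention matrix is
each cell's pathway-attention profile, which can be clustered (PCA + kNN +
Louvain) and tested per cluster for signature pathways (one-vs-rest
Wilcoxon rank-sum, BH-corrected).

See `docs/methods.md` for assumptions, parameter defaults, and numerical
details.

## Worked example

Everything runs end to end on simulated data — no downloads:

```bash
scanno simulate --out sim/ --seed 0                  # 1000 cells, 300 genes, 5 types
scanno annotate --expr sim/ --markers sim/markers.csv \
    --pathways sim/pathways.gmt --out-dir run/ --embed-dim 32 --seed 0
scanno evaluate --predictions run/predictions.csv \
    --truth sim/truth.csv --out run/metrics.json
```

The `evaluate` step prints:

```json
{
  "precision_macro": 0.909231816053186,
  "recall_macro": 0.9094889711413172,
  "f1_macro": 0.9090563844275744,
  "f1_micro": 0.909,
  "nmi": 0.7378953412182186,
  "ari": 0.7845353981728799
}
```

Reading: against the planted ground truth, about 91% of the 1000 cells are
assigned their true type (micro-F1 = accuracy in single-label multiclass),
and the per-type macro averages are balanced around the same level — the
soft pseudo-labels alone label only ~91% of cells correctly at argmax, and
pretraining + self-training preserves and slightly sharpens that signal
under this fixture's noise (NB dispersion 0.5, 30% dropout). `run/` also
contains per-cell type probabilities, the cells × pathways CLS-attention
matrix, Louvain clusters of those attention profiles, and the per-cluster
signature-pathway table.

The same pipeline is available as a library:

```python
from scanno import SimConfig, TrainConfig, annotate, classification_report, generate

ds = generate(SimConfig(seed=0))
res = annotate(ds.expression, ds.markers, ds.pathways,
               train_cfg=TrainConfig(seed=0), embed_dim=32)
print(classification_report(ds.true_labels, res.predicted_type,
                            ds.markers.type_names).to_dict())
```

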