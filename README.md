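# drivergraph

Predicting the **driver gene** behind a cell-state transition from paired
single-cell expression profiles, using a gene-graph-aware transformer.

## The problem

Pooled CRISPR screens with single-cell readout (perturb-seq) produce pairs
of cell states: an unperturbed **source** cell and a perturbed **target**
cell, with the perturbed gene known. The inverse problem — *given* a
source/target pair, infer which gene drove the transition — is central to
understanding differentiation, disease progression and drug mechanisms.
Differential expression alone answers it poorly: the strongest expression
shifts are often downstream consequences, not causes.

`drivergraph` addresses this with two components:

* a **cell manifold model (CMM)** — a transformer encoder over the tokens
  `[CLS] + expressed genes` whose attention is structured by a directed
  gene–gene prior graph 𝒢: learnable in-/out-degree (centrality)
  embeddings are added to token states, and a learnable scalar bias
  b(S_{g₁g₂}), indexed by bucketed shortest-path distance on the
  cell-specific graph, is added to attention logits. The CLS state is
  projected to a low-dimensional **cell coordinate** CRD(x). The encoder
  is pretrained self-supervised: counts are thinned with
  Binomial(x, 1/r), r ~ U[1, 20), and a decoder must reconstruct the
  original profile from the coordinate — forcing the coordinate to capture
  the cell's underlying state rather than sequencing depth;
* a **driver-gene predictor (DGP)** — an MLP on
  CONCAT(CRD(x_src), CRD(x_tgt)) emitting softmax probabilities
  ("likelihood scores") over K candidate drivers, trained by
  cross-entropy with the encoder fine-tuned jointly.

Everything is implemented in numpy (forward and backward passes are
hand-written), so the full pipeline trains on one CPU at desk scale. A
negative-binomial synthetic perturb-seq generator with a known ground-truth
graph makes every stage trainable and testable without external data; see
`docs/methods.md` for the model, the generator and their assumptions.

## Worked example

```python
import numpy as np
import drivergraph as dg
from drivergraph.synthetic_data import SimConfig, build_pair_dataset
from drivergraph.pretraining import TrainOptions, pretrain
from drivergraph.dgp import FinetuneOptions, finetune, predict_pairs
from drivergraph.evaluation import ranks_of_labels

# synthetic perturb-seq: 200 genes, 4 cell states, 20 drivers
data = build_pair_dataset(SimConfig(seed=1), split="in_domain")
cfg = dg.ModelConfig(H=64, n_layers=2, n_heads=8, coordinate_dim=128,
                     max_degree_bucket=32, dgp_hidden=128, dtype="float32")

cmm0, _, rep = pretrain(data.counts, data.graph, cfg,
                        TrainOptions(epochs=12, batch_size=16, lr=2e-3, seed=2,
                                     holdout_frac=0.1, max_cells=2000))
print(f"reconstruction loss ratio {rep.train_loss[-1] / rep.initial_train_loss:.2f}")

cmm, dgp, _ = finetune(data.dataset, data.counts, data.graph, cmm0, cfg,
                       FinetuneOptions(epochs=7, batch_size=16, seed=3,
                                       pairs_per_epoch=1400, weight_decay=1e-4,
                                       eval_every=100),
                       source_pool=data.source_pools())

pairs = data.dataset.split_pairs("test")
pick = np.random.default_rng(4).choice(len(pairs), size=320, replace=False)
pairs = [pairs[i] for i in pick]
probs = predict_pairs(data.counts, pairs, data.graph, cmm, dgp, cfg)
labels = np.array([dgp.candidate_genes.index(p.driver) for p in pairs])
ranks = ranks_of_labels(probs, labels)
print(f"held-out top-1 {(ranks <= 1).mean():.2f}, top-5 {(ranks <= 5).mean():.2f}, "
      f"mean rank {ranks.mean():.1f} of K=20")
```

Output observed for these settings (exact numbers vary with the seed):

```
reconstruction loss ratio 0.21
held-out top-1 0.53, top-5 0.84, mean rank 3.0 of K=20
```

Meaning: pretraining reduces the reconstruction error to about a fifth of
its starting value, and the fine-tuned model places the true driver first
for roughly half the held-out pairs (chance 5%) and within its top five
candidates for ~85%, with the true driver ranked ~3 of 20 on average. The
median rank is 1; masking the driver's own expression drops top-1 to ~0.22
(still >4x chance), and the cluster-based differential-expression baseline
ranks the true driver ~10.7 of 20 on the same pairs.

A `drivergraph` command-line interface wraps the same functions
(`simulate`, `normalize`, `graph`, `pretrain`, `finetune`, `encode`,
`predict`, `evaluate`); run `drivergraph --help`.

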