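# Methods

## The model

`drivergraph` predicts the **driver gene** behind an observed cell-state
transition: given a source cell (unperturbed control) and a target cell
(after a genetic perturbation), it ranks a pool of K candidate genes by the
probability that perturbing them produced the transition.

The core is a **cell manifold model (CMM)** — a graph-aware transformer
encoder. A cell enters as a token sequence `[CLS] + non-zero genes`; each
gene token is the concatenation of a learnable gene-identity embedding
(width H) and a linear embedding of its shifted-log expression
x̃ = ln(L·x/Σx + 1), L = 10⁴ (width H), giving a working width E = 2H. A
directed gene–gene prior graph enters through two channels, both computed
on the *cell-specific* graph (the induced subgraph on the cell's expressed
genes):

* **centrality encoding** — learnable embeddings of each gene's in- and
  out-degree (clipped at 64) added to token states in every layer;
* **spatial encoding** — a learnable per-head scalar bias b(S) added to the
  attention logits, indexed by the bucketed shortest directed path length
  between the two genes (0…d_max, d_max = 8, one extra UNREACHABLE bucket,
  plus a reserved CLS bucket).

Each GeneGraph attention layer applies (pre-norm order) layer-norm + MLP
with a residual, then centrality, then biased multi-head attention with a
residual; `pre_norm_mlp=False` moves the MLP branch after attention. The
CLS token's final state, linearly projected to `coordinate_dim`
(2048 by default), is the **cell coordinate**.

**Pretraining** is downsampling reconstruction: counts are thinned with
Binomial(x, 1/r), r ~ U[1, 20) per cell, the thinned cell is encoded, and a
two-layer MLP decoder must reconstruct the *original* profile, one scalar
per queried gene, from (coordinate ⊕ that gene's embedding). The loss is
the mean squared 2-norm of the residual over queried genes; encoder and
decoder train jointly. The reconstruction target is the shifted-log
profile by default (`raw_target` restores raw counts): squared error on raw
counts is dominated by a handful of high-count genes. The decoder keeps its
*own* gene-embedding table (initialized from the encoder's): sharing the
table lets decoder gradients continually reshape the encoder's input space
and, empirically, stalls joint optimization.

**Driver prediction (DGP)** concatenates the source and target coordinates
and applies a two-layer GELU MLP (hidden width = `coordinate_dim` by
default) with a softmax over the K candidates, trained by cross-entropy
with the encoder fine-tuned jointly.

## Numerical choices that mattered

Two properties of this architecture required explicit handling; both are
invisible in the equations and decisive in practice.

1. **Input-dominant initialization.** With conventional 0.02-scale
   embedding initialization the residual stream is dominated by
   input-independent branch outputs and the CLS coordinate varies only ~1%
   between cells; joint training then parks at uniform predictions.
   Embeddings are therefore initialized at std 0.3 (identity) / 0.5
   (expression) and every residual output projection is scaled by
   1/√(2·n_layers).

2. **Head-input standardization.** Even so, the coordinate vector is a
   large shared offset plus a small cell-specific deviation, and the
   offset *drifts* during joint training faster than the deviation scale.
   Both heads therefore standardize their input coordinates,
   (x − μ)/σ, using current-batch statistics during training and buffers
   (μ, σ) recalibrated from a full inference pass after optimization; the
   statistics are stop-gradient. Training uses batches ≥ 4 so batch
   statistics are defined.

Other choices: Adam (lr 10⁻³ default, 5% linear warmup in pretraining,
linear decay to 10% of the base rate over each run); natural log in the
shifted logarithm; ties in candidate ranking broken by ascending gene
index; degree and distance lookups clipped as above; cells whose thinned
profile would be all-zero keep one count of their most expressed gene (the
encoder requires ≥ 1 token); training-time gene sampling (uniform, without
replacement, at most `max_train_genes`) is available but desk-scale runs
use all non-zero genes — capping below the typical non-zero count slows
convergence because the driver gene is hidden from a fraction of steps.

## Synthetic perturb-seq generator

No public perturb-seq data ships with the package; the generator supplies
data with known ground truth. Counts are Gamma–Poisson (negative binomial,
dispersion θ = 10): gene g in state c has mean s·μ_{c,g} with library size
s ~ LogNormal(0, 0.3), baseline means LogNormal(−0.7, 1.2) shared across
states, and a per-state program (15% of genes, LogNormal(0, 0.8) factors).
Perturbing driver gene d multiplies means by α^(β^depth) for every gene
within directed-graph distance `depth ≤ P` of d (α = 3, β = 0.6, P = 2);
the driver itself gets α. The prior graph is preferential-attachment
directed (heavy-tailed out-degree) with density 0.03 (~1,200 edges at
G = 200).

Drivers are drawn among genes with out-degree ≥ 6 and baseline mean at or
above the median — expressed regulatory hubs, as in real CRISPR screens.
This choice is load-bearing: a negative-binomial likelihood-ratio oracle
that knows the true states, means and effect vectors — an upper bound for
*any* classifier — reaches only ~0.70 top-1 (K = 20) when drivers are
arbitrary low-degree genes, versus ~0.89 for expressed hubs. Single-cell
counting noise, not the model, sets this ceiling.

What the generator does *not* emulate: ambient RNA, doublets, batch
effects, guide inefficiency (every "perturbed" cell is truly perturbed),
multiplicative interactions between perturbation and state programs, and
real regulatory topology. Passing tests therefore demonstrate that the
pipeline recovers graph-propagated perturbations under NB noise — not
performance on real screens.

## Desk-scale study sizes

All training-dependent tests and `scripts/acceptance.py` use one CPU and
these sizes, chosen once:

* dataset A (recovery, masking, DGE comparison): G = 200 genes, 4 states,
  K = 20 drivers, 50 perturbed cells per (state, driver), 500 controls per
  state; encoder with 2 layers, H = 64, 128-d coordinates; pretraining on a
  2,000-cell subset (12 epochs); fine-tuning 8 epochs over 1,400 pairs per
  epoch with control-resampling augmentation (each epoch re-pairs every
  perturbed cell with a fresh same-state control) and weight decay 10⁻⁴;
  evaluation on 320 fixed held-out pairs.
* dataset B (component and graph ablations): G = 80, 3 states, K = 6,
  18 cells per (state, driver); 3 seeds per comparison, medians reported.
  Both ablations use the out-of-domain split: at this scale the in-domain
  task saturates from expression tokens alone, so pretraining and the
  graph prior show their value in generalization to the held-out state.
  The graph ablation trains both arms from random initialization so the
  two runs differ *only* in the graph.

## Known limitations

* The numpy implementation is single-threaded BLAS; wall-clock, not
  methodology, caps the model and dataset sizes above.
* Held-out top-1 at dataset-A scale sits well below the ~0.89 oracle
  ceiling; closing that gap needs more pairs and training steps than a
  desk-scale run affords.
* The `no_dgp` ablation fits scikit-learn logistic regression on frozen
  coordinates; it cannot back-propagate into the encoder.
* LISI is normalized to [0, 1] as (λ − 1)/(n_labels − 1); the rank-sum
  test in the DGE baseline uses the asymptotic normal approximation with
  tie correction, BH-adjusted, and fold changes use a +1 pseudocount on
  the 10⁴-scaled means.
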