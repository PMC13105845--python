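# Methods

## The model

A glycan is a rooted labeled tree: monosaccharide residues are nodes,
glycosidic bonds are edges, and the reducing-end residue (rightmost in
IUPAC-condensed notation) is the root. The encoder is a *tokenized* graph
transformer: rather than message passing, every node and every edge is an
independent token and the model sees the flat sequence

```
[Graph], node_0 … node_{n-1}, edge_0 … edge_{m-1}
```

Each token's input embedding sums three parts:

1. **Content** — an embedding looked up by token id. Residue and linkage
   tokens live in disjoint dictionaries (ids 0–3 reserved for
   `<mask>/<pad>/<unk>/<graph>` in both spaces); stereochemistry and
   chemical modifications (`GalNAc3,4,6Ac3`) are kept verbatim as distinct
   tokens, with no chemical normalization.
2. **Identifier** — a linear projection of `[P_u, P_v]`, where `P` is a
   fixed orthonormal matrix generated by QR-decomposing a seeded Gaussian
   matrix (signs fixed, so regeneration is bit-identical). A node token
   carries `[P_v, P_v]`; an edge token carries `[P_child, P_parent]`.
   Orthonormality gives `⟨[P_u,P_v],[P_u,P_w]⟩ = 1 + δ(v,w)`, so attention
   can detect incidence from inner products alone. The bank is one matrix
   shared across all graphs, with rows assigned by canonical (textual)
   node order; consequently the encoder is invariant to token *order* but
   not to node *relabeling*.
3. **Type** — a trainable embedding distinguishing node, edge and the
   `[Graph]` summary token (three types; the summary token also has its own
   content vector and a zero identifier).

Blocks are post-norm (sub-layer → residual add → LayerNorm) with full
softmax attention over all real tokens (`O((n+m+1)² d)` per glycan), GELU
MLPs of hidden width `4d`, and optional dropout after the attention
projection and the MLP output. The `[Graph]` token's final state is the
whole-glycan embedding. Two linear heads map token states to residue- and
linkage-vocabulary logits; softmax is always taken over *content* classes
(special ids excluded). Scale presets (depth×width×heads): ss 2×64×4,
small 4×128×4, medium 8×256×8, large 12×512×16.

Everything — forward pass, exact backpropagation, AdamW — is implemented
on NumPy in float64. Same config + seed ⇒ bit-identical parameters,
identifier bank and training trajectory.

## Pretraining objective

Masked language modeling over both token types. A masking plan replaces the
content id of selected tokens by `<mask>` while leaving identifiers and
types visible: the model always knows *where* a hidden residue or bond
sits, only *what* it is must be inferred. Counts are fixed per glycan
(`round(ratio · n_eligible)`) rather than Bernoulli, so plans are exactly
reproducible; plans are resampled every epoch. *Terminal* bonds — bonds
incident to a leaf (degree-1, non-root) residue — are excluded from
prediction targets because they lack two-sided context; they remain visible
inputs during pretraining. There is no BERT-style 80/10/10 replacement
noise: masked inputs always become `<mask>`, matching the completion
use-case where hidden tokens really are unknown.

Loss = mean cross-entropy over masked residue positions + **0.5** × mean
cross-entropy over masked bond positions. Optimization: AdamW
(β = (0.9, 0.98), weight decay 0.01, decoupled; biases and LayerNorm
parameters exempt), global-norm gradient clipping at 1.0, an exponential
moving average of the weights (decay 0.999 per step; the EMA weights are
what validation sees and what the returned model carries — disable with
`ema_decay=None`), 90/10 train/validation split, early stopping on mean
validation loss (patience 15 for ss/small, 30 for medium/large), then an
optional refit on the full corpus for the selected epoch count. Masking
modes: `balanced` (default 35%/35%), `node_only` (70%/0%) and `edge_only`
(0%/70%) for ablation.

### Desk-scale training recipe

The reference learning rate for large-corpus pretraining (1e-6, weight
decay 0.01) is kept as the `TrainConfig` default, but it is calibrated for
~84k glycans and long schedules; at desk scale (2,000 toy glycans,
≤50 epochs) it moves the loss by under a percent. The tests and the
acceptance script therefore pass an explicit small-model recipe: lr 2e-3
with 3-epoch linear warmup and cosine decay to lr/10, batch size 16, Adam
β₂ = 0.98, no dropout, and two independent masking draws per glycan per
epoch (the standard duplication trick of masked-language pretraining —
more gradient-signal diversity without changing the masking ratio, corpus
or epoch count). Length-bucketed batching keeps padding waste low. These
choices were fixed by optimizing convergence speed on training diagnostics,
not by adjusting any evaluated quantity.

## The synthetic world

Real repositories cannot ship with the package, so all pipeline stages are
exercised on glycans sampled from a toy grammar designed to make masked
tokens *context-determined*:

* 10 monosaccharides, 8 linkage labels; trees sampled from the reducing end
  outward with branch probability 0.3, stop probability 0.3, depth cap 6 —
  sizes land in the 2–30-residue range typical of repository entries.
* Each parent allows **two** child residues (offsets +1 and +3 in the
  residue list) drawn with probabilities 0.85/0.15 — stochastic, so residue
  completion is not trivial, but skewed, so positions with no deciding
  context are still guessable.
* The bond label between parent `i` and its slot-`j` child is
  `linkages[(2 i + j) mod 8]` — deterministic given the endpoints. With two
  children per parent this map is bijective in every direction that
  matters: parent + label → child, child + label → parent, and even
  grandparent + label → (parent, child) are all unique, and any visible
  bond pins both its endpoints modulo 4.

An exact sum-product (belief-propagation) oracle on the tree — deterministic
label factors, 0.85/0.15 child priors, uniform root prior — puts the
Bayes-optimal masked-bond top-1 accuracy under balanced 35%/35% masking at
≈0.97–0.99 and masked-residue accuracy at ≈0.99. This is the ceiling a
perfect learner could reach; the ss-scale transformer reaches ≈0.95–0.97
within 50 epochs. The family label (root residue) gives downstream
classification tests a decodable target.

What the generator does *not* emulate: real monosaccharide/linkage
frequency distributions, chemical constraints on branching, modification
chemistry, or repository noise. A green test on this world establishes that
the architecture and training loop can extract the structural signal the
world contains — not that any particular biological benchmark number would
be reproduced.

## Completion evaluation

Two ambiguity scenarios mirror the empirically common annotation patterns:
(i) bonds intact, 10–90% of residues hidden; (ii) all bonds hidden, 0–90%
of residues hidden. In scenario (ii) terminal bonds are masked *as inputs*
(a real ambiguous entry hides them too) but stay excluded from scoring,
keeping the terminal-bond convention consistent between pretraining and
evaluation. Predictions are ranked by softmax probability over the content
vocabulary; hit@K is micro-averaged over masked positions (macro per-glycan
averaging available) and reported separately for residues and bonds.

## Analysis

* **WL subtree kernel** — nodes labeled by residue identity, bonds used as
  adjacency only; `h = 3` relabeling rounds by default (label compression
  is order-independent, so the kernel does not depend on input order);
  unnormalized kernel = sum over rounds of histogram dot products; cosine
  normalization yields unit diagonal. Average-linkage clustering on `1 − K`
  is provided as a reporting aid.
* **Classification harness** — fixed train/val/test splits;
  randomized hyperparameter search (SVM: 10 draws over RBF/linear kernels,
  `C ~ logU(1e-3, 1e2)`, `γ ~ logU(1e-4, 1e-1)`; gradient boosting:
  15 draws) with 3-fold CV on train∪val, one final evaluation on test,
  class-balanced weighting, and mean ± s.d. over three seeds. The
  gradient-boosting path is scikit-learn's `HistGradientBoostingClassifier`
  with the boosted-tree ranges mapped onto its parameters
  (`max_iter ∈ [100, 1000]`, `learning_rate ~ logU(0.01, 0.3)`,
  `max_leaf_nodes ∈ [20, 150]`, `max_depth ∈ [5, 20]`,
  `l2_regularization ~ logU(1e-2, 1e1)`); feature-subsampling parameters
  with no HGB equivalent are omitted.
* **AUPRC** — computed from scratch by threshold enumeration with the
  interpolated-precision envelope integrated stepwise over recall (ties in
  scores collapse to one PR point). Macro-F1 and accuracy via
  scikit-learn.
* **PCA + k-means** (50 components, k = 6, fixed seeds) is included as the
  standard preprocessing for embedding-cluster inspection.

## Numerical choices and degenerate inputs

* float64 throughout; LayerNorm ε = 1e-5; attention padding mask and
  excluded softmax classes use an additive −1e30 (exact zeros after
  softmax underflow, which is why padding isolation holds to 1e-5).
* Masked-loss terms with no masked positions contribute 0 (a warning-free
  no-op; an entirely empty plan yields loss 0).
* `round(ratio · n)` uses round-half-up so a 0.5 ratio over 2 eligible
  positions masks exactly 1.
* Serialization normalizes branch order (main chain = lexicographically
  greatest linkage; remaining branches bracketed in sorted order), so
  `parse ∘ serialize` is identity up to labeled-tree isomorphism, which is
  the contract tests assert.
* Curation rejects `?` before attempting `/` expansion; expansion is capped
  at 16 variants per entry (capped entries are rejected with a logged
  warning, not truncated).
* Glycans whose residue count exceeds the identifier bank (default 64) are
  a hard error in training and a recorded skip in corpus embedding.

## Known limitations

* No WURCS/GlycoCT parsing, no atom-level chemistry, no repository API
  access; the IUPAC-condensed grammar covers the common core notation plus
  verbatim modification suffixes, not every repository idiosyncrasy.
* The NumPy encoder is single-threaded CPU code: ss/small scales train in
  minutes on toy corpora, but the medium/large presets are only practical
  for inference or very small corpora.
* The completion experiment mirrors the pretraining objective; high hit@K
  on the toy world demonstrates contextual recovery, not resolution of
  real-world structural ambiguity.
* Scale presets for ss/small/medium/large are package defaults, not tuned
  reproductions of any published configuration.
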