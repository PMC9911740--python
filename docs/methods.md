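# Methods

## Model

`biotext` treats class descriptions and biological measurements as two
views of the same underlying entity and embeds both into one vector space.

**Text side.** A class is its ontology term's `name` plus `definition`,
joined by `". "`. A `TextEncoder` maps text to a unit-norm vector of
dimension `d_bio` (default 768, the dimension of transformer sentence
embeddings; all fixture-scale work here uses 128). Three backends satisfy
the contract:

* `HashingEncoder` — signed bag-of-tokens feature hashing. Stateless and
  deterministic (token buckets come from MD5, not Python's randomized
  hash); texts sharing more tokens have higher cosine, texts with disjoint
  vocabulary are orthogonal in expectation.
* `EmbeddingBagEncoder` — a trainable token-embedding table with mean
  pooling, small enough to fine-tune on a CPU in seconds.
* Any pretrained transformer can implement the same interface; the
  fine-tuning procedure and all downstream code are agnostic to the
  backend.

**Contrastive fine-tuning.** Descriptions of ontology-adjacent terms form
positive pairs; within a batch of B pairs the B×B cosine matrix (scaled by
1/temperature, default 1) is scored against its diagonal with softmax
cross-entropy, symmetrized over rows and columns, and optimized with Adam.
Defaults follow the standard recipe for transformer encoders (lr 1e-5,
batch 16, 256-token truncation); the embedding-bag protocol uses lr 1e-3
because it trains from scratch. The loss gradient is hand-derived,
including backprop through the L2 normalization.

**Instance side.** Each feature block gets one fully connected layer with
ReLU (width `h_j`); blocks are concatenated into F of length Σ h_j.
Protein modality defaults: sequence, description and network blocks of
1500 each (Σ = 4500). Expression profiles use a single 30-wide block over
log1p library-size-normalized counts. Sequences are one-hot encoded over
20 amino acids + X + pad (width 22, pad rows all-pad-channel so appending
pad symbols never changes the result), padded/truncated to L = 2000, and
convolved with 16 kernel sizes 8,16,…,128 × 512 filters, each globally
max-pooled: an 8192-dim embedding.

**Classifier.** p = σ(FᵀWY), trained by multi-label binary cross-entropy
(independent logistic per class, no softmax) with Adam, jointly over the
block encoders and W. The per-batch gradient uses the mean over entries;
the standalone `bce_loss` reports the plain sum so it can be checked
against an elementwise oracle. Class embeddings are computed once and
frozen during classifier training. W is initialized N(0, (0.1/√d_bio)²),
seed-controlled; training is a pure function of (data, config, seed).
`TrainConfig` exposes decoupled (AdamW-style) weight decay, default 0.

**Cross-modal translators.** A translator is a block encoder plus
projection W_m into the text space. It is fitted by *regression*: the
projection of item i's features is driven onto its own description
embedding by mean squared error. We first implemented the alternative —
reusing the multi-label cross-entropy with each item's own description as
its positive class — and found it does not transfer at desk scale: with
10²–10³ training pairs the separating solution leaves the projection
unanchored in text coordinates (cross-modal AUROC ≈ 0.5 while
within-modality retrieval is perfect), whereas the regression solution
matches a ridge oracle. Anchoring to the text coordinates is precisely
what lets two independently trained translators meet in one space. The
pairing score σ((W_aᵀF_a′)·(W_bᵀF_b′)) is unchanged and symmetric in its
arguments. Pathways are embedded by *sum* pooling of member-gene
projections, so pathway size is retained. Ranking candidates uses the
bilinear logit (the logistic is monotone and saturates in float64 at
fixture scales); ties break by candidate id.

**Graph node features.** Where precomputed network embeddings are not
available, nodes of a (phenotype or interaction) graph are embedded by a
diffusion method: the random-walk-with-restart proximity matrix
R = r(I − (1−r)P)⁻¹ (restart r = 0.5, P column-stochastic) is symmetrized
and eigendecomposed; the top-k components scaled by √|λ| are the features,
with a fixed sign convention (largest-magnitude entry positive) for
determinism. Precomputed feature matrices are accepted verbatim.

**Marker genes.** Two routes for a cell type, including ones absent from
any ontology: (1) per-gene Spearman correlation with the per-cell type
probability (constant genes score 0 rather than NaN); (2) the bilinear
score σ(F_geneᵀWY_CL) with W taken from a gene-function model — the same
code path as novel-class scoring, enforced by a regression test. The
cell-type–gene network connects nodes with embedding cosine ≥ 0.9
(configurable), partitions them with seeded Louvain modularity
optimization, and labels each community with the highest-cosine GO term
whose annotation count lies in [100, 2500], falling back to a
breadth-first search over ancestors and descendants (nearest level first,
ties to the lower id).

**Similarity measures.** Text similarity is BLEU (clipped n-gram
precisions n = 1..4, geometric mean, brevity penalty; tokenization is
lowercase word split with punctuation stripped). Orders the candidate is
too short to populate are dropped so identical short texts still score 1;
unsmoothed by default with an add-one smoothing flag for short
definitions; the directional score is available and pairwise tables report
the symmetrized mean. Graph distance is the undirected shortest path over
is_a/part_of edges. Annotation similarity is the cosine of
true-path-propagated binary annotation vectors (Jaccard for pathway gene
sets; k-nearest retrieval defaults to k = 5). The binned association test
groups one similarity by bins of the other (default edges
0.2/0.4/0.6/0.8, last bin open) and applies one-way ANOVA; empty bins are
dropped, fewer than two occupied bins is an error.

## Ontology handling

OBO 1.2/1.4 parsing is delegated to `obonet` behind the module surface,
with a pre-scan that reports malformed tag-value lines by number, quoted
definitions stripped of dbxrefs, obsolete terms retained but excluded from
graph views, and dangling edges dropped with a warning. Annotation
propagation applies the true-path rule over a configurable relation set
(default is_a + part_of; the Cell Ontology graph conventionally uses is_a
only) and is idempotent; cycles raise. Unseen-class splits hold out a
seeded fraction of annotated leaves (or of all annotated terms) and remove
every instance annotated — after propagation — to a held-out term, so no
training example leaks information about an "unseen" class. Unannotated
terms stay in the vocabulary but are never selectable as unseen.

## Synthetic data

The generators plant exactly the structure the method assumes — classes
annotated to similar instances have similar descriptions — and nothing
else:

* **Ontology**: a random tree whose term topics interpolate 50/50 with the
  parent's Dirichlet(0.05) topic over a 500-token vocabulary; descriptions
  sample 30 tokens from the topic, so neighbors share vocabulary.
* **Instances**: every term receives 30 instances with features
  Y_term·M + ε, M a fixed N(0,1) map to 64 dims (unit-variance signal) and
  ε Gaussian with sd 0.5 — i.e. noise-to-signal 0.5 per feature.
* **Expression**: negative-binomial background counts (mean ≈ 2) over 200
  genes × 5 types × 40 cells, with 10 disjoint marker genes per type
  up-shifted by Poisson(4) in their own type only.
* **Paired modalities**: items with independent Dirichlet-topic
  descriptions; modality features are independent N(0,1) linear images of
  the shared description embedding plus noise; 25 % of items are withheld
  from *both* training corpora and form the true-pair evaluation set.

Every generator is a pure function of (spec, seed). What the fixtures do
not model: scRNA-seq dropout and batch structure, realistic sequence
composition, polysemy or grammar in descriptions, annotation
incompleteness. Passing the fixture protocols therefore demonstrates that
the algorithms recover planted signal under the model's own assumptions,
not field performance on real corpora — the latter additionally requires
transformer-grade text embeddings and 10³–10⁶-instance training sets.

## Evaluation protocols and problem sizes

The `benchmarks` module freezes one protocol per headline property, sized
for single-core runs of seconds to a couple of minutes:

* **Zero-shot recovery**: 60-term ontology, 20 annotated leaves held out,
  hashing encoder (d = 128), classifier fit epochs 300 / lr 1e-3 / hidden
  100. Fixture-scale training uses each instance's direct class label: at
  60-term scale the true-path closure makes ancestor columns dominate the
  cross-entropy and blurs sibling leaves (measured mean unseen AUROC 0.81
  propagated vs 0.88 direct against a 0.95 regression-oracle ceiling);
  propagation still governs leakage removal, and propagated training
  remains the default for ontology-scale data.
* **Cross-modal transfer**: 300 items, translators fit epochs 300 /
  lr 1e-3 / hidden 200 / weight decay 3.0 (the decay pulls the regression
  toward the ridge solution, which is what generalizes from a few hundred
  pairs); AUROC of true pairs among all held-out combinations, ranked by
  logit.
* **Contrastive effect**: 30-term ontology, embedding-bag encoder, 5
  epochs; the neighbor-vs-random cosine gap must strictly increase.
* **Markers**: Spearman route trains the expression classifier (epochs
  100) and correlates each gene with the resulting type probabilities;
  embedding route trains a gene→text model on the ontology fixture and
  scores genes against leaf-term descriptions.
* **Association calibration**: all term pairs of a 40-term fixture; the
  response is smoothed symmetric BLEU grouped by bins of annotation
  cosine. One ANOVA on the correlated data plus 200 label-permuted
  replicates at α = 0.05. The permutation type-I rate was measured at
  0.052–0.061 with 2000 replicates; at 200 replicates individual seeds
  fluctuate by ±0.03 around that.

## Numerical choices

* Logistic and softplus are computed in their stable branches; score
  matrices are clipped to the open unit interval at float resolution
  because saturated logits would otherwise round to exactly 0 or 1.
* Rank-based AUROC (ties counted half) delegates to scikit-learn; the
  tests cross-check it against explicit Mann–Whitney pair counting.
* Spearman correlations are computed as Pearson on ranks in one
  vectorized pass; zero-variance columns short-circuit to 0.
* All optimizers are Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) with optional
  decoupled weight decay; non-finite losses or gradients abort with a
  diagnostic rather than propagate NaNs.
* Determinism: every stochastic step draws from a `numpy` Generator
  seeded from the relevant config; re-running a fit with the same seed
  reproduces weights bit-for-bit on one platform.

## Known limitations

* The pretrained-transformer text backend (and hence replication of
  full-scale results on curated corpora) is out of scope here; the
  encoder contract is designed for it but the shipped backends are a
  hashing encoder and a small embedding bag.
* Translator fitting is regression-based; at corpus sizes of 10⁴⁺ pairs a
  discriminative objective may be preferable, and the `TrainConfig`
  surface does not currently switch objectives.
* The diffusion node embedding is a generic RWR+spectral method, not a
  reimplementation of any specific published network-integration
  pipeline; for published precomputed features, pass them through
  directly.
* Community detection and the 0.9 cosine edge threshold are conventional
  defaults, not fitted quantities; downstream biological claims should
  not hinge on them.
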