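# Methods

## Problem setting

Drug–target interaction (DTI) prediction is cast as binary classification of
drug–protein pairs embedded in a heterogeneous graph with four node types
(drugs, proteins, diseases, side-effects) and eight undirected relations: the
drug–protein interaction network that carries the labels, drug–drug and
protein–protein interaction networks, chemical-structure and
sequence-similarity networks (weights in (0, 1]), and drug–disease,
protein–disease and drug–side-effect association networks (weights exactly 1).
Absent edges mean "no known relation", not "no relation". The data model
follows the plain-text dense-matrix layout of the DTINet benchmark family
(`mat_drug_protein.txt` etc.); node identity is the 0-based matrix row index.

## Model

Writing `C(v) ∈ R^dim` for the content vector of node `v`:

1. **Content encoding.** Each node type has its own bidirectional LSTM that
   reads `C(v)` as a one-element sequence:
   `f1(v) = LSTM_fwd(C(v)) ⊕ LSTM_bwd(C(v))`, each direction `dim/2` wide.
   Over a single element the initial cell state is zero, so the forget gate
   multiplies zero and drops out; each direction reduces to
   `c = i ⊙ g`, `h = o ⊙ tanh(c)` with input, candidate and output gates.
   This is functionally identical to a full LSTM cell on length-1 input and
   is implemented that way (the inert gate would receive no gradient).
2. **Homogeneous aggregation.** For node `v` and relation `r` with neighbor
   set `N_r(v)` and edge weights `W_e`,
   `G^r(v) = Σ_{u∈N_r(v)} W_e f1(u) / M^r(v)` with `M^r(v) = Σ W_e` —
   a convex combination of neighbor encodings. Similarity self-entries are
   not edges; aggregation runs over `u ≠ v`.
3. **Attention fusion.** The candidates `φ ∈ {C(v)} ∪ {G^r(v): N_r(v) ≠ ∅}`
   compete through a softmax over scores
   `LeakyReLU(u^T [φ ⊕ C(v)])` with `u ∈ R^{2·dim}` shared across nodes
   (negative slope 0.2): `F(v) = Σ_i α_i φ_i`. The concatenation with `C(v)`
   is what makes a `2·dim`-long attention parameter consumable; a config
   switch (`self_term='encoded'`) replaces the self candidate `C(v)` by
   `f1(v)`, which is the other defensible reading of the fusion step.
   Embeddings are produced for drugs and proteins only; diseases and
   side-effects participate as neighbors.
4. **Pair classification.**
   `O = sigmoid(FC2(ReLU(FC1(F_d ⊕ F_t))))`, `FC1: 2·dim → dim/2`,
   `FC2: dim/2 → 1`. Training minimizes mean binary cross-entropy
   (probabilities clamped at 1e-7) with Adam at learning rate 0.001,
   end-to-end through all four stages, including the learnable content
   vectors of diseases and side-effects.

One aggregation layer is the default; a `depth` parameter stacks further
layers that re-aggregate the previous layer's drug/protein outputs (other
types keep `f1`), for studying aggregation depth.

## Node content

* **Drugs** — a 1024-bit Morgan fingerprint (radius 2, RDKit) read as 256
  hexadecimal digits; the raw 256-vector of digit values (0–15) is reduced to
  128 by the elementwise mean of its two halves. Radius-2 Morgan bits match
  the convention by which the benchmark's chemical-similarity matrix is
  computed. The fingerprint backend is pluggable (precomputed feature files
  are accepted).
* **Proteins** — type-1 pseudo amino acid composition over hydrophobicity,
  hydrophilicity and side-chain mass (each z-scored over the 20 residues):
  20 composition fractions plus λ = 44 sequence-order correlation factors,
  weight w = 0.05, giving 64 components summing to 1; expanded to 128 by
  duplicate concatenation. λ and w are config; λ = 44 is forced by the
  20 + λ = 64 output size, w = 0.05 is the field-standard default.
* **Diseases / side-effects** — seeded uniform vectors, 0–1 (min–max)
  standardized per vector, registered as trainable parameters.
* All content rows are 0–1 standardized per vector, putting hex-digit-scale
  fingerprints (0–15), PseAAC fractions (~0.01) and the learnable vectors on
  one scale; without this the protein gate pre-activations are three orders
  of magnitude smaller than the drug ones and the protein encoder starts
  effectively constant.
* With no SMILES/FASTA supplied (matrix-only runs), drugs and proteins fall
  back to seeded learnable vectors like diseases; the fallback is logged.

## Reliable negative sampling

For an unknown pair `(d_i, t_j)`, with `A` the drug-similarity and `B` the
protein-similarity matrix, `T_{d_i}` the targets of `d_i` and `D_{t_j}` the
drugs of `t_j`:

    s_ij = exp(-(Σ_{t_k∈T_{d_i}} B[t_j,t_k] + Σ_{d_k∈D_{t_j}} A[d_i,d_k]))

so `s_ij ∈ (0, 1]`, equal to 1 exactly when the pair is isolated from the
known interactome. Negatives are drawn from candidates with `s_ij` above a
threshold (default 0.1) — uniformly at random by default, which reconciles
"rank descending and take high scores" with "sample a certain number"; a
`top` mode takes the highest scores deterministically (ties broken by index),
and threshold 0 with uniform draws reproduces plain random sampling for the
sampling-mode comparison. Datasets contain all known DTIs as positives plus
`ratio` (default 10) times as many sampled negatives.

## Evaluation protocol

Stratified ("hierarchical") k-fold cross-validation, k = 10, with the 1:10
class ratio preserved per fold; repeated over trial seeds derived from a
first-level seed (default 10), with fresh negatives drawn each trial; metrics
are AUROC (rank form, ties half) and AUPR (stepwise precision–recall
integration), reported per fold and aggregated as mean ± sd over trials.
Redundancy-removal scenarios greedily drop positives whose drug similarity
(> 0.6), protein similarity (> 0.4) or association-profile Jaccard
similarity (> 0.6; drug interactions, side-effects, or diseases — the latter
also checks protein–disease profiles) ties them to an already-kept positive;
the scan runs in node-id order, so the first member of a redundant group
survives, and the removal log is returned. The unique scenario trains on
positives whose drug or protein has other interactions and tests on pairs
where both endpoints have degree 1. Ablation scenarios drop whole relations
or node types (the drug–protein backbone cannot be dropped).

**Leakage control:** inside `HGDTIClassifier.fit` the drug–protein edges
used for aggregation are restricted to the positive pairs present in the
training data, so a held-out fold's interactions are invisible to message
passing during both training and scoring of that fold.

## Synthetic benchmark

The generator plants k-dimensional latent vectors (default k = 4) for 50
drugs and 80 proteins. Interactions are Bernoulli draws with probability
`sigmoid(z_d·z_t·(3/√k) + b)`, `b` calibrated by bisection so the realized
density matches the configured 0.05. Similarity matrices are
`clip(cos(z,z'),0)²` plus clipped Gaussian noise (sd 0.1), symmetrized with
unit diagonal — mass near zero with a high-similarity tail, as in real
chemical/sequence similarity matrices. Same-type interaction networks
threshold the latent affinity at its 90th percentile; 20 diseases and 15
side-effects attach to the latent-nearest 15–20% of nodes plus 2% background
noise. Because the real benchmark computes its similarity networks *from*
the structures, the sequence fixtures preserve that coupling: drugs in a
latent cluster share a molecular scaffold (decorated more heavily with
latent distance) and proteins are mutated copies of per-cluster prototype
sequences (mutation rate 5–50% growing with latent distance), so fingerprint
and PseAAC features correlate with the planted similarity structure.

What the fixture does **not** emulate: the benchmark's scale (708 × 1512),
its heavy-tailed degree distributions, isolated diseases/side-effects in
bulk, real chemistry (fingerprint bits are only cluster-informative), or the
empirical reliable-score distribution. Passing tests demonstrate that the
pipeline recovers planted low-rank structure under realistic coupling of
content, similarity and interactions — not performance on any real dataset.

## Numerical and design choices

* Hand-derived analytic gradients (verified against central finite
  differences to ≤ 1e-4 relative error in the test suite); float64
  or float32 compute — the estimator defaults to float32, which halves
  training memory traffic; runs are bitwise reproducible either way.
* Mini-batches of 32 pairs (configurable; `None` = full batch) with the full
  graph's embeddings and gradients recomputed every update; epoch loss is
  the sample-weighted mean over batches.
* Convergence: stop when the epoch-loss change stays below tol = 1e-4 for 3
  consecutive epochs (a single sub-tol step of a stochastic mini-batch loss
  is not convergence), or at max_epochs = 100.
* LSTM input/output gate biases initialize at +1 (open gates), other
  parameters uniform in ±1/√fan_in; the attention softmax is max-shifted.
* Weight-normalized aggregation matrices are precomputed per relation; rows
  without neighbors are masked out of the softmax rather than zero-filled.
* The protocol drivers in the acceptance script use 10 folds for the main
  cross-validation and 3 folds / 1 trial (2 folds for the depth-2 run) for
  the sampling-mode, ablation and depth comparisons — directional contrasts
  that do not need the full 10 × 10 design.
* Seeds fan out from one top-level seed through fixed `SeedSequence`
  derivations (content, sampling, model, protocol), mirroring a two-level
  seed scheme; every run is reproducible from its config echo plus seed.

## Known limitations

* Inductive prediction for nodes outside the graph is not supported: a new
  drug or target has no neighborhoods to aggregate (the unique-split
  scenario quantifies the degraded sparse-neighborhood regime).
* The attention parameter is shared across node types and layers; per-type
  attention is not implemented.
* Training recomputes full-graph embeddings per mini-batch, which is exact
  but quadratic-ish in graph size; the implementation targets desk-scale
  graphs (hundreds of nodes), not the full benchmark scale.
* The redundancy filters are order-dependent by design (deterministic
  greedy first-kept scan); other scan orders give different survivor sets.
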