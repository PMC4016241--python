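# Methods

## Problem setting and model

The package addresses disease-gene prioritization as positive-unlabeled
classification.  Given a positive set *P* of confirmed disease genes and an
unlabeled universe *U* (which contains undiscovered disease genes), the
method exploits guilt-by-association on three evidence layers — physical
interaction, co-expression and functional (GO) similarity — plus phenotype
similarity, to (a) manufacture graded pseudo-labels for unlabeled genes and
(b) train an ensemble of three weighted classifiers on them.

### Networks

* **PPI** — binary symmetric adjacency from an undirected edge list; no
  sparsification (interaction maps are already sparse).  Duplicate edges
  keep the maximum weight; self-loops are dropped and counted.
* **Co-expression (GE)** — all-pairs Pearson correlation over tissue
  profiles; each gene keeps its top-k partners (k = 5 by default) ranked by
  descending similarity, ties broken by ascending gene id.  Genes with
  constant profiles correlate 0 with everything and are flagged.
* **GO similarity** — each gene keeps its top-k nearest genes by Euclidean
  distance on the GO feature block, with edge weight `1/(1 + Dis)`.  This
  weight form was chosen because it satisfies the required bound
  `0 ≤ w ≤ 1`, equals 1 at distance 0 and decreases monotonically; it is
  one of several forms consistent with those constraints.

Per-gene top-k lists are directed; we symmetrize by **union** (an edge
survives if either endpoint ranks the other) so the stored matrix is
symmetric, as its use in propagation requires.

The transition operator is the transpose of the row-normalized matrix
`D⁻¹W` (column-oriented, so each connected gene's column sums to 1 and a
matrix-vector product conserves out-flow).  Because co-expression weights
may be negative, both the degree and the propagated weight use |w| by
default (`network.use_abs_weights`); a signed `D⁻¹W` is not a well-defined
flow.  The stored GE edge weights remain raw Pearson values.

### Phenotype filtering and seeding

Phenotype similarities pass through `L(s) = 1/(1 + exp(c·s + d))` with
c = −15 and d = ln 9999 (the standard propagation-method parameterization);
entries with L < 0.5 — i.e. raw similarity below ln(9999)/15 ≈ 0.614 — are
zeroed, the rest replaced by L(s).  Candidate positives (CP) are genes from
the known-disease universe, outside P and outside the current evaluation
sample, with at least one phenotype surviving the filter against PH(P);
their seed score is the maximum such similarity.  "Survives the filter" is
our reconstruction of the CP extraction threshold: it matches the filtered
network's semantics (zero = not similar) and needs no extra parameter.

Reliable negatives (RN) are unlabeled genes strictly farther from the
positive representative vector *pr* than the unlabeled average distance.
*pr* is the **mean** of the positive gene vectors: a unit-normalised sum
would put *pr* on a different scale from the raw gene vectors that the
Euclidean comparison uses.  The strict inequality at exactly the average
distance is a deliberate tie-break (a gene at the average is not "reliably"
far).

Seed scores are flow-balanced: +1 per positive, the phenotype score per CP
gene, and `−(|P| + Σ cp_scores)/|RN|` per RN gene, so the signed seed mass
is zero.  "Positive mass" includes the CP mass by default
(`seed.balance_include_cp`); balancing against |P| alone is available.

### Propagation

`R_t = (1 − α)·Ŵ·R_{t−1} + α·R₀`, starting from `R₁ = R₀`, α = 0.7,
stopping when the L1 change drops below 10⁻⁶ (cap 1000 iterations, flagged
if hit).  With the substochastic Ŵ this is a contraction with factor
(1 − α), so ~20–40 iterations suffice in practice and the iterative fixed
point matches the direct solve `α(I − (1 − α)Ŵ)⁻¹R₀` (tested to 10⁻⁵).
The integrated score is the arithmetic mean of the three network scores; a
gene absent from a network contributes 0 there but the divisor stays 3
(`propagation.mean_over_present` switches to dividing by membership).
A mean rather than a sum does not change sign-based partitions but keeps
classifier confidence weights on a bounded scale.

### Features

Gene vectors concatenate five blocks: MF, BP and CC anchor-term
similarities, binary protein-domain indicators, and four min-max-scaled
interaction-topology statistics (degree, mean neighbour degree, clustering
coefficient, isolation flag).  A GO anchor feature value is the best Wang
similarity between any of the gene's annotated terms and the anchor.  Wang
similarity uses per-ancestor semantic contributions decaying by 0.8
(`is_a`) / 0.6 (`part_of`) per edge along the best child-to-parent path,
and scores a term pair by the shared-ancestor contribution mass over the
total.  Anchor terms are selected per sub-ontology by the absolute
difference of class means, `|mean_P val − mean_U val|`, keeping the top
1000 (or all, when fewer exist — the synthetic ontologies are small); this
class-separation score is our concrete choice for a selection strategy the
source line of work names but does not specify.  Selection uses only
training-fold genes, so held-out genes never influence the feature space.

### Base classifiers

* **WKNN** (k = 3): among the query's k nearest training genes, positive
  integrated-score mass over total mass gives p₊.  Neighbours with score
  exactly 0 sit on the positive side but contribute no mass; an all-zero
  neighbourhood returns (0.5, 0.5).  The mass-ratio form is our
  reconstruction of "accumulates scores per class and estimates the
  probability from the accumulated scores".
* **WNB**: weighted multinomial naive Bayes,
  `P(f|c) = (1 + Σ w·v) / (m + Σ Σ w·v)` (Laplace λ = 1), priors 0.5/0.5,
  computed in log space.  P and RN genes weigh 1; remaining unlabeled genes
  join the pool matching their score sign, weighted by magnitude.  The
  multinomial form with fractional counts is the standard weighted-text
  construction this family of PU methods builds on.
* **MSVM**: the remaining unlabeled genes split into LP (score ≥ mean of
  positive scores), LN (≤ mean of negative scores) and WN (rest).  P and LP
  train as +1, RN/LN/WN as −1, with slack multipliers 1 / 0.5 / 1 / 0.5 /
  0.25 (P/LP/RN/LN/WN) on a base cost chosen from {0.1, 1, 10} by
  stratified 3-fold cross-validation on F-measure (cross-validation being
  the only guidance given for these costs).  Kernel is linear by default
  (RBF available).  Points with non-positive effective cost are dropped
  before fitting — a zero slack penalty removes a point from the
  objective.  Posteriors come from a Platt-style sigmoid (logistic
  regression on training decision values).

### Ensemble

Margins `m_ij = P_j(+|g_i) − P_j(−|g_i)` for every training gene come from
base models that never saw that gene (leave-one-out by default; inner
k-fold as a faster option — the protocol runs use 5).  Weights are learned
by batch least-mean-squares descent on the continuous squared error
`E = ½Σ(y_i − s_i)²` with `s_i = Σ_j a_j m_ij`: the hard ±1 prediction in
the error definition is non-differentiable, so the gradient uses the
continuous score (the classical delta rule) while the hard training error
is reported separately.  η decays as `η₀/(1 + t/100)` from η₀ = 0.001
("reduce η gradually"); initial weights are uniform [0, 1) from a mandatory
seed; stopping is `‖Δa‖₁ < 10⁻⁶` or 10,000 iterations.  Weights are not
renormalized after training, and no nonnegativity constraint is imposed.
A tied ensemble score (s = 0) predicts the negative class — conservative
for prioritization.

## Evaluation protocol

For each of several resampled unlabeled groups (|U| = |P|, drawn uniformly
from the universe minus the declared positives), the (P + U) sample splits
into 3 class-stratified folds; two train, one tests, rotating.  Seeding,
propagation, level partition, classifier fitting and ensemble training all
use only training-fold genes; candidate-positive extraction additionally
excludes the entire evaluation sample, because in a single-disease bundle
the remaining known disease genes are exactly the held-out fold.  A
leakage assertion verifies on every fold that no test gene appears in P,
U, CP, RN, LP/LN/WN or the nonzero seed set.  Precision, recall and
F-measure (harmonic mean) are recorded per fold and model; macro averages
are means over rows (per-run averaging — averaging p and r first and then
taking the harmonic mean would give different, non-comparable numbers).
Test-fold unlabeled genes count as negatives in the metrics even when they
are (unknowingly) hidden positives, which slightly depresses measured
precision by design.

## Synthetic study conditions

Defaults: 600 genes, a 60-gene disease module with 50 % hidden from the
declared list, 16 tissues, within-module edge probability 0.2 vs 0.01
background, within-module expression correlation target 0.7, three
depth-3/branching-3 random sub-ontologies with one disease clade each,
20 domains (3 disease-enriched), 100 phenotypes in 5 groups (within-group
similarity ~U(0.7, 1), between ~U(0, 0.3)), annotation noise rate 0.1,
seed 42.  The 16-tissue count mirrors the tissue panel typical of
body-wide expression atlases; module sizes and probabilities were chosen
once to give a clearly recoverable but noisy signal at desk scale.
Hidden positives are the evaluation currency: they are genuinely in the
module but absent from the positive list, so a correct PU method should
rank them highly among unlabeled genes.

What the generator does **not** emulate: scale-free interaction degree
distributions, realistic GO topology and annotation depth, correlated
evidence errors, multiple overlapping disease modules, or incomplete
phenotype coverage of true disease genes.  Passing tests therefore
demonstrate the machinery is correct and the protocol leak-free under
idealized planted structure — not that the method attains any particular
accuracy on real corpora.

## Numerical choices and degenerate inputs

* Ties everywhere resolve by descending score then ascending identifier,
  making runs reproducible across platforms.
* Zero-variance expression profiles correlate 0 and are flagged; zero-degree
  network nodes get zero transition columns (no division error).
* An empty RN leaves seeds unbalanced with a warning; an empty CP is valid
  (warned when P has no phenotype links at all).
* Problem sizes in the shipped protocol runs (3 unlabeled groups × 3 folds,
  inner 5-fold soft labels on the 600-gene bundle) were chosen as a
  desk-scale design point; LOOCV and 10 groups remain the library defaults.

## Known limitations

* The ensemble's margin over its best base model is small at desk scale;
  with only ~40 training rows and three correlated base models, the learned
  weights mostly track the strongest classifier (usually the multi-level
  SVM), and on some bundle seeds the ensemble trails it by a point or two
  of F.
* Gradient descent on the margin matrix is convex, but the decaying step
  size can stop short of the least-squares optimum within the iteration
  cap; the recorded error history makes this visible.
* Wang-similarity computation caches per-term ancestor contributions; for
  ontologies of real-world size the gene × anchor matrix construction is
  the dominant cost and would need batching.
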