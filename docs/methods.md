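# Methods

This note documents the statistical conventions, numerical choices and
known limitations of the `igisplus` implementation. It covers decisions a
user of the selection results should be aware of; the README describes the
algorithm itself.

## Data model and preprocessing

An expression dataset is a samples × genes real matrix with 2–5 class
labels (every class with at least two members). Each gene is min–max
rescaled to [0, 1] independently; a constant gene maps to all zeros so it
stays inert for distance-based classifiers. In nested cross-validation the
min and max come from the outer training rows only and the resulting
affine map is applied to held-out rows (which may then fall slightly
outside [0, 1]; they are not clipped, since clipping would use held-out
information to redefine the map).

For the information-theoretic filter only, each gene is discretized into
three states at μ_g ± σ_g: −1 below the lower threshold, +1 above the
upper, 0 otherwise, with boundary values mapping to 0. The per-gene mean
and standard deviation are computed over the training rows only and σ uses
the n−1 (sample) convention; `ddof` is configurable through
`SelectorConfig`. Classifiers always see the raw rescaled values — the
states exist only inside the candidate-ranking criterion.

## Information measures

All measures are plug-in (maximum-likelihood) estimates in bits, with no
pseudocounts or bias correction — the criterion is only ever used to *rank*
candidates, where the shared small-sample bias largely cancels. Interaction
information uses the synergy-positive convention
II(Xj; Xi; C) = I(Xj; C | Xi) − I(Xj; C), so the JMI score
J(Xj) = I(Xj;C) + mean_i II(Xj; Xi; C) rewards candidates that are jointly
informative with the selected set. Argmax ties break to the smallest gene
index, for determinism.

A consequence worth recording: algebraically
J(Xj) = mean_i I(Xj; C | Xi), a mean of conditional mutual informations,
so a plug-in JMI score is never negative. The "all remaining candidates
have negative JMI scores (i.e. are redundant)" stopping rule is therefore
implemented as J ≤ 10⁻¹² — it fires exactly when no remaining candidate
carries *any* conditional information beyond the selected set, which in
practice means exact duplicates (empirical conditional MI of even pure
noise is strictly positive at finite sample size). A strictly negative
threshold would be unreachable and the rule dead code.

## Accuracy vectors and the gates

One wrapper evaluation = one k-fold cross-validation pass over one
candidate subset (the unit in all reported evaluation counts). The fold
plan is built once per selection run and reused for every candidate, so
accuracy vectors are fold-aligned: fold f's model is fitted on the other
k−1 folds, its **validation** rate is its accuracy on fold f, and its
**training** rate is its accuracy on the whole training partition (all k
folds). Scoring the whole partition rather than only the fitting rows
keeps training rates informative for memorizing classifiers — an unpruned
CART tree has resubstitution accuracy identically 100%, which would make
effect sizes on training rates identically zero and trip the
perfect-training stopping rule at initialization on every run.

Cohen's d uses the pooled standard deviation with denominator n_t + n_c.
The more common convention divides by n_t + n_c − 2; the algorithm is
defined with the former and the package implements it exactly as defined
(the n − 2 variant is available via `pooled_sd(..., denominator=
"textbook")`, and since both n's are the inner fold count k, the two
differ only by the constant factor sqrt(k/(k−1)) ≈ 1.15 at k = 4 — a
uniform inflation of every d, partially absorbed by the fixed thresholds).
Degenerate cases: zero pooled SD with equal means gives d = 0; with
unequal means it gives signed infinity, so an all-perfect improvement
passes any gate. Both gate thresholds (0.40 training, 0.15 validation)
are inclusive. In the original algorithm's paired t-tests, all-zero
differences give p = 0.5 (not significant), preventing a zero-variance
division from fabricating acceptances.

Accuracies are stored as fractions in [0, 1]; d and t are scale-invariant
so this does not affect any decision.

## Selection loop details

- The first gene is chosen by single-gene accuracy on the full training
  rows (fitting and scoring on the same rows). This is the fast default;
  `SelectorConfig(first_gene_method="cv")` substitutes mean inner-CV
  validation accuracy. Note that for CART the fast method saturates at
  100% for every gene and the choice falls through to the tie-break:
  larger mutual information with the class, then smaller index.
- The perfect-accuracy stop compares the *mean* of the k per-fold rates to
  100% and is checked after initialization and after every acceptance.
- Candidate order is fully determined by the JMI criterion plus the
  smallest-index tie-break: selection itself has no randomness, all
  stochasticity lives in fold-assignment seeds.
- The best-number-of-genes rule (`choose_best_prefix`) returns the prefix
  of the acceptance sequence with maximal mean validation accuracy, ties
  going to the shorter prefix (parsimony).

## Nested cross-validation

Outer stratified 5-fold, inner 4-fold, 10 runs by default; run r uses seed
base + r and each outer fold derives an inner-fold seed from (run seed,
fold index), all below 2³¹. Per-class fold counts differ by at most one
(classes smaller than k are spread round-robin). Selection, discretization
statistics and rescaling statistics see outer-training rows only;
`igisplus.audit.RowAccessRecorder` instruments a run to prove it, and the
test suite additionally verifies that corrupting held-out rows changes
nothing about which genes are selected.

Reported aggregates are arithmetic means of per-run means (accuracy,
macro-F) or of per-fold values (genes selected); comparison tables use
fractional ranks (ties share the mean of the tied ranks).

## Synthetic data generator

The generator emulates the shape of microarray classification problems:
M ∈ [60, 253] samples, thousands of genes (desk-scale default 100 × 200 —
dimensions are configurable and everything scales, the defaults just keep
test runtimes in seconds), 2–5 classes with optional imbalance
(largest-remainder apportionment keeps class sizes deterministic), and
planted structure among independent standard-normal noise genes:

- **informative** genes: class-conditional Gaussian means separated by a
  stated effect size in SD units;
- **xor_pair** genes (binary problems): two latent bits with
  XOR(b₁, b₂) = class, each gene = its bit + Gaussian noise (SD 0.1 by
  default) — individually near-independent of the class, jointly
  predictive;
- **redundant_of** genes: a named planted gene plus small Gaussian noise.

The latent XOR bits are drawn with probability 0.4 rather than 0.5. With
exactly equiprobable bits the two value clusters of each gene sit exactly
at the μ ± σ discretization thresholds (for a symmetric two-point
distribution, σ equals the distance from the mean to either point), so
half of each cluster lands in the ambiguous middle state and the
discretized pair interaction saturates near 0.25 bits. At 0.4 the clusters
move off the thresholds and the pair interaction rises to ≈ 0.43 bits
while each gene's individual MI with the class stays ≈ 0.03 bits.

What the generator does **not** model: probe-level noise, batch effects,
gene–gene correlation beyond the planted structure, or heavy-tailed
expression distributions. Passing recovery tests on this generator shows
the algorithm finds the kinds of structure it was designed for; it does
not certify performance on real microarray data.

## Known limitations

- **Pure pairwise synergy is hard to enter.** Genes are accepted one at a
  time, and a candidate must improve cross-validated accuracy *on its own*
  (relative to the current subset) to pass the effect-size gates. A gene
  that is individually independent of the class — one member of an XOR
  pair, say — therefore rarely enters the subset unless its partner is
  already there; once one member is in, the JMI criterion immediately
  ranks the partner on top and the wrapper accepts it. In recovery
  simulations with an XOR pair planted among noise, both genes are
  selected only in the minority of runs where one member happens to clear
  the gates alone (or wins the first-gene race). This is a structural
  property of incremental wrapper acceptance, not of the ranking
  criterion: the filter sees the synergy, the gate cannot.
- The wrapper gates test accuracy differences across only k = 4 folds;
  effect-size estimates at that sample size are noisy, and acceptance
  decisions near the thresholds vary between fold seeds.
- KNN prediction is O(n²) per fold; selection on datasets with tens of
  thousands of genes is feasible (the loop is O(N) wrapper evaluations and
  O(N·|S|) interaction updates) but takes minutes, not seconds.
- Classifier determinism: KNN breaks distance ties by the smaller
  training-row index and vote ties by the smallest class label; CART is
  seeded. Runs are therefore bit-reproducible given seeds, but tie
  behaviour is a convention, not a statistically motivated choice.
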