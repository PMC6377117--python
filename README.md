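# igisplus

Hybrid filter–wrapper gene selection for high-dimensional classification
data (microarray-style expression matrices: tens to hundreds of samples,
thousands of genes, 2–5 classes).

## The problem and the method

Filter methods rank genes by intrinsic statistics and are fast but keep too
many genes; wrapper methods score candidate subsets with a classifier and
are accurate but expensive and prone to overfitting. `igisplus` implements
a hybrid, incremental algorithm (IGIS+, with its predecessor IGIS included
for comparison):

1. **First gene.** The gene whose single-gene classifier has the highest
   training-set accuracy, `X_k = argmax_i Acc(X_i)`.
2. **Filter step.** With selected set `S`, each remaining candidate `X_j`
   is scored by the joint-mutual-information (JMI) criterion

   `J(X_j) = I(X_j; C) + (1/|S|) · Σ_{X_i ∈ S} I(X_j; X_i; C)`

   — individual relevance plus average interaction information with the
   genes already selected, computed on a three-state discretization of each
   gene at μ ± σ. The interaction term is synergy-positive: a pair of genes
   that is jointly informative (e.g. an XOR pair) scores above its parts,
   while a redundant copy is penalized.
3. **Wrapper step.** The top candidate is added provisionally and the
   subset is evaluated by k-fold cross-validation with the actual
   classifier (KNN with K = 3, or a CART tree) on the raw, un-discretized
   values. The candidate is kept iff Cohen's d between the new and the
   best per-fold accuracy vectors reaches a **medium effect (d ≥ 0.40)**
   on training rates **and a small effect (d ≥ 0.15)** on validation
   rates, with `s_pooled = sqrt(((n_t−1)s_t² + (n_c−1)s_c²)/(n_t+n_c))`.
   A rejected candidate is discarded and the search continues.
4. **Stopping.** The search ends when every gene has been explored, when
   no remaining candidate has a positive JMI score (all remaining genes
   redundant), or when mean training or validation accuracy reaches 100%.

The original IGIS differs in all three places: first gene by mutual
information alone, paired t-tests at the 0.1 level as the gate, and a hard
stop at the first significant validation drop (which can end the search
far too early — see `examples/04_original_vs_improved.py`).

Evaluation uses nested stratified cross-validation: an outer 5-fold
estimates test accuracy while an inner 4-fold drives all selection
decisions, so held-out samples never influence the chosen genes,
discretization thresholds, or rescaling statistics.

## Worked example

```sh
python examples/01_simulate_and_select.py
```

```
dataset: 100 samples x 150 genes, planted informative gene: g42
selected genes (acceptance order): ['g42', 'g11', 'g106']
stop reason: perfect_accuracy
wrapper evaluations used: 23
best prefix by inner validation accuracy: ['g42', 'g11', 'g106']
final per-fold validation accuracies: [1.0, 1.0, 1.0, 1.0]
```

The planted gene `g42` wins the first-gene race; two further genes clear
the effect-size gates before mean validation accuracy reaches 100% and the
search stops after only 23 of 150 possible wrapper evaluations. The other
examples demonstrate pairwise synergy measurement (`02`), the nested-CV
harness (`03`) and the early-stopping contrast with the original algorithm
(`04`).

The same functionality is scriptable from the shell:

```sh
igisplus simulate --m 100 --n 200 --informative 0:4.0 --seed 7 --out data.tsv
igisplus select --data data.tsv --selector igis+ --classifier knn --trace-out trace.tsv
igisplus run --data data.tsv --runs 10 --seed 42 --out report.tsv
```

## Layout

- `src/igisplus/data_io.py` — tab-delimited I/O, unit-interval rescaling, μ±σ discretization
- `src/igisplus/info_theory.py` — entropy, MI, interaction information, JMI ranking
- `src/igisplus/significance.py` — Cohen's d gates and paired t-tests
- `src/igisplus/wrapper_cv.py` — stratified folds, classifiers, wrapper evaluations
- `src/igisplus/selectors.py` — IGIS+ and original IGIS selection loops
- `src/igisplus/metrics.py` — accuracy and macro-averaged F-score
- `src/igisplus/harness.py` — nested-CV experiment driver and rank tables
- `src/igisplus/synthetic.py` — ground-truth data generator and recovery suite
- `src/igisplus/audit.py` — row-access instrumentation for leakage audits
- `src/igisplus/cli.py` — `igisplus simulate | select | run | report`

See `docs/methods.md` for the statistical conventions, generator design
and known limitations.
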