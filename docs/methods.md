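# Methods

This note records the modelling assumptions, parameter choices, and known
limitations behind `epofs`. It documents design, not results: every
empirical statement here is one the test suite or `scripts/acceptance.py`
computes itself.

## The optimizer

EPO maintains `n_pop` real-valued positions in a box and maximizes an
arbitrary objective. One iteration recomputes the population mean, then
moves each candidate with one of the phase's two update rules (fair coin)
and accepts the move only if it improves that candidate's own fitness
(greedy, elitist replacement — the global best can never degrade, which is
what makes the monotone-history invariant testable). Before the first
iteration the whole population takes a single search-space-selection step
toward the incumbent best.

Phase scheduling is a design choice the update rules themselves do not fix:
we run the two exploration rules for the first `phase_split` fraction of
iterations (default 2/3, the convention of this optimizer family) and the
two exploitation rules afterwards.

### Stochastic components

- **Lévy flight.** Steps are `0.01·u·ω/|v|^(1/b)` with `u, v` standard
  normal and `ω` the Mantegna scale
  `[Γ(1+b)·sin(πb/2) / (Γ((1+b)/2)·b·2^((b−1)/2))]^(1/b)`. Uniform draws
  for `u, v` would produce no heavy tail and defeat the purpose of a flight
  distribution; the normal convention is therefore used and the sampler's
  kurtosis is checked by test. Draws of `v` exactly zero are redrawn.
- **Spiral coefficients.** Per dimension, `Θ = a·π·β` and `r = Θ + SC·β`;
  `X` and `Y` are `r·sin Θ` and `r·cos Θ` normalized by their maximum
  absolute entries, so `max|X| = max|Y| = 1`. A numerically all-zero axis
  (every angle a multiple of π) triggers a redraw rather than a division by
  round-off noise.
- **Quality function.** The narrowed-exploitation weight is
  `QF(t) = t^((2β−1)/(1−T)²)`, which stays in a bounded band and decays the
  influence of the incumbent best as the run ends; evaluated from `t = 1`.
- **Randomness.** One `numpy` generator seeded from `EpoConfig.seed` drives
  every draw in a fixed order (branch coin, then the rule's own draws), so
  runs are bit-for-bit reproducible; the acceptance of this contract is a
  test.

### Defaults

| parameter | default | meaning |
|---|---|---|
| `n_pop` | 30 | population size |
| `n_iter` | 100 | iterations |
| `alpha` | 0.5 | search-space-selection step scale, in (0,1) |
| `gamma` | 0.5 | exploration contraction, in (0,1) |
| `b` | 1.5 | Lévy exponent |
| `search_cycle` | 2.5 | spiral cycle SC, in (0,5) |
| `rotation_a` | 5.0 | spiral rotation a, in (2,10) |
| `w_max`, `w_min` | 0.9, 0.4 | exploration-factor schedule endpoints |
| `phase_split` | 2/3 | fraction of iterations spent exploring |

`alpha`, `gamma`, `search_cycle` and `rotation_a` have only stated ranges,
not values, in the method's description; the defaults take midpoints of
those ranges. Population 30 and 100 iterations follow the benchmark
settings commonly used with this family. The exploration factor
`W(t) = w_max − (w_max − w_min)·t/T` is computed and exposed for logging
and schedule reuse (the mutation rate mirrors its shape), but no update
rule consumes it directly — none of the five equations reference it — so
with the hard phase split it is informational. Cognitive/social
coefficients (c1, c2) sometimes quoted alongside this optimizer appear in
no update equation and are deliberately not parameters.

`n_iter = 0` is allowed and returns the best member of the initial
population untouched, which gives callers a clean "no search" baseline.

## The wrapper

- **Binarization.** `sigmoid(position) > 0.5`, strict, so a coordinate of
  exactly 0 is unselected; an empty mask is repaired to the argmax
  coordinate. The box is `[−4, 4]`, covering sigmoid values ~0.02–0.98.
- **Fitness.** `f(s) = α·A + (1−α)·(1 − Ns/Nt) − W·P(s)` with defaults
  `α = 0.9`, `W = 0.1`, chosen so accuracy dominates and sparsity/redundancy
  act as tie-breakers; both are exposed. `A` is stratified 5-fold CV
  accuracy on the training data with fold indices fixed once per
  (dataset, config) — every mask is scored on identical splits, which makes
  fitness a deterministic function of the mask and lets the stochastic
  search be compared against the exhaustive oracle on equal terms. The
  0.632+ estimator is reserved for final reporting: running B bootstrap
  fits inside every fitness call would multiply the wrapper's cost by B.
  `P(s)` is the mean absolute pairwise Pearson correlation of the selected
  genes (Spearman available), 0 for singletons, bounded in [0,1];
  zero-variance genes contribute 0.
- **Mutation.** Each candidate's mask is perturbed once per iteration
  (accepted only on improvement) with a rate decaying linearly from 0.1 to
  0.01 over the run. The kernel matters: a naive symmetric per-bit flip has
  expected size drift `rate·(Nt − 2Ns)`, which pulls every mask toward half
  the genes and overwhelms the sparsity term (the per-gene sparsity gain,
  `(1−α)/Nt`, is far below the accuracy quantum of one CV instance). The
  default `balanced` mode therefore mixes, with a fair coin, (i) a
  size-unbiased exchange flip (drop probability `rate` on selected genes,
  add probability `rate·Ns/(Nt−Ns)` on unselected ones) and (ii) a
  pure-drop backward-elimination step; the symmetric variant is kept behind
  `mutation_mode="symmetric"`. Mutation applies to every candidate, not
  only to freshly accepted ones — with greedy replacement acceptances
  become rare after convergence and a mutation gated on acceptance stops
  searching exactly when local search is most useful.
- **Oracle.** For ≤ 20 genes, every non-empty subset is enumerated; ties
  resolve to the lexicographically smallest mask so the optimum is unique
  and reproducible.
- **Baseline.** `random_search` scores uniformly random subsets (each gene
  with probability 1/2) under the same fold indices and an equal number of
  distinct-mask evaluations, making comparisons budget-fair.

## Classifiers

Five adapters with a uniform contract: CART decision tree, random forest
(100 trees), k-NN (k=5), RBF-SVM (C=1, probability scores enabled for AUC),
and a backpropagation MLP (one hidden layer of 32 units, early stopping
with a 20% validation split and patience of 25 epochs — on the ≤ 250-sample
datasets this package targets, the stock patience halts before the loss
moves). Distance- and margin-based learners (k-NN, SVM, MLP) see
train-fitted standardized features; tree learners see raw values. No
printed hyperparameter settings exist for the study this follows, so these
are ordinary defaults, all overridable through `ClassifierSpec`.

## Evaluation

- **Loss** is 0-1 throughout (identical to squared error on 0/1-encoded
  binary labels), consistent with the label-based metrics.
- **0.632+ bootstrap** (default B=50): `err_B` averages, per instance, the
  losses of models whose resample excluded it; instances contained in every
  resample are excluded from that average and counted. Γ scores the
  full-data model over all (target, prediction) pairs. `R` is clipped to
  [0,1] — without clipping the weight can leave [0.632, 1] — and `Γ = err`
  defines `R = 0`. Degenerate single-class resamples are skipped.
- **Multiclass metrics** are macro averages over one-vs-rest, and AUC is
  macro one-vs-rest on class scores; undefined ratios are reported as 0
  with a flag rather than dropped.
- **Paired tests**: paired t-test, Wilcoxon signed-rank (exact for n ≤ 25),
  Cohen's d on the paired differences, and the t-based 95% CI of the mean
  difference. All-zero differences report Wilcoxon p=1 with a flag;
  zero-variance nonzero differences flag d as undefined.

## Synthetic data

The generator plants, on a standard-normal log-intensity scale: informative
genes (class-conditional normals with class means spaced `effect_size` SDs
apart, ladder permuted per gene so genes discriminate different class
orderings), redundant genes (scaled copies of random informative parents
with the independent noise scaled so the *overall* parent correlation
equals `redundancy_rho` despite the between-class variance), and pure-noise
genes. Column order is shuffled so selection cannot exploit layout; the
planted set is recorded in `truth_mask`. Defaults: 10 informative, 20
redundant, effect 2.0, ρ = 0.9 — well-separated but overlapping classes,
the regime where wrapper selection visibly pays off. Shape presets mirror
the eight public cancer microarray benchmarks (2,000–24,481 genes, 60–253
instances, 2–4 classes).

What the generator does **not** emulate: batch effects, missing values,
probe-level artifacts, heavy-tailed raw intensities, gene–gene networks
beyond pairwise parent correlation, and class-dependent covariance. Passing
recovery tests therefore demonstrates the machinery works when signal is
present and identifiable, not that any particular biological dataset has
recoverable structure.

## Problem sizes in the test suite

The end-to-end checks run at desk scale as a deliberate design choice: the
oracle-equivalence instance uses 10 genes × 60 instances (1,023 subsets
enumerated; wrapper at pop 30 × 100 iterations over 5 seeds), the recovery
instance 500 genes × 100 instances (pop 30 × 100, 5 seeds), and the
dominance comparison reuses that instance over 10 paired seeds at a reduced
pop 20 × 60 budget — dominance is a relative claim and holds at the smaller
budget, which keeps the comparison honest (the random baseline receives the
same evaluation count) while roughly halving its cost.

## Known limitations

- The five update rules contain an origin contraction (`Pos_best·γ`), a
  common trait of this optimizer family; objectives whose optimum is far
  from the box center rely more heavily on the Lévy and mutation terms.
- Fitness caching keys on the binarized mask, so the "evaluation count" is
  distinct masks scored; budget-fair comparisons use that count.
- The 0.632+ estimator refits the classifier B times; with slow learners
  (MLP, RF at scale) evaluation, not selection, can dominate runtime.
- Inner-CV fold counts silently shrink (with a warning) when a class is
  smaller than the requested fold count; classes of size 1 are rejected.
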