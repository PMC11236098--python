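# Methods

## Model overview

`scpruner` treats supervised cell-type annotation as an ensemble-pruning
problem. A labeled reference count matrix **C** (n cells × m genes, k cell
types) is quality-filtered, normalized and used to train l = 30
*identification paths*, each coupling one of five marker-gene ranking
statistics to one of six classifiers. A bi-objective search then selects a
sub-network of paths that jointly minimizes the consensus error on the
reference and the number of retained paths; that sub-network annotates
query cells by majority vote with confidence-based rejection.

## Preprocessing

Genes detected in fewer than `min_cells_per_gene` cells (default 3) are
removed first, then cells detecting fewer than `min_genes_per_cell` genes
(default 200) — conventional droplet-data QC; the thresholds are
configurable because "exceptionally sparse" is dataset-dependent.
Normalization is median-ratio scaling with a log transform:
`M[i,j] = ln(1 + C[i,j] / L_i · median(L))` where `L_i` is cell i's total
count. Reference and query are normalized independently, each against its
own median library size, and brought onto the intersection of their gene
namespaces in reference order. Natural log with pseudocount 1 is used
throughout.

## Gene selectors

All selectors emit per-gene ranking scores; no p-values are computed and no
multiple-testing correction is applied, because the scores are only ever
compared within one selector.

- **Variance ratio** (one-vs-rest): `W = s²_class / s²_rest` with sample
  variances floored at ε = 1e-8; score `|(n−1)·ln W| / df`, df = k − 1.
- **Kolmogorov–Smirnov** (one-vs-rest): the two-sample KS statistic
  `max |F_class − F_rest|` over the pooled sample (scipy's implementation).
- **χ² detection test** (one-vs-rest): expression is binarized at
  `detect_threshold` (default 0, i.e. detected vs not); the score is
  `Σ (O − E)² / E` over the 2×2 {class, rest} × {detected, not} table, no
  continuity correction; zero-margin genes score 0.
- **Bimodality index** (one-vs-rest):
  `|mean_x − mean_y| / (p_x·s_x + p_y·s_y + ε)` with p the cell-fraction
  weights — the proportion-weighted pooled spread is the only
  dimensionally coherent denominator, and it makes the score
  scale-invariant.
- **ANOVA F** (multi-class): `F = (SSB/(k−1)) / (SSW/(n−k))`, SSW floored
  at ε so perfectly separated genes receive a large finite score.

Each path keeps the top `budget` genes per class (default 300) and takes
the union across classes (top overall for the F statistic), ties breaking
toward the lower gene index; a union smaller than two genes falls back to
the top two genes overall. Whether selection should be per-class or global
is genuinely open; per-class-union was chosen so minority cell types are
guaranteed representation in every path's feature set.

## Classifiers

scikit-learn estimators behind a uniform contract (fit / predict /
predict_proba, probabilities summing to 1 per cell): multinomial naive
Bayes (α = 1), linear SVM (one-vs-rest, C = 1), RBF SVM (one-vs-one votes,
γ = 'scale'), KNN (K = 5 — K is deliberately named apart from k, the number
of cell types), random forest (100 trees, probability averaging), and an
MLP (one hidden layer of 100 rectified units, softmax output, ≤ 200
epochs; non-converged fits are kept as best-effort). The margin classifiers
expose probabilities as a softmax over their decision values rather than
Platt scaling: rejection only needs a confidence that is monotone in the
decision score, and internal cross-validation would triple training cost.
All stochastic fits take a path-specific seed derived as
`master_seed + path_index`, making training bit-reproducible.

## Pareto pruning

A sub-network is a binary mask s over the 30 paths (selector-major order).
Objectives: f₁(s) = number of reference cells whose consensus label
(per-cell mode over the selected paths; ties broken by the largest summed
probability, then the lexicographically smallest label) differs from the
true label, and f₂(s) = |s|. The empty mask scores the sentinel f₁ = n + 1.

The search keeps an archive ("population") that is an antichain under weak
domination (f₁ ≤ and f₂ ≤): a candidate weakly dominated by a member is
discarded, otherwise it enters and evicts everything it weakly dominates.
Each of `max_iter` iterations (default 2·l² = 1800) mutates a uniformly
chosen member by independent bit flips with probability 1/q (q defaults to
l, one expected flip), offers the mutant to the archive, and runs a greedy
Hamming-1 local search from it: among the single-bit flips whose index has
not yet been used this walk, move to the one with minimal f₁ (ties: smaller
f₂, then lowest flipped index), retiring that index; the walk ends after at
most l steps and every visited point is offered to the archive. Restricting
the neighborhood to unused indices is what makes the stop condition
reachable. The final answer is the archive member with minimal f₁ (ties:
minimal f₂, then lexicographically smallest mask). Objective evaluations
are memoized per run — masks recur heavily — which is what makes 3000
iterations on small instances take seconds.

f₁ is evaluated on resubstitution (training-set) predictions by default.
An `out_of_fold` flag replaces the cached predictions with 5-fold
cross-fitted ones to penalize overfit paths; it is off by default, but see
the limitation below.

## Annotation and rejection

Query cells are labeled by the same consensus rule applied to the pruned
sub-network's query predictions. Confidence is the mean probability the
selected paths assign to the consensus label — the simplest monotone
statistic consistent with a per-cell threshold — and cells with confidence
strictly below τ are relabeled `unknown`. τ defaults to 0.65, the
empirically optimal rejection threshold for this family of annotators;
`threshold_sweep` recomputes the metrics across a τ grid (the number of
rejections is non-decreasing in τ by construction). `unknown` is a reserved
label and rejected in input class lists at load time. Metrics are accuracy,
macro-F1 (unweighted mean of per-class F1 over the observed label union)
and the multiclass Matthews correlation coefficient from the full confusion
matrix.

## Synthetic data

The simulator draws per-cell types from stated proportions
(largest-remainder allocation, so fractions are exact), gives each type a
disjoint block of `markers_per_type` = 25 marker genes elevated
`marker_fold_change` = 8-fold over a shared baseline, and samples counts
from a gamma–Poisson (negative binomial) model: mean `nb_mean` = 0.5 per
gene (≈ 60% zeros, droplet-scale sparsity), shared dispersion 0.25, and
log-normal library-size factors with σ = 0.3. Types listed in
`novel_types` appear only in the query. Everything is a deterministic
function of the seed.

What it emulates: overdispersed counts, library-size variation, marker
structure with known ground truth, and open-set queries. What it does not:
batch effects, doublets, ambient RNA, correlated gene programs, or cell
types related by continua. Passing tests on these fixtures therefore
demonstrate the machinery (selection, training, pruning, consensus,
rejection) under known truth — not performance on real tissue atlases.

## Problem sizes used in tests and the acceptance script

Unit tests run on matrices of tens to hundreds of cells. The end-to-end
checks use the canonical closed-set fixture (2000 reference cells × 1000
genes, five equal types, fold change 8) and an open-set fixture (1500 × 800,
four reference types plus one query-only type at 20% of 1000 query cells),
with a per-class gene budget of 50 and 150 pruning iterations — on fixtures
this separable, larger budgets and longer searches change nothing (verified
for budget 300), and these sizes keep a full pipeline run under a minute.

## Numerical choices

- ε = 1e-8 floors every variance or denominator that can vanish.
- Sample statistics use ddof = 1; one-vs-rest selectors therefore require
  at least two cells per class.
- All ties anywhere (vote modes, local-search moves, final mask selection,
  gene ranking) break deterministically as documented above, so identical
  inputs, configuration and seed reproduce every output byte for byte.

## Known limitations

- **Perfectly separable references collapse the ensemble.** Flexible
  classifiers (forest, MLP) reach zero resubstitution error on almost any
  reference, and on cleanly separable data *every* path does — including
  under out-of-fold evaluation. Any zero-error singleton then weakly
  dominates every larger zero-error sub-network, so the pruned "ensemble"
  is a single path, and the deterministic lowest-index local-search
  tie-break makes it specifically the highest-index path (ANOVA-F × MLP).
  Open-set rejection quality then rests entirely on that one classifier's
  softmax calibration on out-of-distribution cells, which is mediocre: on
  the open-set fixture roughly a quarter of novel-type cells exceed
  τ = 0.65 and evade rejection (unknown-recall ≈ 0.72–0.75, with zero
  false rejection of known cells). On noisy references, where singleton
  errors are nonzero, the minimal-f₁ front member is a genuine multi-path
  consensus and confidences are better behaved.
- The consensus-error objective on resubstitution predictions rewards
  memorization; the out-of-fold mode mitigates this only when the data are
  hard enough for cross-fitted errors to differ from zero.
- Margin-classifier "probabilities" are softmaxed decision values: monotone
  confidences, not calibrated posteriors.
- Forest and MLP fits are seeded but sensitive to training-row order, so
  cell-order invariance of the cached predictions holds exactly only for
  the order-insensitive classifier kinds.
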