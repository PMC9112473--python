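# Methods

`pathdriver` nominates biological pathways — and the protein-interaction
modules they induce — that drive sensitivity or resistance to a drug,
starting from a gene × sample expression matrix and a per-sample
drug-response AUC. This note documents the statistical model behind each
stage, the defaults and why they were chosen, what the synthetic benchmark
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Labeling and normalization

Samples are split into *sensitive* and *resistant* classes from the AUC
(higher AUC = more resistant), either at a fixed cutoff (sensitive iff
`auc < cutoff`; a sample exactly at the cutoff is resistant, since the
cutoff is chosen to sit between the modes of the AUC distribution and the
upper mode is the resistant one) or at a nearest-rank percentile of the
observed AUCs (sensitive iff `auc <=` that percentile). All percentile
computations in the package use the nearest-rank definition — the value at
sorted rank `ceil(q/100 * n)` — because it is exact and free of
interpolation dialects.

Expression is z-normalized per gene (mean 0, sd 1 with ddof 1) across the
labeled samples only; constant genes are dropped. Restricting the
normalization to labeled samples keeps the z-scores aligned with the
population the discriminative statistics are computed on.

## Pathway activity and the greedy gene search

For a pathway p with selected genes S of size k, the per-sample activity is

    a_pj = sum_{i in S} z_ij / sqrt(k)

and the pathway's score is the two-sample t statistic of `a_p` between
resistant and sensitive samples (oriented resistant − sensitive). Welch's
unequal-variance t is the default everywhere (a pooled-variance variant is
available via `t_variant="pooled"`).

S is found by a prefix search: member genes are ranked by their individual
t-scores and every prefix of the ranking is scored; k is the smallest
prefix length attaining the maximal |t|. The classical heuristic ranks
ascending when the mean member t-score is negative and descending
otherwise, and searches only that one ordering. We evaluate the prefixes
of *both* orderings and keep the better one (ties prefer the mean-t
direction). This is a strict superset of the heuristic that coincides with
it whenever the strongest gene agrees in sign with the pathway's mean
shift — the signal case — and it guarantees by construction that the
pathway score dominates every single member gene's |t|, since each gene is
the length-1 prefix of one of the two orderings. Ties between genes with
equal t are broken lexicographically by gene id so reruns are identical.

Two pathway filters are provided. The percentile filter retains pathways
whose score falls in the bottom `tail_pct` nearest-rank percentile or the
mirrored top tail (implemented as the same rule on the negated scores, so
the retained set is invariant under score negation and both tails keep
`ceil(tail_pct% * n)` pathways); `tail_pct=10` therefore retains ~20% of
pathways. The permutation filter shuffles the sample labels, re-runs the
entire greedy search per permutation, and reports the add-one empirical
p-value `p = (1 + #{|t*| >= |t|}) / (1 + n_perm)` (so `p >= 1/(1+n_perm)`
and the p-values are valid under the null); defaults `n_perm=1000`,
`alpha=0.05`.

## Interaction modules via topological overlap

Genes of the retained pathways are pooled and an adjacency matrix is built
from protein–protein interaction edges with combined score ≥ 0.4 (the
conventional medium-confidence STRING cutoff; raw STRING files carry
0–1000 integers, which the loader rescales by 1/1000). Surviving edges
keep their score as the edge weight — binarization is available as a flag
but weighted adjacency is the more general default. The topological
overlap between genes i ≠ j is

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = sum_u a_iu a_uj,   k_i = sum_u a_iu,

with `omega_ii = 1`; a pair of isolated genes gets omega 0 through the
`+1` in the denominator. Genes are partitioned by agglomerative clustering
of the dissimilarity `1 − omega` (average linkage by default, the
convention for TOM-based clustering; complete linkage available), cut
either at a fixed height (default 0.95 — TOM dissimilarities between
unrelated genes sit at 1.0, so the cut separates anything with appreciable
shared neighborhood) or into a requested number of clusters. Clusters
smaller than `min_module_size` (default 5) are pooled into module 0
together with interaction-less genes; module 0 is still forwarded to
feature selection as a single pooled group, so no gene is silently
discarded. Modules are relabeled 1..M by decreasing size with ties broken
by smallest member gene id.

## Per-module shadow-feature selection

Within each module, informative genes are found with the shadow-feature
(Boruta) scheme: each run appends an independently shuffled copy of every
active feature, fits a random-forest classifier, and credits a *hit* to
each real feature whose importance exceeds the maximum shadow importance.
After each run a one-sided binomial test (hit probability 0.5) is applied
to every undecided feature, Bonferroni-corrected across the features still
undecided: significantly many hits → Confirmed, significantly few →
Rejected (rejected features leave the model; confirmed features stay in).
Features undecided after `max_runs` (default 100) remain Tentative, and
only Confirmed genes advance — Tentative genes are deliberately not
promoted. A single-gene module cannot support the shadow comparison and
its gene is returned Tentative with a warning.

Defaults: `p_value = 0.01`, impurity (mean-decrease-in-impurity)
importance, 100 trees. The forest is deliberately moderate in size: the
hit indicator only asks whether a feature's importance beats the best of
~p shadows, a coarse comparison whose error is averaged over the binomial
accumulation across runs, so enlarging the forest well beyond 100 trees
sharpens per-run importances that the run-level test already smooths out,
at linear cost in a loop that may execute up to `max_runs` times per
module. Tree count, run cap and the test level are all exposed
(`n_trees`, `max_runs`, `p_value`), as is a permutation-importance option.

## SVM-RFE and module importance

Confirmed genes from all modules are pooled into one linear-SVM (C = 1)
recursive-feature-elimination ranking: at each iteration the SVM is
refitted and the feature with the smallest squared weight is removed; the
rank of a feature is `n_features − removal_iteration + 1`, so the last
survivor has rank 1. Ranks are computed within each fold of a stratified
10-fold cross-validation (or leave-one-out) and averaged; features are
standardized with the training split's mean/sd only, so no information
leaks from held-out samples (constant training columns get sd 1, hence
weight ~0 and early removal). The error curve reports, for every feature
count m, the held-out misclassification of the SVM refit on that fold's
top-m features, pooled over folds, next to the no-information rate error
`1 − max class frequency`.

Module importance is the minimum average rank over the module's Confirmed
genes — a module is as good as its best marker. Modules are ordered by
increasing minimum rank, ties broken by more Confirmed genes, then by
smaller module id; modules with no Confirmed gene are excluded and logged.

## Enrichment and comparators

Top modules are annotated by the one-sided hypergeometric
over-representation test of the module's genes against a gene-set
collection, within a universe of expression-matrix genes that appear in at
least one term; p-values are Holm step-down corrected across terms. Holm
is the only correction offered, matching the convention of the analyses
this package mirrors. The comparators are a per-gene Welch t-test screen
(Holm-significant at 0.1), drug ranking by mean absolute deviation of the
AUC, and drug–drug Pearson correlation of AUC over shared samples.

## Synthetic benchmark

`simulate.generate_dataset` draws datasets with the structure the pipeline
assumes. Genes are partitioned into blocks; each block is simultaneously a
pathway (gene set), a dense stochastic-block-model community in the
interaction network (within-block edge probability 0.3 with scores uniform
on [0.4, 1.0]; between-block probability 0.01 with scores below the 0.4
threshold), and a co-expression group (a shared per-sample factor with
sd 0.5 on top of unit noise). Driver-pathway genes additionally shift by
`effect_delta` (default 1.5 within-gene sd) in resistant samples, and the
AUC is `6 + 2·resistant + N(0, 0.5)`, so a cutoff of 7 recovers the
planted classes up to ~2% label noise. The default condition is 100
samples, 1000 genes, 20 pathways of 15–25 genes, one 20-gene driver.
Decoy pathways are disjoint from driver genes by default so recovery is
unambiguous; enrichment collections contain one term per planted block
plus random decoy terms.

What the generator does *not* emulate: microarray-specific noise (probe
effects, batch structure), dose–response curve fitting (AUC is generated
directly), overlapping pathways, hub-dominated degree distributions, or
identifier mismatch between data sources. Passing the recovery tests
therefore demonstrates that the machinery identifies planted structure
under idealized conditions, not that it will rank the right pathway on any
real dataset.

## Problem sizes, determinism and degenerate inputs

The recovery and calibration studies run at the default synthetic
condition with 5–20 generator seeds and permutation filters at 199–1000
permutations — sizes chosen so a full study completes in minutes on a
single core while leaving the statistical conclusions stable across seeds.
One global seed fans out to per-stage substreams (permutation filter,
per-module Boruta, CV folds) via `numpy` seed sequences, so identical
config + seed reproduces every output table byte for byte while stages
remain independently re-runnable. Degenerate inputs are handled
explicitly: pathways with no gene in the matrix are skipped and logged;
constant genes are dropped before z-scoring; genes with zero within-class
variance are excluded from t-scores; labelings that empty a class, folds
that lose a class, and single-gene modules raise or degrade with explicit
warnings rather than propagating NaNs.

## Known limitations

- The greedy prefix search is a heuristic over orderings; it does not
  search all subsets of a pathway (by design — the prefix family is the
  method's definition).
- Module construction depends on the interaction network's coverage:
  genes absent from the network land in module 0 and compete there rather
  than in a specific module.
- The pipeline's binary labeling discards within-class AUC variation; a
  regression mode is out of scope.
- Holm correction across modules' enrichment tables is per-module, not
  global across all modules tested.
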