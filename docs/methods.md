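# Methods

## Problem and model

A differential-expression experiment ends with a gene list, and the usual
next step — over-representation analysis against Gene Ontology (GO) or
transcription-factor (TF) target annotations — treats that list as one
homogeneous block. Real DE lists mix several biological programmes, each with
its own regulators, and programme-level signal is easily drowned. This
package clusters the list into annotation-homogeneous subgroups first and
then asks the statistically meaningful question across annotation systems:
which TFs are over-represented in a cluster that was formed using only GO
terms, and vice versa. Because the clustering variable and the tested
variable are then independent, those p-values — *independent enrichment
analysis* (IEA) — retain their usual inferential meaning, whereas testing a
cluster with the same annotation system that formed it (*dependent*
enrichment, DEA) is circular and is reported only as a descriptive
enrichment score.

### Clustering

Gene-annotation associations for one system form a binary incidence matrix
`V` (genes x annotations, cell 1 = associated). For each k in `1..k_max` the
matrix is factorized as `V ≈ W H` with non-negative `W` (genes x k) and `H`
(k x annotations) under the generalized Kullback-Leibler divergence

    D(V || WH) = Σ_ij [ V_ij log(V_ij/(WH)_ij) − V_ij + (WH)_ij ],

minimized by Lee-Seung multiplicative updates, which are monotone in D. KL
is the natural divergence for sparse counts, and factor models let a cluster
be supported by a small subset of columns — both properties of annotation
data. Each gene is hard-assigned to `argmax_k W[g, k]` (ties to the lowest
index). The multiplicative updates are implemented in the package because
the restart protocol, the initialization and the objective trace are part of
the method's contract; scikit-learn's independent MU/KL solver is used as a
cross-check in the test suite.

Numerical choices: initial `W`, `H` entries uniform on (0, 1] scaled so the
product matches the data mean; `restarts = 10` random initializations with
seeds `seed, seed+1, ...`, keeping the lowest final divergence; stop at
`max_iter = 500` or relative objective decrease `< tol = 1e-6`; a tiny-float
epsilon guards divisions. Empty clusters are legal outcomes (re-running
until non-empty would break determinism); they fit no parameters and are
skipped downstream. Levels are *independent* solutions — level k+1 is not a
split of level k — which is what makes the cross-level tree informative.

### Cluster-number selection (AIC and dAIC)

A partition is scored by a per-cluster Bernoulli model: cluster c carries
annotation j with ML rate θ(c,j) = (carriers of j in c)/|c|; the
log-likelihood sums `ln θ` / `ln(1−θ)` cell-wise with `0·ln 0 = 0`, and

    AIC = 2·p − 2·lnL,   p = (nonempty clusters) × (scored columns),

smaller better. Most annotation columns are spread at random over any
partition; they dominate p without rewarding structure, biasing plain AIC
toward very few clusters. The dAIC variant therefore first keeps only the
columns whose *per-column* AIC improves on the one-cluster solution in at
least one solution with more than two clusters (`min_k_filter = 3`,
configurable, since "at least two" is an equally plausible policy), then
rescores every level — including k = 1 — on that fixed column set. The best
AIC and best dAIC levels are both marked on the tree; ties go to smaller k.

### Tree construction

The solutions for k = 1..k_max are stacked into a non-nested tree: every
nonempty cluster at level k+1 receives exactly one edge to the level-k
cluster maximizing the phi coefficient (Pearson correlation of the binary
membership indicators over the clustered genes; a constant indicator yields
phi = 0 by convention, and ties go to the lower parent index). Per-child
best-match is the construction that guarantees tree-like fan-in; clusters
that persist across levels are visible as chains of phi ≈ 1 edges.

### Enrichment statistics

All tests are one-sided Fisher exact tests (hypergeometric upper tails):
`a` carriers among `n` cluster genes against `K` carriers among the `N` list
genes, or list vs genome for the root level. The background `N` is the full
input gene list — genes without any annotation in the tested system count as
non-carriers, which is how the published worked-example tables are
constructed. Only annotations with at least one carrier in the cluster are
tested; records with p = 1 are kept so that correction families are
reproducible. BH step-up FDR correction is applied per (level, mode) family
by default (per-cluster families are available by configuration; the choice
of family is a genuinely open design point). Cross-tree *inter-correlation*
applies the same Fisher/BH machinery to the membership-overlap table of
every cluster pair taken from the two trees at their best dAIC levels, over
the universe of genes clustered in both; because the pairs share genes, the
correction is conservative and the values should be read with care.

## Synthetic data

The generator plants a balanced partition of `n_genes` into `k_true`
clusters. Each cluster owns `signal_dims` disjoint annotation columns per
system; a gene hits its own cluster's signal columns with probability `p_in`
and every other column (foreign signal or background) with `p_out`; each
system additionally has `background_dims` pure-background columns. The
second system follows the same partition with probability `coupling`
(decided once per dataset), else a permuted partition with identical sizes —
a clean alternative/null dichotomy for IEA power and type-I measurement.

Defaults, fixed as the package's standard study conditions: `n_genes = 200`,
`k_true = 4`, `signal_dims = 3`, `background_dims = 20`, `p_in = 0.9`,
`p_out = 0.05`, `coupling = 1`. Three signal columns per cluster and ~40%
background columns give sparse matrices (≈ 14% ones) of the order a few
hundred DE genes would produce, while 200 genes keeps a full benchmark sweep
in minutes on one CPU; the filter benchmarks use 500 genes so that noise
columns at rate 0.3 have well-behaved counts. What the generator does *not*
emulate: the GO DAG (no nesting or ancestor closure), overlapping signal
columns, annotation bias toward well-studied genes, and false associations
correlated between systems. Passing benchmarks therefore demonstrate the
machinery's behavior under clean planted structure, not performance on any
real annotation corpus.

## Benchmark definitions and observed behavior

The `evaluation` module recomputes (and `scripts/acceptance.py` reports):

* exact-oracle agreement of the Fisher tail (integer enumeration, all
  tables with N ≤ 60) and of BH (independent step-up, 1000 random vectors);
* worked-example reconstruction: raw Fisher p from each published
  contingency table, which must not exceed the published FDR-corrected
  value;
* recovery: ARI of the k = k_true solution (exact on noiseless blocks;
  mean over 20 datasets at the standard conditions);
* dAIC selection: fraction of 20 datasets with argmin dAIC within ±1 of
  `k_true`, at `k_max = 6`;
* noise filtering: fraction of 30 i.i.d. Bernoulli(0.3) columns over 500
  genes removed by the dAIC filter, scored against clustering solutions fit
  to the planted annotation system of the same genes. This isolates the
  filter's specificity. When the noise columns are instead included in the
  clustered matrix (reported as the `_in_matrix` variant), solutions above
  the true cluster count partly adapt to the noise — best-of-restarts
  minimizes the joint divergence, noise included — and the removed fraction
  drops to roughly 0.4. This adaptation is a known limitation of AIC-style
  filtering with factorizations refit per level, and it grows with
  `k_max − k_true`;
* IEA calibration and power at FDR < 0.1: the mean fraction of IEA calls on
  uncoupled data (clustering at k_true, testing the other system), and the
  fraction of coupled datasets in which every planted cluster's cross-system
  annotation is detected;
* determinism: two pipeline runs with one seed must produce byte-identical
  files (all randomness flows from the single seed; TSV/JSON writers use
  fixed orderings and formats).

## Known limitations

* Annotation ancestry is not expanded; inputs are used as given, so GO
  inputs should be pre-propagated if closure semantics are wanted.
* Genes unannotated in a system are excluded from that system's clustering
  (an all-zero row gives the factorization no signal) and reported; they
  still count as non-carriers in enrichment backgrounds.
* The dAIC filter's specificity degrades when high-rate random columns are
  numerous in the clustered matrix (above).
* Inter-correlation p-values are conservative and mutually dependent.
* Hard argmax assignment discards membership strength; soft or consensus
  clustering is out of scope.
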