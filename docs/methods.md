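# Methods

`mirmodulenet` detects miRNA–mRNA regulatory modules from paired expression
profiles of the same case/control cohort and ranks them by their power to
separate the two classes. The design follows the grouping–scoring–modeling
(G-S-M) pattern: group features by statistical structure (G), score each
group by internal cross-validated classification (S), and build cumulative
classifiers over the top-ranked groups (M), all inside an outer Monte-Carlo
cross-validation (MCCV) loop whose per-iteration rankings are fused by
robust rank aggregation.

## Pipeline

Each MCCV iteration *i* (seed = `master_seed + i`) performs, in order:

1. **Stratified 90/10 split.** Per class, `round(test_fraction · n)` samples
   (at least one) are held out; the test partition is used only in step 7.
2. **Under-sampling (1:2).** All minority-class training samples are kept;
   the majority class is randomly thinned without replacement to at most
   `undersample_ratio × n_minority` (default 2). Applied to the training
   partition only, so test-set prevalence reflects the cohort; e.g. training
   classes of 405/19 reduce to 38/19.
3. **Normalization.** Optional RPM (miRNA counts, `value·10⁶ / library
   size`) and RPKM (mRNA counts, `value·10⁹ / (library size · length_bp)`),
   then per-feature z-scoring with population (n-denominator) standard
   deviation. z-score parameters are *fitted on the training partition* and
   applied to both partitions; a `leaky_zscore` compatibility switch
   restores whole-data fitting for protocols that standardize before
   splitting, at the cost of test-statistic leakage. Features containing
   missing values are removed up front; constant features z-score to zeros.
4. **Differential-expression filter.** Per feature, a two-sided
   Mann–Whitney U test between classes, Benjamini–Hochberg adjustment
   across features, and a fold-change gate
   `|log2((mean_case+ε)/(mean_control+ε))| ≥ min_abs_log2fc` (ε = 1e-9).
   Defaults `alpha = 0.05`, `min_abs_log2fc = 1`. This distribution-free
   filter replaces negative-binomial count models such as edgeR: for count
   data the candidate sets are broadly comparable but not identical, and the
   downstream machinery only needs a candidate list, so the stage is
   pluggable. The fold-change ratio is meaningful for non-negative
   expression units; where a shifted class mean is non-positive (possible
   for already-standardized input) the gate defers to the p-value. The DE
   test runs on the count-normalized scale, before z-scoring.
   **Candidate floor:** if fewer than `min_candidate_mirnas` (10) /
   `min_candidate_mrnas` (20) features pass, the smallest-adjusted-p
   features are carried forward instead, so low-signal iterations still
   reach the grouping stage rather than silently emptying the pipeline.
5. **Mutual-information grouping (G).** Expression profiles are discretized
   by equal-frequency binning (`mi_bins = 3`; ties resolved by stable sort
   order; constant vectors map to one bin) and MI is the plug-in estimate
   `I = H(X)+H(Y)−H(X,Y)` in bits, computed on training samples only.
   Entropy sums run over sorted count vectors, making the estimator exactly
   symmetric; tiny negative values are clipped at 0. Quantile binning is
   invariant to monotone per-feature transforms, so the estimate is the
   same before and after z-scoring. For every candidate miRNA the *seed*
   mRNA is its strongest MI partner (lexicographic tie-break); if even that
   maximum falls below the threshold `tau` (default 0.25 bits) the miRNA
   forms no module. Members are then added in exactly one hop.
   Three expansion criteria exist:
   * `center` (default): every mRNA with `I(gene, center miRNA) ≥ tau`.
   * `seed`: every mRNA with `I(gene, seed mRNA) ≥ tau`.
   * `strict`: both conditions.
   The default reads module membership off the miRNA–mRNA MI matrix itself.
   This choice is empirical as well as structural: in co-regulated blocks
   the miRNA→target coupling is direct while target–target coupling is the
   *product* of two regulation edges, hence substantially weaker (for
   jointly Gaussian profiles with regulation correlation ρ, co-targets
   correlate at ρ²; at ρ = 0.7 and tertile binning that is ≈ 0.16 bits
   versus ≈ 0.29 bits for the direct edge). Seed-based expansion therefore
   recovers almost none of a planted block at the default threshold, while
   center-based expansion recovers most of it; both remain available.
6. **Group scoring (S).** Each module's member mRNAs form a samples ×
   members sub-matrix of the training data. A seeded random forest is
   evaluated by stratified k-fold CV (`inner_folds = 5`, reduced with a
   warning when the minority class is smaller than k, minimum 2); pooled
   out-of-fold case-class probabilities yield accuracy, sensitivity (case
   recall), specificity (control recall), precision, F-measure, Cohen's
   kappa and AUC. Modules are ranked AUC-first (accuracy, then center ID as
   tie-breaks); `rank_by="accuracy"` swaps the first two keys for
   compatibility with scoring tables sorted by accuracy.
7. **Cumulative modeling (M).** For f = 1..`top_f` (default 10), a random
   forest is trained on the training sub-matrix of the *union* of the top-f
   modules' members and evaluated on the held-out test partition. Gene
   counts are therefore non-decreasing in f.

Iterations producing zero modules are recorded and skipped; if more than
half are skipped the run raises `TooManySkippedError` carrying the partial
result (typical causes: no class signal, or `tau` above every observed MI).

**Aggregation.** Per-iteration module rankings (center miRNA IDs, best
first) are fused by the beta/binomial order-statistic method: each
element's normalized ranks r(1) ≤ … ≤ r(L) across L lists (absent ⇒ worst
rank 1.0; normalization by the universe size) give
`rho = min_k P(Bin(L, r(k)) ≥ k)`, evaluated through the regularized
incomplete beta function (stable to L ~ 10⁴), and
`corrected_p = min(1, rho · |universe|)`. The universe is every miRNA that
*entered module construction* in any iteration, not only those that formed
modules: ranks must be normalized against the candidate pool, otherwise a
handful of consistently recovered modules would occupy all rank positions
and even a module ranked first in every iteration could not reach a small
normalized rank. The Bonferroni factor `|universe|` is the number of
elements tested; the original R implementation of this score corrects by
the number of order statistics (the list length) instead, which is less
conservative whenever the universe outnumbers the lists. Downstream
significance uses `corrected_p < 0.05`.

## Random forest

`sklearn.ensemble.RandomForestClassifier`, 50 trees (`n_trees` in the
config), default split criteria, seeded per iteration/fold, single-threaded.
Fifty trees leave module rankings and test AUC indistinguishable from
larger forests on sub-matrices of tens of features, and fit time is linear
in tree count. Class predictions are derived from averaged case-class
probability > 0.5, which coincides with majority vote for two classes.

## Synthetic data generator

`synthetic.generate` emulates the structure the pipeline targets:

* **Drivers:** `n_driver_mirnas = 5` miRNA profiles, Gaussian with the case
  mean shifted by `effect_size = 2.0` standard deviations.
* **Targets:** `targets_per_driver = 10` mRNAs per driver,
  `-ρ·(driver standardized by its population moments) + √(1-ρ²)·noise`
  with `regulation_strength ρ = 0.7`, so the population driver–target
  correlation is exactly −ρ and the class shift propagates into targets
  through the driver. Negative coupling mirrors miRNA repression of its
  targets.
* **Background:** 95 noise miRNAs and 500 noise mRNAs, i.i.d. Gaussian,
  class-independent.
* **Cohort:** 66 cases / 33 controls, exercising the 1:2 under-sampling
  path; an optional count-scale transform (`round(2^(x+8))`) produces
  pseudo-counts for the RPM/RPKM paths.

What the generator does *not* emulate: count over-dispersion, library-size
variation, batch effects, correlated noise between unrelated genes, many-
to-many miRNA–target topologies, and any real regulatory sequence
structure. Passing tests therefore demonstrate that the machinery recovers
the planted statistical structure, not that it resolves real regulatory
biology.

**An intrinsic ceiling worth knowing about.** Because the class signal
reaches every target only through its driver's profile z, any classifier
built from a *single* module — however many member genes it has — is capped
at AUC = Φ(effect_size/√2) ≈ 0.92 at the default effect size: the module's
genes are conditionally independent of the class given z. Unions of two or
more modules span independent drivers and push past this cap (measured
mean test AUC rises from ≈ 0.93 at one module to ≈ 1.00 at five). This is
a property of the generative model, not of the pipeline.

## Numerical choices and degenerate inputs

* Equal-frequency bin edges at `round(i·n/bins)`; a constant profile maps
  to a single bin (MI = 0 against anything).
* MI symmetry is bitwise because entropies sum over sorted counts.
* Argmax/tie situations (seed choice, ranking) always break
  lexicographically, so identical inputs give byte-identical outputs.
* Features constant across all samples get DE p = 1 (the rank test is
  undefined there).
* All writers emit 6-decimal fixed-point; readers round-trip at that
  precision.
* Per-iteration seeds are `master_seed + i`; iterations are independent
  given their seeds and may run in any order.

## Tunable parameters

| name | default | meaning |
|---|---|---|
| `iterations` | 100 | MCCV repetitions |
| `test_fraction` | 0.10 | held-out fraction per class |
| `undersample_ratio` | 2.0 | majority cap as multiple of minority |
| `mi_threshold` | 0.25 | MI threshold tau, bits |
| `mi_bins` | 3 | quantile bins for discretization |
| `top_f` | 10 | cumulative model depth |
| `inner_folds` | 5 | scoring CV folds |
| `n_trees` | 50 | random-forest size |
| `de_alpha` | 0.05 | BH-adjusted p threshold |
| `de_min_abs_log2fc` | 1.0 | fold-change gate |
| `min_candidate_mirnas/mrnas` | 10 / 20 | DE candidate floor |
| `expansion` | center | module expansion criterion |
| `rank_by` | auc | module ranking metric |

The MI threshold is in bits and interacts with `mi_bins` (MI ≤ log2(bins));
the 0.25 default sits well above the small-sample bias of the plug-in
estimator at tertile binning (≈ (bins−1)²/(2·n·ln 2) ≈ 0.03 bits at n ≈ 90)
and well below typical direct-edge MI at moderate regulation strength.
Raising it from 0.15 to 0.5 monotonically shrinks both module count and
membership.

## Known limitations

* The plug-in MI estimator is biased upward at small n; no permutation
  p-values or k-NN estimators are provided.
* The DE stage is rank-based and will differ from count-model filters on
  strongly over-dispersed data.
* One-hop expansion only; no transitive module growth, no multi-miRNA
  module topologies.
* Aggregation treats per-iteration rankings as exchangeable lists; it does
  not model the correlation between iterations induced by shared samples.
* Scoring and the acceptance batteries use desk-scale problem sizes
  (~100 samples, ~650 features, 20 iterations); defaults for real cohorts
  (100 iterations) are set in `RunConfig`.
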