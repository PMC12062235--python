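# Methods

## The screening model

`bivarscan` ranks genes for case/control classification across several
independent expression cohorts by the performance of *gene pairs* rather
than single genes.  The pipeline is:

1. **Harmonization.** Each cohort is a genes × samples matrix with binary
   labels and a platform tag (`rnaseq` or `microarray`).  Cohorts are
   restricted to their common gene symbols (upper-cased, lexicographically
   ordered).  An optional `log2(x+1)` transform is applied to RNA-Seq
   cohorts only; microarray intensities are treated as already log-scale.
   The default is no transform — expression units are the caller's
   responsibility — but every synthetic-data analysis in this package runs
   on the log scale, where the generator's planted geometry lives.

2. **Filter stage (Relief-F).** Genes are scored in one designated
   *selection cohort* by deterministic full-pass Relief-F: every sample is
   a target once; its k nearest same-class neighbours (hits) and k nearest
   other-class neighbours (misses) are found by Manhattan distance on
   range-scaled features; the weight of a feature accumulates miss diffs
   minus hit diffs, miss terms weighted by the multi-class prior form
   (unit weight in the two-class case), normalized by n·k.  Defaults:
   k = 3, top 500 genes (tests and synthetic analyses use top 50).
   Full-pass rather than sampled iterations makes weights a pure function
   of the data; distance ties break by sample index and weight ties by
   gene symbol, so the ordering is bit-reproducible.

3. **Exhaustive pair screen.** All n(n−1)/2 unordered pairs of the
   selected genes (canonical lexicographic order) are scored in every
   cohort by stratified 5-fold cross-validation of a linear SVM with
   C = 100.  Features are standardized *inside each training fold* and the
   fitted scaling applied to the held-out fold, so no leakage occurs; with
   standardized features the large penalty is numerically stable.  The CV
   fold layout is fixed by a seed; it is the pipeline's only source of
   randomness.

4. **Aggregation (CV_sum).** A (pair, cohort) cell *passes* when its CV
   accuracy strictly exceeds the threshold (default 0.70).  Each passing
   cell credits its score to both member genes; a gene's CV_sum is the sum
   over all its passing cells in all cohorts.  Strict inequality follows
   from "above the threshold"; Σ genes CV_sum = 2 × Σ passing cell scores
   (each cell credits exactly two genes), and lowering the threshold can
   only add passing cells, so CV_sum is non-increasing in the threshold.
   An alternative mode thresholds a pair's cross-cohort mean instead of
   each cell (`mode="pair_sum"`); the per-cell mode is the default.

5. **Pair-level statistics.** Per pair: the aggregate ΣSᵢ of its CV scores
   across cohorts, and the selectivity σ = max(Sᵢ²) − min(Sᵢ²).  Squaring
   before differencing stretches differences among high scores; σ ∈ [0, 1],
   zero iff all squared scores are equal.  Low σ marks pairs that transfer
   across cohorts; high σ marks cohort-specific pairs.

6. **Transfer summary.** Pairs passing in a source cohort are evaluated in
   every other cohort; the mean scores are compared with a two-sided
   Welch t-test on the score vectors.

## CV fold layout: why not sklearn's StratifiedKFold

The permutation null (below) compares a ranking computed under the
observed labels with rankings computed under shuffled labels.  That
comparison is only valid if the observed and shuffled runs draw their CV
fold layouts from the same distribution.  `StratifiedKFold`'s per-fold
class composition depends on where in the sample order the classes sit,
and real label files are typically block-sorted (all controls, then all
cases); measured on pure-noise data this produced a systematic ≈0.04
accuracy gap between sorted-label and shuffled-label runs.  The package
therefore uses its own stratified splitter: each class's member indices,
taken in increasing order, are shuffled with the seed and dealt into
folds.  The per-fold class-count pattern then depends only on the class
sizes, never on the label arrangement, making observed and permuted runs
exchangeable.

## Robustness suite

* **Noise injection.** Each gene receives independent zero-mean Gaussian
  noise with sd = α × sd(gene) (default α = 0.05; constant genes
  untouched), and the filter stage (optionally also the pair screen) is
  rerun.  Agreement is Kendall tau-b on the score vectors over the union
  of the clean and noisy top-n lists, with absent genes scored 0.  Tau on
  scores (not just ranks) weighs both position and magnitude.

* **Threshold sensitivity.** The gene ranking is recomputed at 0.65, 0.70
  and 0.75 and all pairwise tau-b values reported.  If every ranking is
  all-ties (e.g. nothing passes any threshold), tau-b is undefined; the
  conventional value 1 is reported with a degenerate flag.

* **Permutation null.** Per permutation, labels are shuffled independently
  within each cohort (cohorts are separate experiments), the pair tensor
  is re-scored on the *fixed* selected gene list with the same CV seed,
  and all aggregated gene scores are pooled: P permutations × G genes
  null scores (the full-scale arithmetic is 200 × 500 = 100,000).  The
  per-gene empirical p-value is #(pooled null ≥ observed)/N; when no null
  score reaches the observed one the bound "< 1/N" is reported.  The
  count/N convention (not (count+1)/(N+1)) reproduces p = 1/N at exactly
  one exceedance.  Each permutation's shuffle stream is derived from the
  seed and its index, so any single permutation is reproducible alone.

### Calibration caveats

Two properties of this null are easy to mis-read as bugs:

* Under the passing threshold, most null aggregated scores are exactly
  zero, so null-data p-values carry a large atom at p = 1.  That is
  conservative, not a miscalibration; uniformity of the p-values is a
  property of the *un-thresholded* aggregate, where scores are continuous.

* All p-values from one run share a label configuration and a permutation
  pool, so they are strongly correlated: a pooled KS test across genes of
  one run over-rejects in a random direction.  Calibration checks in the
  test suite therefore take one designated gene's p-value from each of
  many independent small studies.

## Seeding

Every stochastic component takes an explicit integer seed.  Components
namespace their streams with a domain tag word (`SeedSequence([seed,
tag])`), so passing the same seed to the generator, the CV layout and the
permutation engine — the natural usage — can never make one component
replay another's random numbers.

## The synthetic multi-cohort generator

The generator emulates a three-cohort hippocampal case/control study:
cohorts of 28 (10 control/18 case) and 35 (15/20) samples with
RNA-Seq-like expression, and 63 (32/31) samples with microarray-like
expression, over 2,000 genes (`paperlike` preset; `tiny` is a 60-gene
miniature for tests).  All genes start from a latent log2-scale Gaussian
with per-gene sd `noise_sd` (default 1.0, a typical log-scale biological
coefficient of variation); platform mapping is distributional only:

* *RNA-Seq*: values are exponentiated, `2^(z + b)` with per-gene baselines
  b ~ U(4, 10), giving the skewed positive RPKM-like scale;
* *microarray*: values are compressed (×0.5) onto log-intensity baselines
  b ~ U(6, 12) with a small additive background proportional to each
  gene's latent spread (factor 0.02, kept small so planted joint geometry
  is attenuated, not erased — a pair's conditional spread can be far
  tighter than its marginal spread).

Planted structure (defaults in parentheses):

* **Univariate-signal genes** (20): case mean shift of
  `univariate_effect` (1.5) latent sd in every cohort — the classical
  DE gene, chosen so a 28-sample cohort detects it reliably.
* **Synergy pairs** (10): each pair is drawn within-class from a bivariate
  Gaussian with correlation ρ = `within_pair_correlation` (0.997) and
  within-class sd `synergy_noise_scale` × noise_sd (0.4 — tightly
  co-regulated genes).  The class centroids are displaced along the
  (+a, −a) direction — the direction the correlation does *not* explain —
  with a sized so the joint Mahalanobis separation equals
  `synergy_effect` (4.0): a linear classifier on the pair separates the
  classes (Bayes accuracy ≈ Φ(2) ≈ 0.98) while each marginal standardized
  shift is only `synergy_effect·√((1−ρ)/2)` ≈ 0.15, below the cap
  `synergy_marginal_cap` (0.3).  Geometries whose implied marginal exceeds
  the cap are rejected as infeasible.  The anti-correlated oblique
  geometry (not XOR) is deliberate: a linear SVM, the screening
  classifier, can discover it.
* **Discovery-cohort shift.** In the first (discovery) cohort only,
  synergy members additionally carry a common-mode case shift of
  `synergy_discovery_shift` (0.8) absolute log2 units.  This reproduces
  the cross-study pattern the screen is designed around: candidate genes
  separate classes by themselves in the discovery cohort — which is what
  makes them findable by a univariate filter such as Relief-F — while in
  the replication cohorts their class signal is purely joint.  A filter
  cannot select genes with no marginal signal anywhere: with thousands of
  features, nearest-neighbour distances are dominated by the null genes
  and Relief-F's conditional (interaction) sensitivity vanishes, so a
  generator that left synergy members globally marginal-null would plant
  signal the pipeline's own filter provably cannot find.  The numbers are
  chosen to keep the two baselines apart: the standardized discovery
  separation is 0.8/0.4 = 2.0 (stronger than the univariate genes' 1.5,
  so Relief ranks them), while the fold change 0.8 stays below the DE
  baseline's |log2FC| ≥ 1 cutoff even allowing for estimation noise
  (se ≈ 0.16 at these cohort sizes) — these are exactly the genes a
  fold-change screen discards and a margin-based learner keeps.
* **Cohort-specific genes** (9): the univariate shift in exactly one
  cohort, round-robin assigned — the non-transferable signal that the
  selectivity statistic and the transfer summary are designed to expose.
* **Null genes** (rest): latent noise only.

What the generator does *not* emulate: count-based sampling noise,
gene–gene correlation outside the planted pairs, batch effects within a
cohort, missing values, or any real gene's expression distribution.
Passing recovery tests on these data therefore demonstrates that the
pipeline's machinery (filter, pair screen, aggregation, null) does what it
claims under its own assumptions — not that the discovered biomarkers of
any real study are correct.

## Univariate DE baseline

A deliberately minimal contrast, not a count-model DE analysis: per-gene
Welch t-test on log2 expression (RNA-Seq values log2(x+1)-transformed
first — the baseline must always receive *raw* expression), BH-adjusted,
flagged when |log2FC| ≥ 1 and adjusted p < 0.05.  On generator defaults
the baseline flags most univariate-signal genes in the discovery cohort
and almost no synergy members (their fold change sits below the cutoff),
so the bivariate ranking's advantage is visible as a planted property.

## Problem sizes in tests and the acceptance script

The packaged analyses run reduced designs chosen to exercise every stage
at desk scale: top-50 selection over the 2,000-gene preset (1,225 pairs ×
3 cohorts), 20-permutation nulls over 50 genes (1,000 pooled scores, the
same arithmetic as 200 × 500 = 100,000 at full scale), recovery averaged
over 5 generator seeds, and calibration over 40 small independent studies.
Full-scale runs are a matter of the same calls with larger parameters.

## Known limitations

* The pair screen is O(n²) SVM fits per cohort; at the full 500-gene,
  3-cohort, 200-permutation scale that is ~7.5 × 10⁷ fits — parallel
  across pairs in principle (the tensor contract is order-independent),
  but this implementation evaluates serially.
* Relief-F is run in one selection cohort; the package deliberately does
  not define a merge rule for selections repeated per cohort (the
  selection cohort is a parameter).
* The empirical p-values are not multiplicity-adjusted (by design — the
  pooled-null convention is the published one), and the permutation count
  bounds the smallest attainable p at 1/N.
* Tau-b after noise injection is computed on score vectors over the
  union of top lists with absent genes scored 0; other conventions (rank
  overlap, weighted tau) would give different numbers.
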