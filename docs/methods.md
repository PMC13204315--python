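# Methods

This note documents the models and procedures implemented in `gliosig`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Synthetic cohorts

`syndata.generate_cohort` draws a genes × samples matrix with:

* **Classes.** Exactly `round(positive_fraction · n_samples)` positive
  (GBM-like) samples, positions shuffled by the seeded generator. Counts are
  deterministic so stratified-split arithmetic is exact in tests. Defaults
  `n_samples = 268`, `positive_fraction = 159/268` mirror a two-class glioma
  cohort with a 1.46:1 imbalance after a 70/30 split (train 187 = 111 + 76).
* **Co-expression modules.** Module genes are `x = √ρ·f + √(1−ρ)·ε` with a
  per-module latent factor `f ~ N(0,1)` shared across the module and
  independent noise `ε`; pairwise within-module correlation is ρ in
  expectation (default ρ = 0.8, recovered within 3/√n in tests). The
  latent-factor construction was chosen over a Cholesky factor of an explicit
  correlation matrix because it hits the target correlation in expectation at
  O(genes × samples) cost.
* **Informative genes.** `n_informative` genes receive a `+effect_size` mean
  shift (in within-class SD units) in the positive class. Informative genes
  occupy the leading gene slots and therefore fill the leading co-expression
  modules when modules exist (default: 10 informative genes = two 5-gene
  modules). This layout is deliberate: the hypergraph stage promotes genes by
  co-expression, so planted disease genes must be mutually correlated above
  the hyperedge threshold to be discoverable on their own merit. With ρ = 0.8
  and a shared 1.5-SD class shift, the pooled informative–informative
  correlation is (0.8 + e²p(1−p)) / (1 + e²p(1−p)) ≈ 0.87 > τ = 0.75, and the
  joint discrimination of the panel lands near AUROC 0.9–0.95 — the regime a
  moderately separable grading problem occupies — rather than at ceiling.
* **Platforms.** `microarray_like` leaves approximately normal intensities;
  `rnaseq_like` exponentiates an intensity-like latent and applies
  log2(x + 1), giving a positive, log-scaled matrix with the same ordering
  structure. No probe-level artefacts, GC bias or count overdispersion are
  emulated; passing cross-platform tests therefore demonstrates
  scale-invariance of the normalisation protocols, not robustness to
  platform-specific noise processes.
* **Covariates.** Binary IDH-like (default 5% "mutant" among positives, 80%
  among negatives) and codeletion-like markers with class-conditional
  frequencies; used by subgroup and survival analyses.
* **Batch confounding.** With `batch_confound=True`, batch identity equals the
  class label and a `batch_offset` (default 2 SD) is added to a random 10% of
  genes in one batch. With `n_informative = 0` the offset is the *only*
  class-separating structure — the construction used to demonstrate that a
  classifier trained inside such a cohort attains inflated internal AUROC yet
  transfers at chance to a clean cohort.
* **Survival.** Event times are exponential with rate
  `baseline_rate · exp(β_risk·risk + β_class·class)`; censoring is the minimum
  of an independent exponential clock and an administrative follow-up horizon
  (defaults: baseline 1/1500 per day, censoring 1/4000 per day, horizon 5000
  days — median survival on the order of a few years with roughly 60–90%
  events depending on covariates). Exponential rather than Weibull times keep
  closed-form sanity checks; the proportional-hazards assumption holds exactly
  by construction, so Cox coefficient recovery is a pure estimator check.

## Discovery pipeline

* **Variance filter** (default threshold 0.10) is estimated on the training
  partition only and applied frozen elsewhere; a config switch
  (`variance_scope="all"`) exposes the permissive whole-cohort variant. The
  leakage-free reading was chosen because every other estimated quantity in
  the pipeline follows the same fence.
* **Hypergraph.** Pearson correlations on training samples; constant genes get
  r = 0 (logged) rather than NaN to keep shapes stable. Hyperedge weight is
  the sum of |r(seed, member)| over non-seed members ("seed-anchored"): it is
  anchored to the seed gene, reduces to 0 for singleton edges, and makes the
  hyperdegree a weighted co-participation count. The all-pairs-within-edge
  alternative is available via `weight_mode="all_pairs"`. Ranking ties break
  lexicographically by gene id for reproducibility. Top 300 candidates
  (default) proceed.
* **Permutation null.** Each gene's sample vector is permuted independently,
  destroying co-expression while preserving marginals; suprathreshold
  unordered-pair counts are tabulated on τ ∈ {0.50, …, 0.95}; the empirical
  FDR at τ is mean(null count)/max(real count, 1). For independent noise with
  ≥ 150 samples, P(|r| > 0.75) per pair is below 10⁻¹⁰, so the null count at
  the operating threshold is zero across 50 permutations of a 1500-gene
  subsample — asserted in the acceptance suite.
* **Discretisation.** Equal-frequency thirds with cut-points at the
  33.33rd/66.67th percentiles of training values; binning uses half-open
  intervals (−∞,c₁], (c₁,c₂], (c₂,∞) so ties at a cut-point fall to the lower
  bin (the convention had to be fixed somewhere; lower-bin assignment is the
  common "≤" reading). Frozen cut-points are applied to new samples.
* **Reduct search.** Forward greedy adds the attribute with maximal
  incremental dependency gain (ties → lexicographically first) until γ_R
  reaches γ_A. Zero-gain plateaus are crossed rather than treated as a stop:
  attribute interactions (XOR-like structure) are exactly the situations
  rough-set reducts must handle, and stopping at the first zero-gain step
  would strand the search below γ_A. A backward pruning pass then removes
  every attribute whose deletion leaves γ unchanged; by monotonicity of γ a
  single sequential pass yields a superset-minimal set. Inconsistent tables
  (identical attribute tuples, conflicting decisions) are legal: γ_A < 1 and
  the stop criterion is γ_R = γ_A. An exhaustive enumeration oracle (≤ 15
  attributes) backs the property tests.
* **Metaheuristic searches.** Stochastic greedy draws each addition uniformly
  from the top-3 candidates by gain; simulated annealing proposes single-gene
  swaps on a fixed-size subset under geometric cooling (T₀ = 0.05, α = 0.95,
  80 iterations, subset size 10). The annealing objective is a function
  parameter; inside `roughsel` it defaults to γ (keeping the module
  self-contained), while the stability analysis in `pipeline` passes a
  cross-validated discrimination objective, matching how alternative subsets
  are scored when comparing them with a published panel.
* **Panel selection.** Candidates are ranked by the two-group ANOVA F
  (identical to the squared pooled-variance t; zero within-group variance
  yields F = 0 at equal means and an ∞ sentinel ranked first otherwise). The
  size grid {5, 8, 10, 12, 16, 20, 30, 50, 100} is evaluated by five-fold
  stratified CV with **fold-internal re-ranking**: ranking once on the full
  training partition and then cross-validating on the same samples inflates
  large panels (genes selected for cohort-level chance correlation look good
  in every fold), and under that protocol the argmax drifts systematically to
  N = 50–100. With fold-internal ranking the curve rises to the true signal
  size and plateaus. The selected size is the argmax of mean CV AUROC (ties →
  smallest); the final panel is the top-N of the full-training ranking.
  **Known limitation:** beyond the knee the curve is flat to within one or two
  misordered validation pairs, so the argmax position on the plateau is
  jitter-dominated; the selected size concentrates near the planted size but
  does not fall in {8, 10, 12} in a large majority of seeds under the default
  generator. The discovery acceptance simulation asserts the planted-gene
  recovery rate and reports the size-selection hit rate honestly.
* **ANOVA pool.** The pool fed to ANOVA ranking defaults to the hypergraph
  candidates (`anova_pool="hypergraph"`). Ranking within only the reduct genes
  (`"reduct"`) is supported but the reduct of a well-separated table typically
  has fewer than 10 attributes (3-bin tuples become pure after ~6 genes),
  which would cap the panel below the size grid; `"all"` ranks over every
  variance-filtered gene and is the pure-ANOVA baseline path.

## Classifier and evaluation battery

* Random forest, 200 trees, depth ≤ 10, min leaf 3, balanced class weights,
  fixed seed; features are z-scored with training-partition statistics
  (σ = 0 genes map to z = 0, the same convention as missing-gene imputation).
* Classification uses the strict rule "positive iff score > threshold", so
  scores tied at the threshold are called negative. Thresholds: training-score
  median (the conservative rule reused for survival dichotomisation), or CV
  fold-averaged optima of Youden's J / F1 / balanced accuracy; the fold-optimal
  threshold is placed mid-way through its equivalence region (all values
  between two adjacent observed scores act identically under the strict rule),
  which keeps the CV average inside the separating gap on separable data.
* AUROC is trapezoidal (equal to the normalised Mann–Whitney U with ½ credit
  for ties); AUPRC is step-integrated (average precision) to avoid optimistic
  linear interpolation, with the no-skill baseline equal to prevalence.
* The unpaired DeLong estimator computes per-cohort variance S₁₀/m + S₀₁/n
  from sample variances of the per-positive/per-negative placement components
  (ψ = 1/½/0); z = ΔAUC/√(var_A + var_B) with a two-sided normal p. Both
  cohorts degenerate at variance 0 with equal AUCs give p = 1.
* Calibration: Brier score with the p(1−p) no-information baseline;
  Hosmer–Lemeshow χ² = Σ (O−E)²/(E(1−E/n_g)) over 8 score-quantile groups
  (ties kept together; degenerate groups skipped with df reduced), df = g − 2
  = 6.
* The label-permutation test refits the full pipeline per shuffled-label
  iteration and uses the add-one empirical p = (#{null ≥ observed}+1)/(n+1),
  which can never return exactly zero.

## Survival module

Kaplan–Meier estimation, the log-rank test and Cox partial-likelihood
maximisation (Breslow ties) delegate to `lifelines`; the in-repo content is
the dichotomisation protocol (strict > at training percentiles 33/50/67),
the nested likelihood-ratio battery over predictor sets (χ² = 2ΔLL, df =
covariate gap; identical models give χ² = 0, p = 1), and the Harrell optimism
loop: per bootstrap resample, refit, optimism = C(boot model, boot sample) −
C(boot model, original sample); corrected C = apparent − mean optimism.
Failed bootstrap refits are skipped and counted. Bootstrap resampling is at
patient level.

## Problem sizes in the acceptance script

Worked examples are exact computations; simulations use: 200 random decision
tables (≤ 12 attributes, ≤ 40 objects) for reduct/oracle agreement; 5 random
instances ≤ 50 genes for the hyperdegree oracle plus one 1500-gene × 160-sample
null matrix with 50 permutations; 1000 simulated equal-AUC cohort pairs
(n = 100 each) for DeLong type-I calibration; 20 cohort seeds of the full
discovery pipeline (2000 genes, 268 samples) for signature recovery; one
n = 2000 survival cohort with 100 optimism bootstraps; and 10 seeds of the
batch-confound transfer comparison (500 genes, 268 samples). These sizes give
stable rates while keeping a single-CPU run at a few minutes.

## Known limitations

* The generator plants mean shifts and module correlation only; no outliers,
  missingness, batch structure (beyond the explicit confound mode), or
  heavy-tailed noise. Passing tests demonstrate correctness of the statistical
  machinery under the stated model, not robustness to real microarray/RNA-seq
  artefacts.
* Panel-size selection by argmax CV AUROC is intrinsically noisy on plateaued
  curves (see above); a parsimony rule (e.g. smallest size within one SE of
  the maximum) would stabilise it but is deliberately not the default, which
  follows the plain argmax-with-smallest-tie convention.
* No recalibration (Platt/isotonic), time-varying covariates, competing risks
  or proportionality diagnostics.
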