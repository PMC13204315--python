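# gliosig

Transcriptomic biomarker discovery and multi-layer validation for glioma
grading: an integrative pipeline combining **co-expression hypergraphs**,
**rough-set attribute reduction** and a balanced random-forest risk
classifier, with a full statistical validation battery (hold-out,
cross-platform external transfer, DeLong AUROC comparison, probability
calibration, permutation nulls) and survival analysis (Kaplan–Meier /
log-rank, multivariate Cox, Harrell bootstrap optimism correction).

## The problem

Distinguishing glioblastoma (GBM, WHO grade IV) from lower-grade glioma (LGG,
grades II–III) from bulk expression profiles, with a gene panel small enough
to be clinically tractable, and validating that panel on *other platforms*
(microarray-trained, RNA-seq-evaluated) and for *prognosis* (overall
survival), without information leaking from evaluation data into feature
selection. The package is aimed at computational biologists who want each
stage — and its leakage discipline — as reusable, tested components. A
synthetic-cohort generator with planted differential expression, latent-factor
co-expression modules, platform scale profiles, molecular covariates
(IDH-like, 1p/19q-codeletion-like) and exponential survival times makes every
stage exercisable without any data download.

## The method

Discovery runs in four layers, all estimated on the training partition only:

1. **Variance filter** — drop genes with sample variance < 0.10.
2. **Hypergraph hub ranking** — for each gene *gᵢ*, an ego hyperedge
   *eᵢ = {gⱼ : |r(gᵢ,gⱼ)| > τ}* (Pearson, τ = 0.75) with weight
   *wₑ = Σⱼ |r(gᵢ,gⱼ)|*; genes are ranked by hyperdegree
   *deg(g) = Σ_{e∋g} wₑ* and the top 300 become the candidate pool. A
   permutation null (every gene's sample vector shuffled independently, 50
   permutations, τ grid 0.50–0.95) certifies that noise alone produces
   essentially no suprathreshold pairs at the operating τ.
3. **Rough-set reduction** — expression is discretised by equal-frequency
   thirds into a decision system (U, A ∪ {D}); the dependency degree
   γ_B(D) = |POS_B(D)|/|U| counts samples whose class is deterministically
   inferable from attribute subset B; greedy forward selection (argmax
   incremental γ gain) plus backward pruning yields a minimal reduct with
   γ_R = γ_A. Stochastic-greedy and simulated-annealing searches quantify the
   stability of such subsets (pairwise Jaccard similarity).
4. **Panel selection and classification** — candidates are ranked by the
   two-group ANOVA F statistic; the panel size is chosen over
   N ∈ {5,8,10,12,16,20,30,50,100} by five-fold stratified cross-validated
   AUROC (fold-internal re-ranking, leakage-free); a random forest
   (200 trees, depth ≤ 10, min leaf 3, balanced class weights) on z-scored
   panel expression produces P(GBM | x), the continuous risk score.

Validation applies the frozen model to the locked hold-out and to external
cohorts under three normalisation protocols: per-cohort z-score
z = (x − μⱼ)/σⱼ (Method A), a fixed stored reference (Method B), and
per-sample rank→normal-quantile mapping (Method C, reference-free). Cohorts
are compared with the unpaired DeLong z-test built from structural V10/V01
components; calibration uses the Brier score and a Hosmer–Lemeshow χ² over 8
score-quantile groups (6 df). Survival analysis dichotomises patients at
training-derived risk percentiles {33, 50, 67}, fits
h(t|X) = h₀(t)·exp(β₁·RiskScore + β₂·IsGBM) with Breslow ties, tests nested
predictor sets by likelihood ratio, and corrects Harrell's C for overfitting
by bootstrap optimism.

## Worked example

```python
from gliosig import syndata, pipeline

design = syndata.SyntheticDesign(
    n_samples=268, positive_fraction=159/268, n_genes=2000,
    n_informative=10, effect_size=1.5, n_modules=10, module_size=5,
    module_rho=0.8, seed=7)
cohort = syndata.generate_cohort(design)

report = pipeline.run_discovery(cohort.expression, cohort.labels,
                                pipeline.PipelineConfig(seed=42))
internal = pipeline.run_internal_validation(report, cohort.expression, cohort.labels)

planted = set(cohort.truth["informative_genes"])
print("panel size:", report.sweep.selected_size)
print("planted genes recovered:", len(planted & set(report.panel)))
print("reduct:", sorted(report.reduct.attributes), "gamma=", report.reduct.gamma)
print("hold-out AUROC: %.3f  AUPRC: %.3f"
      % (internal["roc_pr"]["auroc"], internal["roc_pr"]["auprc"]))
```

prints

```
panel size: 10
planted genes recovered: 10
reduct: ['G0000', 'G0001', 'G0005', 'G0013', 'G0135', 'G0217'] gamma= 1.0
hold-out AUROC: 0.958  AUPRC: 0.960
```

The ten planted genes (1.5 within-class-SD shift, embedded in two
co-expression modules) are recovered exactly; the six-gene reduct achieves
full dependency (γ = 1: every training sample's class is determined by its
discretised values on those genes); the hold-out AUROC sits in the regime
expected for this effect size under module-correlated (partially redundant)
signal genes.

A command-line interface mirrors the stages
(`gliosig simulate / discover / validate-internal / validate-external /
survival / report`), driven by a single JSON config.

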