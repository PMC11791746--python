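# Methods

This note documents the statistical models, the synthetic data-generating
process, the defaults and their rationale, and the numerical choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A cohort (`ExpressionDataset`) is a genes × samples matrix of finite log2
expression values plus a clinical table aligned to the same samples (ER/PR/
HER2 status, grade, node, size class, subtype, follow-up time in months,
0/1 event, endpoint, treatment flag; missing values are the literal `NA` in
files). Matrices whose maximum exceeds 50 are treated as linear-scale
intensities and transformed with `log2(x + 1)`: log2 microarray values
rarely exceed ~16, so 50 separates the scales with a wide margin; the
threshold is an argument, and the transform is idempotent. Gene identifiers
are opaque labels — no probe-to-symbol mapping layer is provided. Survival
endpoints are recorded per cohort as RFS/DMFS/DSS in fallback preference
order; the analysis treats them uniformly.

## Synthetic cohort generator

The generator encodes, as testable ground truth, the assumptions the
analysis makes about real multi-platform cohort collections:

* latent proliferation `P_j ~ N(0,1)` per sample;
* expression `x_gj = μ_g + a_g^{(d)} + β_g P_j + ε_gj` with per-cohort
  platform offsets `a_g^{(d)} ~ N(0, platform_sd²)` and residual
  `ε ~ N(0, noise_sd²)`;
* `β_g = proliferation_loading_scale` on a dedicated gene block (the
  cell-cycle analog), per-gene `marker_loadings` on the marker analogs,
  0 elsewhere;
* an *ERBB2* analog shifted by `her2_shift` log2 units in a
  `her2_fraction` minority of samples;
* survival `T ~ Exponential(h₀·exp(γP + θ(x_m − x̄_m)))`, censoring
  `C ~ Uniform(0, censoring_max)`, observed time `min(T, C)` in months.

Defaults (the study conditions exercised throughout the tests): 10 cohorts
× 200 samples, 1,000 genes, a 150-gene proliferation block with unit
loadings, `platform_sd = noise_sd = 0.5` log2 units, 15% HER2+ with a +2
log2 shift (4 residual SDs — the outlier-detection regime such callers face
on real arrays), `h₀ = 0.01` events/month, `γ = 0.4` per SD of latent
proliferation, `θ = 0` (the fully mediated scenario), censoring uniform
over 120 months so the 60-month horizon restriction is exercised, 70% ER+.
The default marker loadings (PGRMC1 0.14, TMEM97 0.30, TK1 0.47, LDLR 0.08)
were chosen once so that the per-gene correlation with the latent level,
`β/√(β² + noise_sd²)`, spans the weak-to-strong range (~0.16 to ~0.69)
reported for such markers in tumor cohorts. Receptor labels are independent
of `P` by default; `er_negative_proliferation_shift` optionally couples ER−
status to higher mean proliferation. With `θ = 0`, any marker's survival
association exists only through `β_m P` — regressing out the proliferation
estimate must attenuate its log HR toward 0, which is the computational
analog of the mediation claim the adjusted Cox models test. The hazard uses
the *centered* marker expression in the `θ` term so that `θ` is a
per-log2-unit effect regardless of the gene's baseline mean.

The serum-response experiment plants `n_de` differentially expressed genes
(the proliferation block up-regulated in high serum, so derived weights are
sign-correct; additional genes with random sign) at exact magnitude
`log_fc_scale`, on the same gene universe as the cohorts. Defaults: 10
arrays per condition, 300 DE genes, unit log fold change. The cell-cycle
gene set analog is the proliferation block plus decoy genes drawn from the
end of the filler block, guaranteed disjoint from the planted serum genes.

What the generator does **not** emulate: probe-level platform structure,
batch-correction artifacts, RNA-seq count distributions, non-proportional
hazards, informative censoring, or correlated noise between genes beyond
the single latent factor. Passing tests therefore demonstrate correctness
of the estimators under the model's assumptions, not robustness to their
violation on real data.

All randomness flows from one root seed through named `SeedSequence`
substreams (baseline means, cohorts, serum experiment), so identical
configurations are byte-identical and stages are independently
reproducible.

## Signature derivation and scoring

The regularized two-sample t-test shrinks each gene's per-group variance
toward a background `σ₀²`, the mean sample variance over the `window` genes
nearest in rank of mean expression within that group (centered window,
truncated at the edges):

    s̃² = (ν₀σ₀² + (n−1)s²)/(ν₀ + n − 2)
    t = (mean_high − mean_low)/√(s̃²_a/n_a + s̃²_b/n_b),  df = ν₀ + n_a + n_b − 2

Defaults `ν₀ = 10`, `window = 101` follow the Baldi–Long convention for
this estimator; both are configurable. Note that at `ν₀ = 0` the statistic
equals the ordinary equal-variance t only up to the exact factor
`√((n−2)/(n−1))` per group — a consequence of the Bayesian df convention in
the variance denominator, which we keep rather than special-casing zero.
A constant matrix with `ν₀ = 0` has zero variance everywhere and is
rejected. Selection uses Benjamini–Hochberg step-up at FDR `q = 0.10`
(via `statsmodels.multipletests`).

The signature is the intersection of the significant serum-responsive genes
with the cell-cycle set, each gene weighted by its log fold change
(high-serum minus low-serum, so positive = proliferation-up; genes with
exactly zero fold change cannot carry a signed weight and are dropped). The
per-sample score is the |w|-normalized weighted sum of cohort-mean-centered
expression. The scoring reference the derivation follows gives the
log-fold-change weighting but not the normalization; the `Σ|w|`
normalization was chosen because it makes scores scale-comparable across
gene panels and invariant to positive rescaling of the weights, and
centering within cohort (rather than globally) removes additive platform
offsets. A `standardize` switch replaces centering with per-gene z-scoring
for users who prefer variance-equalized genes; centering is the default.

## HER2 approximation

HER2 calls use an outlier-profile rule on within-cohort *ERBB2* expression:
positive iff strictly above `median + 1.5 × spread`. "1.5 absolute
deviations above the median" admits two readings — the unscaled median
absolute deviation and the mean absolute deviation about the median. Both
are implemented; the **mean absolute deviation is the default** because
under the planted outlier mixture the generator produces (15% positives
shifted 4 residual SDs) it operates at ~98% specificity and ~97%
sensitivity, the regime expected of this approximation on annotated
cohorts, whereas the unscaled-MAD cutoff sits ~1.5 null SDs above the
median and misclassifies ~7% of true negatives. The strict inequality
matters only at exact ties and makes a constant cohort all-negative
(spread 0, warning logged). Approximation is skipped in
hormone-receptor-homogeneous cohorts (all non-unknown ER labels identical,
or ER entirely unknown), where the ER–HER2 association breaks the mixture
assumption.

Nearest-centroid subtyping median-centers each gene within the cohort and
assigns the centroid with maximal Spearman correlation over shared genes;
rank correlation is standard for published centroid classifiers and robust
to scale. Ties break by centroid column order with a warning. No published
centroid matrices ship with the package; the classifier takes any.

## Association and survival meta-analysis

Per-cohort Pearson correlations are mapped to Fisher z (`atanh r`,
`se = 1/√(n−3)`, requiring n ≥ 4) and pooled with the same machinery as
log hazard ratios; pooled correlations are reported back-transformed. At
`|r| = 1` the z-effect is computed on a value nudged just inside ±1 and the
p-value reported as the smallest positive float. Stratified analyses filter
samples before estimation; cohort/stratum cells below 10 samples are
dropped with a logged reason. Pooled categorical comparisons subtract the
per-cohort baseline-group mean first (exact platform-offset cancellation,
property-tested) and then run a one-way fixed-effects ANOVA on the pooled
values.

Cox models maximize the Efron-tie partial likelihood by Newton iteration
with step-halving (convergence at max |score| < 1e−8, at most 50
iterations; Breslow available by flag). Covariates are mean-centered
internally for numerical stability (coefficients unchanged). Standard
errors come from the inverse observed information. Degenerate inputs are
rejected explicitly: zero events, constant covariates, singular or
non-positive-definite information (flat likelihood), and monotone
likelihood — detected as a coefficient magnitude exceeding 15 during
iteration, since the score can flatten below the convergence tolerance
while the MLE is infinite. Genes are standardized to unit SD within cohort
before fitting, so the HR is per-SD and cross-platform comparable — the
only interpretation under which pooling heterogeneous platforms is
coherent; a no-standardization flag exists. The 5-year analysis
administratively censors at 60 months (time := 60, event := 0) rather than
excluding late events. No winsorization or transformation is applied beyond
standardization.

Meta-analysis: fixed-effect pooling is the inverse-variance weighted mean;
heterogeneity is tested with Cochran's Q against χ²(k−1); when p_Q < 0.05
the DerSimonian–Laird random-effects model is used
(`τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw))`, weights `1/(se² + τ²)`). The 95%
CI is `pooled ± 1.96·se` with a two-sided normal p — the standard
meta-analysis approximation. With k = 1 the pooled result is the single
estimate, reported with Q = 0 on 0 df and the fixed model.

## Concordance evaluation

Harrell's C with exact pair counting: a pair is usable iff the shorter
observed time is an event; the pair is concordant when the higher score
belongs to the shorter time; score ties count 0.5. Pairs with exactly equal
observed times are not usable under this reading (neither time is
shorter) — a deliberate, documented convention that matters only on heavily
discretized time scales. Pooling across cohorts uses the sample-size
weighted mean, with per-cohort values always emitted alongside. Harrell's
estimator (not Uno's inverse-probability-weighted variant) matches the
usage in the public challenge literature this evaluation style follows.

## Problem sizes

The test suite and acceptance script run the documented study conditions
(10 cohorts × 200 samples; 20 replicates for the HER2 and signature
recovery checks; 50 replicates for the mediation coverage check; 100 random
instances for the Cox grid-search and concordance brute-force oracles;
500 replicates of m = 2000 for the FDR calibration), chosen to make
Monte-Carlo margins comfortable at desk scale. End-to-end pipeline
determinism is verified by hashing two full output trees from the same
configuration.

## Known limitations

* The survival generator is exponential (constant baseline hazard) — the
  simplest model satisfying proportional hazards exactly; Cox estimation is
  agnostic to the baseline, so this loses no generality for the estimators
  tested, but hazard-shape misspecification is untested.
* No multivariable clinical adjustment (age, stage), time-varying effects,
  or proportional-hazards diagnostics.
* No global cross-platform batch correction beyond per-cohort centering and
  baseline normalization; no probe summarization or symbol mapping.
* The treated flag is generated but unused by the default analyses.
* Real published signatures (the 224-gene proliferation panel, PAM50
  centroids, recurrence scores) are external inputs: the pipeline accepts
  any gene set, centroid matrix, or score vector but ships none.
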