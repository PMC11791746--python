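# prolifmeta

Multi-cohort biomarker analysis for bulk breast cancer expression data:
derivation and scoring of a weighted proliferation gene signature,
outlier-based approximation of HER2 status from *ERBB2* expression,
per-cohort correlation and Cox survival effect estimation, and
heterogeneity-gated inverse-variance meta-analysis — exercised end-to-end on
a synthetic cohort generator with known ground truth.

## The scientific problem

Candidate biomarkers such as *PGRMC1*, *TMEM97* (the sigma-2 receptor) and
*LDLR* — components of a ternary complex implicated in rapid LDL
internalization — are associated with breast cancer recurrence. The central
analytic question is whether such an association is a *direct* hazard effect
or is *mediated by tumor proliferation*: proliferation drives both marker
expression and relapse, so a marker can predict recurrence without any
direct effect. Because Ki-67 and mitotic indices are rarely available in
public expression cohorts, proliferation must itself be estimated from
expression, and effects must be pooled across heterogeneous microarray
platforms.

The package implements that workflow as a reusable library (`src/prolifmeta`)
plus numbered analysis drivers (`analysis/`):

1. **Signature derivation** (`signature`): a regularized two-sample t-test
   (Cyber-T style: per-gene variance shrunk toward a background estimate
   pooled over the `window` genes nearest in mean-expression rank,
   `s̃² = (ν₀σ₀² + (n−1)s²)/(ν₀ + n − 2)`) contrasts low- vs high-serum
   conditions; Benjamini–Hochberg selection at FDR *q* = 10%; the significant
   serum-responsive genes are intersected with a cell-cycle gene set and
   weighted by their log fold change. Samples are scored with
   `score_j = Σ_g w_g x̃_gj / Σ_g |w_g|` on cohort-mean-centered expression.
2. **HER2 approximation** (`subtyping`): samples strictly above
   `median + 1.5 × spread` of within-cohort *ERBB2* expression are called
   HER2+, with the mean absolute deviation about the median as the default
   spread (unscaled MAD available); skipped in hormone-receptor-homogeneous
   cohorts. Generic nearest-centroid subtype classification (Spearman
   correlation on median-centered genes) is also provided.
3. **Association** (`association`): per-cohort Pearson correlations carried
   to the Fisher-z scale (`z = atanh r`, `se = 1/√(n−3)`) and pooled;
   one-way ANOVA on baseline-normalized values pooled across cohorts;
   transcriptome-wide correlate screens at a configurable |r| threshold.
4. **Survival meta-analysis** (`survival_meta`): per cohort, expression is
   standardized to unit SD, follow-up administratively censored at 60
   months, and the per-SD log hazard ratio estimated by a Cox
   proportional-hazards fit (Efron ties, Newton iteration), optionally
   adjusted for the proliferation score. Cohort effects are pooled by
   inverse variance (`ê = Σwᵢeᵢ/Σwᵢ`, `wᵢ = 1/seᵢ²`); when Cochran's Q is
   significant at p < 0.05 the DerSimonian–Laird random-effects model
   (`τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw))`) is used instead.
5. **Evaluation** (`evaluation`): Harrell's concordance index with exact
   pair counting, compared across risk-score sets.
6. **Synthetic data** (`syndata`): cohorts with a latent per-sample
   proliferation level `P ~ N(0,1)` driving a gene block and marker analogs
   (`x = μ_g + a_g^{(d)} + β_g P + ε`), per-cohort platform offsets, an
   *ERBB2* outlier mixture for HER2+, and exponential survival with hazard
   `h₀·exp(γP + θx_m)` — so that with θ = 0 a marker's survival association
   is fully mediated by proliferation, a truth the adjusted models must
   recover.

## Worked example

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_derive_signature.py
python analysis/03_score_and_associate.py
python analysis/04_survival_meta.py
python analysis/05_evaluate_scores.py
```

Driver 02 derives the signature from the simulated serum experiment:

```
serum DE genes called at FDR 10%: 309 (false-discovery proportion 0.036)
signature size after cell-cycle intersection: 152 genes
planted proliferation block recovered: 99.3%
```

Driver 03 pools marker-score correlations across the 10 cohorts (the weak
*LDLR*, moderate *PGRMC1*, strong *TMEM97*/*TK1* ordering is planted by the
generator's marker loadings):

```
  PGRMC1   r = +0.283 [+0.242, +0.323]  p = 3.18e-38 (fixed, k = 10)
  TMEM97   r = +0.498 [+0.464, +0.531]  p = 4.43e-130 (fixed, k = 10)
  TK1      r = +0.687 [+0.663, +0.709]  p = 1.22e-305 (fixed, k = 10)
  LDLR     r = +0.131 [+0.087, +0.174]  p = 4.86e-09 (fixed, k = 10)
```

Driver 04 shows the mediation signature of the generative model: markers
carry a significant unadjusted pooled hazard ratio that collapses to ~1 once
the estimated proliferation score enters the Cox model, because their hazard
association exists only through the latent proliferation level:

```
  TMEM97   unadjusted HR = 1.216 [1.131, 1.308] p = 1.29e-07 (fixed)
           adjusted   HR = 0.991 [0.914, 1.075] p = 8.25e-01
```

Driver 05 ranks the scores by pooled concordance index
(proliferation score C = 0.613, single-gene *TK1* C = 0.580, noise C = 0.520).

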