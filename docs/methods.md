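# Methods

This note documents the models, the synthetic-data generator, numerical
conventions and known limitations of `ironmr`.

## Genotypic risk scores

The instrument set is the published 12-SNP table of genome-wide-significant
associations with serum iron, ferritin, transferrin and transferrin
saturation, shipped verbatim as `ironmr/data/iron_snp_weights.tsv`
(columns: rsID, nearest gene, per-biomarker risk allele, per-biomarker
effect in biomarker SD per risk allele, genotyped/imputed flag). Five
records are flagged genotyped and seven imputed, following the
accompanying text of the source table; rs8177240's flag is ambiguous in
the original legend and is resolved to *imputed* so the 5/7 split holds.

**Weight sign.** Risk alleles are defined as the alleles predicting *lower*
iron status, yet the published effect estimates for iron, ferritin and
transferrin saturation are negative (risk allele ⇒ lower biomarker). To
keep the stated semantics — higher score ⇒ greater liability to low iron —
scores use magnitude weights `|w_i|`. This is a pure reflection of the
score axis; standardized scores differ only in sign from the signed-weight
alternative, so no inference changes.

**Orientation.** `GenotypeMatrix` stores one dosage per SNP plus the
counted allele. Scoring and per-allele analyses flip `d → 2 − d` whenever
the counted allele differs from the analysis biomarker's risk allele; in
the shipped table this only ever triggers for rs8177240 (T counts for
iron, G for transferrin and saturation).

**Missingness.** Individuals missing more than 20 % of a score's SNPs are
dropped with a logged warning; remaining missing dosages are mean-imputed
per SNP (standard allele-score practice). Standardisation is
`(raw − mean)/SD` with the sample SD (ddof = 1) over the analysis sample,
matching per-SD reporting. A zero-variance raw score raises a
degenerate-input error rather than emitting NaNs.

## Synthetic cohort generator

The generator is a pure function of `CohortConfig` (seed included) and
encodes the study's causal diagram:

1. Maternal genotypes: dosage ~ Binomial(2, p) per SNP, i.e. Hardy-Weinberg
   proportions, independent loci. Default risk-allele frequencies are
   approximate European values for the 12 loci (e.g. 0.93 for rs1800562,
   whose risk allele is the wild type); all overridable.
2. Child genotypes: one allele drawn uniformly from the mother's two, one
   paternal allele ~ Bernoulli(p). Mother-child dosage correlation is 1/2
   in expectation.
3. Latent maternal iron (SD units):
   `iron = −√h2 · score_std + √(1−h2) · ε`, so higher score ⇒ lower iron.
   Default `h2 = 0.03`, a realistic variance share for a genome-wide-
   significant biomarker score.
4. Supplementation: `logit P(supp_late) = logit(0.42) − γ·iron + c_s·U`,
   with U ~ N(0,1) unmeasured. The base rate 0.42 mirrors the proportion
   supplemented in late pregnancy in the motivating cohort (2 248 of
   5 303); γ (default 1 log-odds/SD) is the *collider dial* — deficient
   mothers are supplemented more. Early supplementation uses a lower base
   rate (0.15) and half the iron effect.
5. Restoration: supplemented mothers recover `supp_restore` (default 0.5)
   of any iron *deficit* (`max(0, −iron)`), mirroring clinical indication;
   this is what dilutes genetic associations among supplemented women.
6. Haemoglobin proxy: `hb = mean + 0.6·iron + N(0, 1)` g/dL, with late
   haemoglobin loading on post-supplementation iron and early haemoglobin
   on the unmodified latent iron (plus ~1 g/dL haemodilution offset).
   `hb_loading = 0.6` makes the score→late-Hb slope ≈ −0.10 g/dL per score
   SD at the defaults, the magnitude scale of the motivating analysis.
7. Offspring outcomes: continuous lung-function outcomes
   `y = β·iron_post + c_o·U + N(0,1)`, re-standardised to SD units
   (emulating age/height/gender standardisation); binary asthma/atopy via
   logistic models at baseline prevalences 0.12/0.20 with the same iron
   log-odds effect; log-IgE Normal(3.7, 1.3); ten "principal components"
   as independent N(0,1) noise covariates.

The re-standardisation divisor of each continuous outcome is recorded in
`SyntheticCohort.outcome_sd_scale` so parameter-recovery studies can map
estimates back to model units; the latent iron and the confounder U are
likewise exposed as generator truth.

**Confounder strength.** The single U acts on supplementation (`c_s`) and
on outcomes (`c_o`), defaults 1.0 each. The within-stratum collider bias
scales with the *product* of the two arms; at 0.5/0.5 it is numerically
negligible (< 0.005 SD at n = 5 000), so the defaults are set where the
mechanism under study is actually expressed while U still represents a
plausible aggregate of unmeasured determinants (education, parity, BMI,
smoking…). Both arms are configurable, and setting either to zero breaks
the collider path — the falsifiable signature used by the tests.

**What the generator does not emulate:** linkage disequilibrium between
the 12 loci (the source screen found all pairwise R² < 0.10; loci are
simulated independent), population stratification (the PCs are pure
noise), missing data unless configured, assortative mating, and paternal
genotype effects.  Passing tests therefore demonstrate correctness of the
estimators and of the pipeline's causal logic, not robustness to those
real-data features.

## Statistical conventions

- Two-sided tests at α = 0.05 throughout; no multiple-testing correction.
- OLS and logistic models are fitted by statsmodels; Wald intervals use
  the t distribution (residual df) for OLS and the normal for logistic.
  Complete-case analysis per outcome; collinear design columns raise an
  error naming the aliased column; logistic separation is detected and
  raised rather than silently returning exploding estimates.
- IgE geometric-mean ratios: OLS on ln(IgE) with HC1 (Huber-White)
  sandwich variances; `exp(β)` with log-scale symmetric CIs.
- HWE: likelihood-ratio test against the saturated multinomial, χ²₁
  asymptotic p; monomorphic SNPs return stat 0, p 1, flagged.
- LD: composite (dosage-correlation) r², pairwise-complete; phase-free by
  design since the check is a correlation screen.
- IVW and MR-Egger use fixed-effect weighted least squares with
  first-order weights 1/se²(βy) and covariance (XᵀWX)⁻¹ (no residual
  scaling). Consequences: Egger with its intercept constrained to zero
  reproduces IVW *exactly*, and exposure-beta uncertainty is not
  propagated (the source meta-analysis prints betas without SEs) — both
  declared limitations. Overdispersion (pleiotropy heterogeneity) is not
  absorbed into the SEs.
- Weighted median: ratios sorted ascending, weights wⱼ = βxⱼ²/se²(βyⱼ)
  normalised, midpoint convention sⱼ = Σ_{k≤j} w_k − wⱼ/2, linear
  interpolation at 0.5 (clamped to the end ratios outside the midpoint
  range). SE by parametric bootstrap of βy ~ N(βy, se), default 2 000
  draws, mandatory seed; p and CI are normal-theory from that SE.
  *Known limitation:* this canonical construction is mildly conservative —
  measured true size ≈ 0.040–0.044 at five instruments (and lower with
  more), because the bootstrap SE co-varies with the realised estimate.
  The package reports it as is rather than recalibrating.
- Collider simulation: per gamma and replicate, a null cohort
  (causal effect forced to 0) is generated and the standardized iron score
  is tested against the outcome within each supplementation stratum and
  overall (simple OLS Wald test, matching the substantive analysis);
  rejection rates carry binomial Monte-Carlo SEs. Default grid
  {0, 0.5, 1, 2, 4} log-odds/SD, 1 000 replicates of n = 5 000 — sized to
  run in minutes on one CPU. Replicates with a stratum under 10 records
  are skipped and counted. Inflation is non-monotone in γ: it peaks near
  γ ≈ 2 and declines again as selection becomes nearly deterministic in
  iron (the U arm then contributes relatively less to selection), while
  the unstratified analysis stays nominal at every γ.

## Problem sizes used by the automated checks

The test suite and `scripts/acceptance.py` size their simulations for
single-CPU runs: null calibrations use 4 000–10 000 replicates (cohort
replicates at n = 250, summary-data replicates at 5 instruments),
parameter recovery uses 500 replicates at n = 5 000, the collider runs use
400 replicates per grid point at n = 5 000, and transmission checks use
50 000 mother-child pairs. These are the package's declared study
conditions; all are overridable through the config objects.

## Design choices made where the design was open

- Early-pregnancy haemoglobin reflects unmodified latent iron (supplements
  mostly start after early measurement); only late haemoglobin and
  outcomes see post-supplementation iron.
- Per-allele haemoglobin models default to unadjusted (score term only);
  covariates are accepted but not required.
- The Wald IV ratio used in recovery studies takes post-supplementation
  iron as the exposure — the generator's actual causal variable — and
  ignores first-stage uncertainty in its delta-method SE (conventional
  with a strong instrument).
- `causal_effect` is defined on the iron scale (SD outcome per SD iron);
  because the score is inversely related to iron, a *positive* causal
  effect produces the *negative* score-outcome associations reported for
  lung function.
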