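# Methods

## The mediation model

The analysis concerns a three-variable path diagram: an exposure X (a coded
SNP genotype, by default the dominant contrast "carrier of ≥1 minor allele"
vs major-allele homozygote), a candidate mediator M (a circulating
biomarker on the log₁₀ scale), and an outcome Y (a metabolic phenotype,
continuous or binary).  Three regressions, all adjusted for the same
covariates and fit on the same complete-case rows, estimate

| path | model | coefficient |
|---|---|---|
| X → M | M ~ X + covariates | α |
| M → Y and X → Y given M | Y ~ M + X + covariates | β (on M), γ′ (on X) |
| X → Y | Y ~ X + covariates | γ (total effect) |

Four criteria are evaluated at a two-sided 0.05 level (configurable):
(1) α significant; (2) β significant; (3) γ significant; (4) the indirect
effect αβ significant by the Sobel test,

    se(αβ) = sqrt(β²·se(α)² + α²·se(β)²),    Z = αβ / se(αβ),

with p from the standard normal.  The two-term (first-order delta-method)
variance is the default; the Aroian variant, which adds se(α)²·se(β)², is
available behind a flag.  Criterion 3 is reported but deliberately **not**
required for a suppression verdict: in a suppression configuration the
total effect is expected to be small or nonsignificant, because the direct
and indirect paths cancel.

**Verdict rule.**  "suppression" requires Sobel p < 0.05, sign(αβ) ≠
sign(γ′), and |γ′| > |γ| (the fitted total when available, otherwise the
reconstruction αβ + γ′, with magnitudes compared in absolute value);
Sobel-significant concordant signs give "mediation"; everything else is
"none".

**Assumptions.**  This is a statistical decomposition, not a counterfactual
one: no unmeasured-confounding or cross-world assumptions are asserted, and
no bootstrap mediation intervals are computed (the Sobel normal
approximation is the method implemented).  For linear outcomes the OLS
identity γ = γ′ + αβ holds exactly on shared rows; the pipeline asserts it
to 1e-6 as an internal consistency check.  For logistic outcomes the
identity fails by odds-ratio non-collapsibility, so the fitted total and
the linear-style reconstruction are both reported under explicit labels and
never forced to agree.

## Regression conventions

* Inference is normal-based Wald everywhere: p = 2·Φ(−|coef/se|), 95% CI =
  coef ± 1.96·se.  At the cohort sizes this pipeline targets (hundreds of
  rows) the difference from t-based inference is far below reporting
  precision; using the normal keeps linear, logistic and Sobel inference on
  one reference distribution.
* OLS standard errors use the unbiased residual-variance estimator;
  logistic models are fit by Newton maximum likelihood (relative tolerance
  1e-10, max 100 iterations) and perfect separation raises an error rather
  than returning a divergent estimate.
* Each model is complete-case on exactly its own columns and records
  `n_used`, so per-analysis sample sizes differ across outcomes the way
  real association tables do.  No multiple-testing correction is applied by
  default.
* A constant outcome yields exact-zero slopes with zero SEs and exposure
  p = 1, flagged rather than crashed on.
* Stepwise selection is forward-entry (p < 0.05) with backward removal
  (p > 0.10), skipping candidates that make the design rank deficient;
  given the data it is deterministic.
* Sex is coded 0 = male, 1 = female everywhere; only exposure coefficients
  are treated as reportable surfaces, so the covariate reference levels are
  a convention, not a result.

## Derived phenotypes and risk flags

* HOMA-IR = insulin[µU/mL] × glucose[mmol/L] / 22.5, converting glucose
  from mg/dL at 18.0 mg/dL per mmol/L.
* QUICKI = 1/(log₁₀ insulin + log₁₀ glucose[mg/dL]).  Decimal logs are used
  here and for all "logarithmically transformed" biomarkers: QUICKI's
  original definition is decimal, and a dominant-model genotype contrast of
  −0.137 on the transformed adiponectin scale is consistent with the
  log₁₀ ratio of the observed group means (log₁₀(6.15/8.58) ≈ −0.145), not
  with the natural-log ratio (≈ −0.33).
* ATP-III metabolic syndrome: ≥3 of {BP ≥ 130/85 mm Hg or antihypertensive
  medication; triglycerides ≥ 150 mg/dL; HDL < 40 (men) / < 50 (women)
  mg/dL; fasting glucose ≥ 100 mg/dL or antidiabetic medication; waist
  > 90 (men) / > 80 (women) cm}.  Boundary strictness follows each
  clinical definition verbatim ("at least" inclusive, "greater/less than"
  exclusive).  Whether medication alone satisfies the BP/glucose attributes
  is configurable (`med_flags_count`, default true) — the question is moot
  in a cohort from which medication users were excluded, but both
  interpretations are exposed.
* Binary risks: hypertension SBP ≥ 140 or DBP ≥ 90 or medication; diabetes
  fasting glucose ≥ 7.0 mmol/L or medication; obesity BMI ≥ 25 (Asian
  criterion).  Insulin resistance is cohort-relative: HOMA-IR at or above
  the cohort 75th percentile, computed by linear-interpolation percentile
  with an inclusive boundary (the percentile estimator is a package choice;
  alternatives shift the flag only for ties at the boundary).
* Exclusions (age < 18, any regular medication) are applied before
  analysis, idempotently, with per-criterion counts logged.  Missing
  phenotype data are never imputed; models drop incomplete rows and say so.

## Population-genetic components

* **HWE**: Pearson χ² with 1 df against expected counts N·(p², 2pq, q²)
  with p estimated from the data.  The exact test would be preferable for
  rare alleles; the χ² matches the small-panel, common-variant setting this
  pipeline targets and is validated against brute-force arithmetic.
* **EM haplotype inference**: diplotypes compatible with each unphased
  multilocus genotype are enumerated (2^(h−1) resolutions for h
  heterozygous sites; panels capped at 10 SNPs), E-steps weight them by
  products of current haplotype frequencies, M-steps re-estimate
  frequencies from posterior gamete counts.  The observed-data
  log-likelihood trace is stored and must be non-decreasing.
  Initialization is the linkage-equilibrium product of allele frequencies —
  deterministic, no RNG — so symmetric ambiguities (a lone double
  heterozygote) land on the symmetric fixed point reproducibly.
  Participants missing any panel SNP are excluded from the EM.  Per-person
  expected haplotype dosages (posterior mean counts, summing to 2) are
  returned as the regressors for haplotype association — the standard
  dosage-regression choice.
* **LD**: two-locus haplotype frequencies from the same EM; D is computed
  on the minor-minor haplotype, D′ = |D|/D_max with the usual sign-dependent
  bound, r² = D²/(q_A p_A q_B p_B).  Monomorphic pairs are reported missing
  with a reason rather than as zeros.  Minor alleles are defined by cohort
  frequency with lexicographic tie-breaking.

## The synthetic cohort generator

The generator exists so that every stage — including the full mediation
table — can be exercised against known truth.  It emulates a middle-aged
East-Asian health-examination cohort *after* exclusions:

* **Genotypes**: two haplotypes per participant drawn i.i.d. from a fixed
  4-SNP haplotype simplex, so HWE holds by construction and LD is induced
  by haplotype sharing.  Defaults put the three major haplotypes at 97.73%
  of gametes (AGGG 0.4733, ATTT 0.329, TGGG 0.175, remainder ATTG 0.0227),
  giving the exposure SNP a minor-allele frequency of 0.329 and near-complete
  D′ across the panel.  These frequencies are a calibration choice.
* **Mediator**: log₁₀ adiponectin = 0.78 + α·dominant(G) + covariate terms
  + N(0, 0.25), with α = −0.137 by default; raw values are therefore
  log-normal (right-skewed, matching how such biomarkers are distributed).
* **Phenotypes**: each continuous phenotype is intercept + β·(log₁₀M −
  0.78) + γ′·dominant(G) + covariate terms + Gaussian noise, generated on
  the raw scale (DBP, glucose) or the log₁₀ scale (HDL, triglycerides,
  insulin).  Default β/γ′ pairs mirror published adjusted associations:
  glucose β = −16.730 mg/dL per log₁₀ unit with γ′ = −4.183 and residual
  SD 15 (a floor at 40 mg/dL truncates ~3×10⁻⁴ of draws — negligible for
  bias); DBP gets a weak mediated path (β = −1.929, SE-dominated) so its
  verdict is expected to be "none".  A binary syndrome outcome `mets_sim`
  uses a logistic link with β = −3.946, γ′ = −1.136 and intercept −1.3
  (≈15% prevalence).  It is kept separate from the ATP-III-derived `mets`
  flag so link-scale recovery tests have an outcome with exactly known
  coefficients.
* **Covariates**: age, sex, BMI and smoking (smoking rate sex-dependent,
  0.348 men / 0.038 women); covariates are otherwise independent because
  only marginals are being emulated — a documented simplification.  Waist
  tracks BMI; SBP tracks DBP; total/LDL cholesterol are marginal only.
* **Determinism**: one `numpy.random.Generator` stream per run with a fixed
  draw order (haplotypes → age, sex, smoking, BMI → mediator noise →
  phenotypes in declaration order → auxiliary marginals), so a seed pins
  every file byte-for-byte.  The truth JSON contains the full config.

What the generator does **not** emulate: real LD decay (LD here is purely
haplotype-block), genotype-covariate correlation, measurement error in the
biomarker assay, population stratification, or any cohort-specific joint
distribution.  Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the assumed structural model, not robustness
to the violations above.

## Validation problem sizes

Unit oracles run at n of tens to hundreds; distributional checks (MAF, HWE,
LD) at n = 10⁴; pipeline-level parameter recovery uses 200 replicates of
n = 5000 for both the suppression-geometry arm (bias of α̂, β̂, γ̂′ within
2 Monte-Carlo SE of zero; suppression verdict in ≥90% of replicates) and
the α = 0 null arm (verdict rate bounded by the nominal 5% level plus
simulation error — the Sobel test is conservative under a null path, so
the observed rate sits well below 5%).  These sizes make the whole suite
run in well under a minute on one CPU while leaving the Monte-Carlo
standard errors small enough for the bias bounds to bite.

## Known limitations

* Sobel inference assumes approximate normality of α̂β̂; for small cohorts
  or tiny paths a resampling interval would be preferable and is out of
  scope here.
* The suppression verdict is a pattern classification on fitted
  coefficients, not a causal claim.
* The EM returns frequencies and dosages but no per-individual phase calls
  beyond the diplotype posterior; panels are capped at 10 SNPs by design.
* Published coefficient tables can only be consumed as given (the bundled
  example dataset); their underlying individual-level data are not
  available to refit, so cohort-dependent quantities (association
  p-values, odds ratios) are outside what this package can reproduce.
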