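# medsuppress

Mediation and suppression analysis for genotype → circulating-biomarker →
metabolic-phenotype pathways.

## The problem

Epidemiological genetics regularly turns up variants whose association with a
disease phenotype only appears *after* adjusting for an intermediate
biomarker.  The textbook case is the *CDH13* locus: its minor alleles lower
circulating adiponectin, yet carriers show a *more* favorable metabolic
profile — but only once adiponectin is in the model.  That pattern is a
**suppression effect**: the direct path (genotype → phenotype) and the
indirect path through the mediator (genotype → biomarker → phenotype) have
opposite signs and partially cancel, leaving a total effect near zero.

`medsuppress` packages the full workflow an analyst needs to test for this:

* **cohort model** — derived metabolic indices
  (HOMA-IR = I₀ × G₀[mmol/L] / 22.5, QUICKI = 1/(log₁₀ I₀ + log₁₀ G₀)),
  base-10 log transforms of right-skewed biomarkers, ATP-III
  metabolic-syndrome scoring with Asian waist cutoffs, and age/medication
  exclusion filters with a logged audit trail;
* **popgen** — genotype coding (dominant/additive/genotypic),
  Hardy–Weinberg χ² (1 df), pairwise LD (D, D′, r²), and EM
  haplotype-frequency inference with per-individual expected dosages;
* **regression** — covariate-adjusted OLS and logistic models producing
  α, β, γ′ with normal-based Wald inference, plus stepwise predictor
  selection (enter p < 0.05, remove p > 0.10);
* **mediation** — the four-criterion framework: α (exposure predicts
  mediator), β and γ′ (mediator predicts outcome, exposure-adjusted), the
  total effect γ, the indirect effect αβ with the two-term Sobel standard
  error

  δ<sub>αβ</sub> = √(β²δ²<sub>α</sub> + α²δ²<sub>β</sub>),  Z = αβ / δ<sub>αβ</sub>,

  and a verdict rule: *suppression* when the Sobel test is significant,
  sign(αβ) ≠ sign(γ′), and |γ′| > |γ|;
* **synthetic** — a seeded cohort generator with 4 SNPs in haplotype-induced
  LD, a log-normal mediator shifted by genotype, and phenotypes carrying
  opposite-signed direct and mediated paths, with every structural
  parameter written to a truth JSON for recovery testing.

## Worked example

Generate a synthetic cohort and run the pipeline end to end:

```sh
$ medsuppress simulate --out demo/fixture --n 500 --seed 7
wrote demo/fixture/phenotypes.tsv, demo/fixture/genotypes.vcf, demo/fixture/truth.json

$ cat > demo/cfg.yaml <<EOF
phenotype_file: demo/fixture/phenotypes.tsv
genotype_file: demo/fixture/genotypes.vcf
outdir: demo/run
EOF

$ medsuppress run --config demo/cfg.yaml
pipeline complete; artifacts in demo/run
  diastolic_bp: none
  glucose: suppression
  quicki: suppression
  hdl: suppression
  triglycerides: suppression
  metabolic_syndrome: suppression
```

The generator embeds a genotype → log₁₀-adiponectin contrast of −0.137 and
opposite-signed β/γ′ paths into glucose, HDL, triglycerides and the
syndrome outcome, but *not* into diastolic BP's mediated path (its β is
weak) — so the verdict column is exactly what the embedded truth predicts:
suppression everywhere except diastolic BP.  `demo/run/` contains the HWE
and LD reports, haplotype frequencies, tier-1/tier-2 association tables,
the criterion-by-criterion mediation table and a manifest with per-model
sample sizes.

The single-shot Sobel calculator works directly on published coefficients.
For a log-odds model with α = −0.137 (SE 0.021) and β = −3.946 (SE 0.646):

```sh
$ medsuppress sobel --alpha -0.137 --se-alpha 0.021 --beta -3.946 --se-beta 0.646
indirect effect (alpha*beta): 0.540602
standard error: 0.121241
z: 4.4589
two-sided p: 8.23796e-06
```

i.e. the indirect effect is 0.54 on the log-odds scale with Sobel SE 0.121
— highly significant, and opposite in sign to a negative direct effect:
the suppression geometry.

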