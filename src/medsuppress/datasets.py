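"""Bundled example coefficient sets.

:func:`cdh13_adiponectin_decomposition` returns the published path
coefficients from a Taiwanese health-examination cohort study of *CDH13*
genotypes, circulating adiponectin, and metabolic phenotypes — the canonical
worked example of a suppression geometry.  The exposure is the intron-1 SNP
rs12051272 under a dominant model (GG vs GT+TT), the mediator is log10
adiponectin, and all models were adjusted for age, sex, BMI and current
smoking.  Five of the six phenotypes (fasting glucose, QUICKI, HDL
cholesterol, triglycerides, metabolic syndrome) show the suppression
pattern — opposite-signed direct and indirect effects with a significant
Sobel test — while diastolic BP does not reach Sobel significance.

These are inputs for the mediation calculator, not data this package can
refit: the underlying individual-level cohort was never deposited.  Notes:

* the diastolic-BP mediator coefficient is stored as −1.929; one rendering
  of the source table dropped the sign, but the companion association table
  and the positive printed product alpha*beta both require the negative
  value (two-sided quantities are unaffected either way);
* the metabolic-syndrome column is logistic (log-odds scale), so its fitted
  total (−0.492) differs from the linear-style reconstruction
  alpha*beta + gamma' (−0.595) — odds-ratio non-collapsibility, not an error.
"""

from __future__ import annotations

from .mediation import MediationInput

_ALPHA = dict(alpha=-0.137, se_alpha=0.021, p_alpha=1.57e-10)


def cdh13_adiponectin_decomposition() -> list[MediationInput]:
    """Published six-phenotype mediation inputs (see module docstring)."""
    return [
        MediationInput(
            **_ALPHA,
            beta=-1.929, se_beta=1.669, p_beta=0.248,
            gamma_prime=-1.861, se_gamma_prime=0.827, p_gamma_prime=0.025,
            total=-1.597, se_total=0.795, p_total=0.045,
            family="linear", label="diastolic_bp",
        ),
        MediationInput(
            **_ALPHA,
            beta=-0.056, se_beta=0.012, p_beta=4.84e-5,
            gamma_prime=-0.013, se_gamma_prime=0.006, p_gamma_prime=0.039,
            total=-0.005, se_total=0.006, p_total=0.339,
            family="linear", label="glucose",
        ),
        MediationInput(
            **_ALPHA,
            beta=0.024, se_beta=0.004, p_beta=3.81e-9,
            gamma_prime=0.005, se_gamma_prime=0.002, p_gamma_prime=0.019,
            total=0.001, se_total=0.002, p_total=0.487,
            family="linear", label="quicki",
        ),
        MediationInput(
            **_ALPHA,
            beta=0.164, se_beta=0.017, p_beta=2.58e-21,
            gamma_prime=0.027, se_gamma_prime=0.008, p_gamma_prime=0.001,
            total=0.005, se_total=0.009, p_total=0.571,
            family="linear", label="hdl",
        ),
        MediationInput(
            **_ALPHA,
            beta=-0.314, se_beta=0.040, p_beta=2.24e-14,
            gamma_prime=-0.073, se_gamma_prime=0.020, p_gamma_prime=2.39e-4,
            total=-0.030, se_total=0.020, p_total=0.134,
            family="linear", label="triglycerides",
        ),
        MediationInput(
            **_ALPHA,
            beta=-3.946, se_beta=0.646, p_beta=9.85e-10,
            gamma_prime=-1.136, se_gamma_prime=0.317, p_gamma_prime=3.34e-4,
            total=-0.492, se_total=0.275, p_total=0.074,
            family="logistic", label="metabolic_syndrome",
        ),
    ]
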