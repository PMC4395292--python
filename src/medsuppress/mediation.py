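"""Four-criterion mediation framework with Sobel test and suppression detection.

The causal diagram is the classic three-variable one: an exposure X (here a
coded genotype), a candidate mediator M (log10 biomarker), and an outcome Y
(a metabolic phenotype).  Three regressions, all sharing the same
complete-case rows and covariate adjustment, give

* alpha  — X -> M            (criterion 1: exposure predicts the mediator),
* beta   — M -> Y | X        (criterion 2: mediator predicts the outcome,
  adjusted for exposure; the same model's X coefficient is the direct effect
  gamma'),
* gamma  — X -> Y            (criterion 3: the total effect).

The indirect (mediated) effect is the product alpha*beta, its delta-method
standard error is the two-term Sobel form

    se(alpha*beta) = sqrt(beta^2 * se_alpha^2 + alpha^2 * se_beta^2)

(the Aroian variant adds se_alpha^2*se_beta^2 and is available behind a
flag), and criterion 4 tests H0: alpha*beta = 0 with Z = alpha*beta / se
against the standard normal (two-sided).

For linear outcomes the OLS identity total = gamma' + alpha*beta holds
exactly on shared rows and the pipeline asserts it.  For logistic outcomes
the identity fails (non-collapsibility of the odds ratio): both the fitted
total and the linear-style reconstruction are reported with explicit labels.

Suppression is the configuration where direct and indirect effects have
opposite signs and partially cancel, so that removing the mediator weakens
the apparent exposure-outcome association: verdict "suppression" requires a
significant Sobel test, sign(indirect) != sign(direct), and
|direct| > |total| (fitted total when available, else the reconstruction).
A significant Sobel test with concordant signs is ordinary "mediation";
anything else is "none".  A significant total effect (criterion 3) is
reported but deliberately not required for a suppression verdict: the
defining feature of suppression is precisely that the total effect may be
near zero or nonsignificant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy import stats

from .errors import DomainError
from .regression import ModelSpec, RegressionResult, fit, fit_linear

ALPHA_LEVEL = 0.05


def sobel_se(
    alpha: float, se_alpha: float, beta: float, se_beta: float, *, aroian: bool = False
) -> float:
    """Delta-method standard error of the product alpha*beta.

    Two-term Sobel form by default; ``aroian=True`` adds the second-order
    term se_alpha^2 * se_beta^2.
    """
    if se_alpha <= 0 or se_beta <= 0:
        raise DomainError("standard errors must be positive")
    var = beta * beta * se_alpha * se_alpha + alpha * alpha * se_beta * se_beta
    if aroian:
        var += se_alpha * se_alpha * se_beta * se_beta
    return math.sqrt(var)


def sobel_test(
    alpha: float, se_alpha: float, beta: float, se_beta: float, *, aroian: bool = False
) -> tuple[float, float]:
    """Sobel Z statistic and two-sided standard-normal p for H0: alpha*beta = 0."""
    se = sobel_se(alpha, se_alpha, beta, se_beta, aroian=aroian)
    ab = alpha * beta
    if se == 0:
        if ab != 0:
            raise DomainError("zero Sobel SE with nonzero indirect effect")
        return 0.0, 1.0
    z = ab / se
    return z, float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class MediationInput:
    """Coefficient/SE triples assembled from the three path regressions.

    p-values may be supplied (e.g. from a published table); when omitted they
    are recomputed as two-sided normal Wald p from coefficient/SE.
    """

    alpha: float
    se_alpha: float
    beta: float
    se_beta: float
    gamma_prime: float
    se_gamma_prime: float
    total: float | None = None
    se_total: float | None = None
    family: str = "linear"
    label: str = ""
    p_alpha: float | None = None
    p_beta: float | None = None
    p_gamma_prime: float | None = None
    p_total: float | None = None

    def __post_init__(self) -> None:
        for name in ("se_alpha", "se_beta", "se_gamma_prime"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")


def _wald_p(coef: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(coef / se)))


@dataclass
class MediationDecomposition:
    """Full decomposition for one phenotype, Table-4 style."""

    input: MediationInput
    indirect: float
    se_indirect: float
    z: float
    p_sobel: float
    total_reconstructed: float
    criteria: dict[str, bool] = field(default_factory=dict)
    verdict: str = "none"

    @property
    def label(self) -> str:
        return self.input.label

    @property
    def total_for_comparison(self) -> float:
        return self.input.total if self.input.total is not None else self.total_reconstructed


def decompose(
    minput: MediationInput, *, alpha_level: float = ALPHA_LEVEL, aroian: bool = False
) -> MediationDecomposition:
    """Indirect effect, Sobel inference, reconstruction, criteria flags, verdict."""
    indirect = minput.alpha * minput.beta
    se_ind = sobel_se(minput.alpha, minput.se_alpha, minput.beta, minput.se_beta, aroian=aroian)
    z, p_sobel = sobel_test(
        minput.alpha, minput.se_alpha, minput.beta, minput.se_beta, aroian=aroian
    )
    total_rec = indirect + minput.gamma_prime
    p_alpha = minput.p_alpha if minput.p_alpha is not None else _wald_p(minput.alpha, minput.se_alpha)
    p_beta = minput.p_beta if minput.p_beta is not None else _wald_p(minput.beta, minput.se_beta)
    if minput.p_total is not None:
        p_total = minput.p_total
    elif minput.total is not None and minput.se_total:
        p_total = _wald_p(minput.total, minput.se_total)
    else:
        p_total = None
    criteria = {
        "c1_exposure_predicts_mediator": p_alpha < alpha_level,
        "c2_mediator_predicts_outcome": p_beta < alpha_level,
        "c3_total_effect_significant": (p_total is not None and p_total < alpha_level),
        "c4_sobel_significant": p_sobel < alpha_level,
    }
    out = MediationDecomposition(
        input=minput,
        indirect=indirect,
        se_indirect=se_ind,
        z=z,
        p_sobel=p_sobel,
        total_reconstructed=total_rec,
        criteria=criteria,
    )
    out.verdict = classify_suppression(out, alpha_level=alpha_level)
    return out


def classify_suppression(
    decomp: MediationDecomposition, *, alpha_level: float = ALPHA_LEVEL
) -> str:
    """Verdict: "suppression", "mediation", or "none".

    Suppression: significant Sobel test, indirect and direct effects of
    opposite sign, and |direct| > |total|.  Mediation: significant Sobel test
    with concordant signs.  The magnitude comparison uses the fitted total
    effect when available, else the reconstruction alpha*beta + gamma'.
    """
    if decomp.p_sobel >= alpha_level:
        return "none"
    direct = decomp.input.gamma_prime
    opposite = (decomp.indirect > 0) != (direct > 0) and decomp.indirect != 0 and direct != 0
    if opposite and abs(direct) > abs(decomp.total_for_comparison):
        return "suppression"
    if not opposite:
        return "mediation"
    return "none"


@dataclass(frozen=True)
class PhenotypeModel:
    """One outcome in the mediation table."""

    label: str
    column: str
    family: str = "linear"  # "linear" | "logistic"
    outcome_scale: str = "raw"  # "raw" | "log10"


def run_mediation_table(
    data: pd.DataFrame,
    *,
    exposure: str,
    mediator: str,
    phenotypes: Sequence[PhenotypeModel],
    covariates: Sequence[str] = (),
    alpha_level: float = ALPHA_LEVEL,
    aroian: bool = False,
) -> list[MediationDecomposition]:
    """Fit the three path models per phenotype and assemble decompositions.

    ``data`` must already contain the coded exposure column and the
    (transformed) mediator column.  All three models for a phenotype are fit
    on the same complete-case rows (the intersection over outcome, mediator,
    exposure and covariates), so the OLS decomposition identity holds exactly
    for linear outcomes; this is asserted.  A failure fitting one phenotype
    does not abort the others; an exception is raised only if every
    phenotype fails.
    """
    covariates = tuple(covariates)
    results: list[MediationDecomposition] = []
    errors: list[str] = []
    for ph in phenotypes:
        try:
            cols = [ph.column, mediator, exposure, *covariates]
            sub = data.dropna(subset=cols)
            m1 = fit_linear(ModelSpec(mediator, exposure, covariates), sub)
            m2 = fit(
                ModelSpec(ph.column, mediator, (exposure,) + covariates, ph.family, ph.outcome_scale),
                sub,
            )
            m3 = fit(
                ModelSpec(ph.column, exposure, covariates, ph.family, ph.outcome_scale), sub
            )
            g_coef, g_se, g_p = m2.term(exposure)
            minput = MediationInput(
                alpha=m1.coefficient,
                se_alpha=m1.se,
                beta=m2.coefficient,
                se_beta=m2.se,
                gamma_prime=g_coef,
                se_gamma_prime=g_se,
                total=m3.coefficient,
                se_total=m3.se,
                family=ph.family,
                label=ph.label,
                p_alpha=m1.p_value,
                p_beta=m2.p_value,
                p_gamma_prime=g_p,
                p_total=m3.p_value,
            )
            dec = decompose(minput, alpha_level=alpha_level, aroian=aroian)
            if ph.family == "linear":
                resid = abs(m3.coefficient - dec.total_reconstructed)
                if resid > 1e-6:
                    raise AssertionError(
                        f"OLS decomposition identity violated for {ph.label}: "
                        f"|total - (alpha*beta + gamma')| = {resid:.3g}"
                    )
            results.append(dec)
        except AssertionError:
            raise
        except Exception as exc:  # isolate per-phenotype fit failures
            errors.append(f"{ph.label}: {exc}")
    if not results and errors:
        raise RuntimeError("all phenotype fits failed: " + "; ".join(errors))
    return results


def decompositions_to_frame(decomps: Sequence[MediationDecomposition]) -> pd.DataFrame:
    """Tidy one-row-per-phenotype summary of the decomposition list."""
    rows = []
    for d in decomps:
        i = d.input
        rows.append(
            {
                "phenotype": d.label,
                "family": i.family,
                "alpha": i.alpha,
                "se_alpha": i.se_alpha,
                "beta": i.beta,
                "se_beta": i.se_beta,
                "gamma_prime": i.gamma_prime,
                "se_gamma_prime": i.se_gamma_prime,
                "total": i.total,
                "se_total": i.se_total,
                "indirect": d.indirect,
                "se_indirect": d.se_indirect,
                "total_reconstructed": d.total_reconstructed,
                "sobel_z": d.z,
                "p_sobel": d.p_sobel,
                "verdict": d.verdict,
                **d.criteria,
            }
        )
    return pd.DataFrame(rows)
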