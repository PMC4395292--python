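"""Covariate-adjusted linear and logistic models.

This module produces the coefficient / standard-error / p-value triples the
mediation stage consumes: the exposure->mediator path (alpha), the
mediator->outcome path adjusted for exposure (beta), the direct effect
(gamma'), and the total effect.  Fitting is delegated to statsmodels (OLS for
linear outcomes, maximum-likelihood Logit for binary ones); inference is
normal-based Wald throughout — p = 2*Phi(-|coef/se|) and 95% CI =
coef +/- 1.96*se — matching the reporting convention of epidemiological
association tables.  Each fit is complete-case on exactly the columns it
uses and records the rows retained, so per-analysis sample sizes are
reproducible.

A forward-entry / backward-removal stepwise selector (enter p < 0.05, remove
p > 0.10) is provided for "independent predictors of the biomarker" style
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import SeparationError, SingularDesignError

Z95 = 1.96


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one association model.

    ``outcome_scale`` applies a base-10 log to the outcome before fitting
    (used for right-skewed biomarkers).  The exposure is the term whose
    coefficient the result exposes; covariates are adjusted for.
    """

    outcome: str
    exposure: str
    covariates: tuple[str, ...] = ()
    family: str = "linear"  # "linear" | "logistic"
    outcome_scale: str = "raw"  # "raw" | "log10"

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.outcome in self.covariates:
            raise ValueError("outcome cannot appear among covariates")
        if self.exposure in self.covariates:
            raise ValueError("exposure cannot appear among covariates")

    @property
    def columns(self) -> tuple[str, ...]:
        return (self.outcome, self.exposure) + self.covariates


@dataclass
class RegressionResult:
    """Exposure coefficient with Wald inference, plus the full term table."""

    spec: ModelSpec
    coefficient: float
    se: float
    p_value: float
    n_used: int
    converged: bool
    table: pd.DataFrame = field(repr=False)  # coef/se/p for every term
    row_index: pd.Index = field(repr=False, default=None)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.coefficient - Z95 * self.se, self.coefficient + Z95 * self.se)

    @property
    def odds_ratio(self) -> float | None:
        if self.spec.family != "logistic":
            return None
        return float(np.exp(self.coefficient))

    @property
    def or_ci95(self) -> tuple[float, float] | None:
        if self.spec.family != "logistic":
            return None
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))

    def term(self, name: str) -> tuple[float, float, float]:
        """(coefficient, se, p) for an arbitrary model term."""
        row = self.table.loc[name]
        return float(row["coef"]), float(row["se"]), float(row["p"])


def _wald_p(coef: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, coef / se, np.where(coef == 0, 0.0, np.inf))
    return 2.0 * stats.norm.sf(np.abs(z))

def _design(spec: ModelSpec, data: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    missing = [c for c in spec.columns if c not in data.columns]
    if missing:
        raise KeyError(f"model columns not in data: {missing}")
    sub = data[list(spec.columns)].dropna()
    y = sub[spec.outcome].astype(float)
    if spec.outcome_scale == "log10":
        if (y <= 0).any():
            raise ValueError(f"log10 outcome {spec.outcome!r} has non-positive values")
        y = np.log10(y)
    X = sub[[spec.exposure, *spec.covariates]].astype(float)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns that add no rank beyond the ones before them
        bad = []
        cols = X.columns.tolist()
        r = 0
        for k, col in enumerate(cols):
            nr = int(np.linalg.matrix_rank(X.iloc[:, : k + 1].to_numpy()))
            if nr == r:
                bad.append(col)
            r = nr
        raise SingularDesignError(
            f"design matrix rank deficient; collinear columns: {bad or cols}",
            tuple(bad),
        )
    return y, X


def _result(spec, params, bse, n_used, converged, index) -> RegressionResult:
    p = _wald_p(params.to_numpy(), bse.to_numpy())
    table = pd.DataFrame({"coef": params, "se": bse, "p": p})
    coef, se, pv = table.loc[spec.exposure, ["coef", "se", "p"]]
    return RegressionResult(
        spec=spec,
        coefficient=float(coef),
        se=float(se),
        p_value=float(pv),
        n_used=int(n_used),
        converged=bool(converged),
        table=table,
        row_index=index,
    )


def fit_linear(spec: ModelSpec, data: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares; SEs from the unbiased residual variance."""
    y, X = _design(spec, data)
    if len(y) <= X.shape[1]:
        raise ValueError(f"n_used={len(y)} too small for {X.shape[1]} parameters")
    if np.ptp(y.to_numpy()) == 0.0:
        # constant outcome: exact zero slopes, intercept = the constant, se 0
        params = pd.Series(0.0, index=X.columns)
        params["const"] = float(y.iloc[0])
        return _result(spec, params, pd.Series(0.0, index=X.columns), len(y), True, X.index)
    fit = sm.OLS(y, X).fit()
    return _result(spec, fit.params, fit.bse, len(y), True, X.index)


def fit_logistic(spec: ModelSpec, data: pd.DataFrame, *, maxiter: int = 100) -> RegressionResult:
    """Maximum-likelihood logistic regression (log-odds scale).

    Raises :class:`SeparationError` on perfect separation rather than
    returning a silently divergent estimate.
    """
    y, X = _design(spec, data)
    vals = set(np.unique(y))
    if not vals <= {0.0, 1.0} or len(vals) < 2:
        raise ValueError(f"logistic outcome {spec.outcome!r} must be binary with both classes")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, tol=1e-10)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(f"perfect separation fitting {spec.outcome!r}") from exc
    converged = bool(fit.mle_retvals.get("converged", False))
    if not converged or not np.isfinite(fit.bse).all():
        raise SeparationError(
            f"logistic fit for {spec.outcome!r} did not converge (possible separation)"
        )
    return _result(spec, fit.params, fit.bse, len(y), converged, X.index)


def fit(spec: ModelSpec, data: pd.DataFrame) -> RegressionResult:
    return fit_logistic(spec, data) if spec.family == "logistic" else fit_linear(spec, data)


@dataclass
class StepwiseResult:
    selected: tuple[str, ...]
    final: RegressionResult | None
    trace: list[str] = field(default_factory=list)


def stepwise_select(
    candidates: Sequence[str],
    outcome: str,
    data: pd.DataFrame,
    *,
    always_in: Sequence[str] = (),
    enter_p: float = 0.05,
    remove_p: float = 0.10,
    outcome_scale: str = "raw",
) -> StepwiseResult:
    """Forward-entry / backward-removal stepwise OLS on Wald p-values.

    At each forward step the candidate with the smallest p-value below
    ``enter_p`` (given current terms) enters; after each entry any selected
    term whose p-value rises above ``remove_p`` leaves.  Candidates that make
    the design rank deficient are skipped.  Deterministic given the data.
    ``always_in`` covariates are kept in every model and never removed.
    """
    data = data.dropna(subset=[outcome, *always_in, *candidates])
    selected: list[str] = []
    trace: list[str] = []

    def _fit(exposure: str, others: Sequence[str]) -> RegressionResult | None:
        spec = ModelSpec(outcome, exposure, tuple(others), "linear", outcome_scale)
        try:
            return fit_linear(spec, data)
        except SingularDesignError:
            return None

    while True:
        remaining = [c for c in candidates if c not in selected]
        best: tuple[float, str] | None = None
        for cand in remaining:
            res = _fit(cand, list(always_in) + selected)
            if res is None:
                continue
            if best is None or res.p_value < best[0]:
                best = (res.p_value, cand)
        if best is None or best[0] >= enter_p:
            break
        selected.append(best[1])
        trace.append(f"enter {best[1]} (p={best[0]:.3g})")
        # backward pass
        changed = True
        while changed and selected:
            changed = False
            worst: tuple[float, str] | None = None
            for term in selected:
                others = list(always_in) + [t for t in selected if t != term]
                res = _fit(term, others)
                if res is None:
                    continue
                if worst is None or res.p_value > worst[0]:
                    worst = (res.p_value, term)
            if worst is not None and worst[0] > remove_p:
                selected.remove(worst[1])
                trace.append(f"remove {worst[1]} (p={worst[0]:.3g})")
                changed = True
    if not selected:
        return StepwiseResult((), None, trace or ["no candidate passed entry"])
    final = _fit(selected[0], list(always_in) + selected[1:])
    return StepwiseResult(tuple(selected), final, trace)
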