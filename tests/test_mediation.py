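import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from medsuppress.datasets import cdh13_adiponectin_decomposition
from medsuppress.errors import DomainError
from medsuppress.mediation import (
    MediationInput,
    PhenotypeModel,
    decompose,
    run_mediation_table,
    sobel_se,
    sobel_test,
)
from medsuppress.synthetic import PhenotypeSpec, SyntheticConfig, simulate_cohort
from medsuppress.popgen import code_genotype

coef = st.floats(min_value=-50, max_value=50, allow_nan=False)
se = st.floats(min_value=1e-3, max_value=10, allow_nan=False)


class TestSobel:
    @pytest.mark.parametrize(
        "alpha, se_a, beta, se_b, expected",
        [
            (-0.137, 0.021, -3.946, 0.646, 0.121),  # log-odds scale product
            (-0.137, 0.021, -0.056, 0.012, 0.00202),
            (0.137, 0.021, 1.929, 1.669, 0.232),
        ],
    )
    def test_se_published_examples(self, alpha, se_a, beta, se_b, expected):
        assert sobel_se(alpha, se_a, beta, se_b) == pytest.approx(expected, abs=5e-4)

    def test_se_zero_when_both_paths_zero(self):
        assert sobel_se(0.0, 1.0, 0.0, 1.0) == 0.0

    def test_aroian_variant_adds_second_order_term(self):
        plain = sobel_se(1.0, 0.5, 2.0, 0.25)
        aroian = sobel_se(1.0, 0.5, 2.0, 0.25, aroian=True)
        assert aroian**2 - plain**2 == pytest.approx(0.5**2 * 0.25**2, abs=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(DomainError):
            sobel_se(1.0, 0.0, 1.0, 1.0)

    def test_z_and_p_for_weak_path(self):
        z, p = sobel_test(0.137, 0.021, 1.929, 1.669)
        assert abs(z) == pytest.approx(1.138, abs=2e-3)
        assert p == pytest.approx(0.255, abs=1e-3)

    def test_null_product_gives_p_one(self):
        z, p = sobel_test(0.0, 0.5, 3.0, 0.5)
        assert z == 0.0 and p == 1.0

    def test_critical_value_1_96_gives_p_05(self):
        # inputs constructed so the product SE is 1 and z lands on 1.96
        z, p = sobel_test(1.96, 1.0, 1.0, 1e-12)
        assert z == pytest.approx(1.96, abs=1e-9)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_matches_symbolic_evaluation(self, rng):
        a_s, sa_s, b_s, sb_s = sympy.symbols("a sa b sb", positive=True)
        expr = sympy.sqrt(b_s**2 * sa_s**2 + a_s**2 * sb_s**2)
        for _ in range(1000):
            a, saa, b, sb = rng.uniform(0.01, 5, size=4)
            want = float(expr.subs({a_s: a, sa_s: saa, b_s: b, sb_s: sb}).evalf(30))
            assert math.isclose(sobel_se(a, saa, b, sb), want, rel_tol=0, abs_tol=1e-12)

    @given(alpha=coef, beta=coef, se_a=se, se_b=se)
    @settings(max_examples=200, deadline=None)
    def test_p_invariant_to_simultaneous_sign_flip(self, alpha, beta, se_a, se_b):
        _, p1 = sobel_test(alpha, se_a, beta, se_b)
        _, p2 = sobel_test(-alpha, se_a, -beta, se_b)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestDecompose:
    def test_product_and_reconstruction(self):
        minput = MediationInput(
            alpha=-0.137, se_alpha=0.021, beta=-3.946, se_beta=0.646,
            gamma_prime=-1.136, se_gamma_prime=0.317, family="logistic",
        )
        d = decompose(minput)
        assert d.indirect == pytest.approx(0.541, abs=5e-4)
        assert d.total_reconstructed == pytest.approx(-0.595, abs=1e-3)

    def test_triglyceride_style_reconstruction(self):
        minput = MediationInput(
            alpha=-0.137, se_alpha=0.021, beta=-0.314, se_beta=0.040,
            gamma_prime=-0.073, se_gamma_prime=0.020,
        )
        d = decompose(minput)
        assert d.indirect == pytest.approx(0.043, abs=5e-4)
        assert d.total_reconstructed == pytest.approx(-0.030, abs=5e-4)

    def test_zero_beta_collapses_to_direct_effect(self):
        minput = MediationInput(
            alpha=0.5, se_alpha=0.1, beta=0.0, se_beta=0.1,
            gamma_prime=-0.8, se_gamma_prime=0.1,
        )
        d = decompose(minput)
        assert d.indirect == 0.0
        assert d.total_reconstructed == minput.gamma_prime
        assert d.verdict == "none"


class TestSuppressionVerdicts:
    def test_published_six_phenotypes(self):
        verdicts = {i.label: decompose(i).verdict for i in cdh13_adiponectin_decomposition()}
        assert verdicts == {
            "diastolic_bp": "none",
            "glucose": "suppression",
            "quicki": "suppression",
            "hdl": "suppression",
            "triglycerides": "suppression",
            "metabolic_syndrome": "suppression",
        }

    def test_concordant_signs_is_mediation(self):
        minput = MediationInput(
            alpha=0.5, se_alpha=0.05, beta=1.0, se_beta=0.1,
            gamma_prime=-1.0, se_gamma_prime=0.2, total=-1.5, se_total=0.2,
        )
        # indirect +0.5 vs direct -1.0: opposite, but |total| > |direct| -> none
        assert decompose(minput).verdict == "none"
        minput2 = MediationInput(
            alpha=0.5, se_alpha=0.05, beta=-1.0, se_beta=0.1,
            gamma_prime=-1.0, se_gamma_prime=0.2, total=-1.5, se_total=0.2,
        )
        assert decompose(minput2).verdict == "mediation"

    def test_nonsignificant_total_does_not_block_suppression(self):
        minput = MediationInput(
            alpha=-0.5, se_alpha=0.05, beta=-1.0, se_beta=0.1,
            gamma_prime=-0.45, se_gamma_prime=0.2, total=0.05, se_total=0.2,
            p_total=0.8,
        )
        d = decompose(minput)
        assert not d.criteria["c3_total_effect_significant"]
        assert d.verdict == "suppression"


@pytest.fixture(scope="module")
def analysis_frame():
    config = SyntheticConfig(n=3000, seed=5)
    df, panel = simulate_cohort(config)
    df = df.copy()
    df["genotype"] = code_genotype(panel.column(config.exposure_snp), "dominant")
    df["log_adiponectin"] = np.log10(df["adiponectin"])
    return config, df


class TestMediationTable:
    def test_structured_phenotypes_show_suppression(self, analysis_frame):
        config, df = analysis_frame
        decomps = run_mediation_table(
            df,
            exposure="genotype",
            mediator="log_adiponectin",
            phenotypes=[
                PhenotypeModel("glucose", "glucose_fasting"),
                PhenotypeModel("hdl", "hdl", outcome_scale="log10"),
                PhenotypeModel("mets", "mets_sim", family="logistic"),
            ],
            covariates=("age", "sex", "bmi", "current_smoker"),
        )
        verdicts = {d.label: d.verdict for d in decomps}
        assert verdicts["glucose"] == "suppression"
        assert verdicts["hdl"] == "suppression"

    def test_phenotype_equal_to_mediator_is_pure_mediation_structure(self, analysis_frame):
        _, df = analysis_frame
        df = df.assign(copy_of_mediator=df["log_adiponectin"])
        (d,) = run_mediation_table(
            df,
            exposure="genotype",
            mediator="log_adiponectin",
            phenotypes=[PhenotypeModel("copy", "copy_of_mediator")],
            covariates=("age", "sex"),
        )
        assert d.input.beta == pytest.approx(1.0, abs=1e-8)
        assert d.input.gamma_prime == pytest.approx(0.0, abs=1e-8)

    def test_permuted_mediator_breaks_criterion_one(self, analysis_frame):
        _, df = analysis_frame
        rng = np.random.default_rng(0)
        df = df.assign(log_adiponectin=rng.permutation(df["log_adiponectin"].to_numpy()))
        (d,) = run_mediation_table(
            df,
            exposure="genotype",
            mediator="log_adiponectin",
            phenotypes=[PhenotypeModel("glucose", "glucose_fasting")],
            covariates=("age", "sex"),
        )
        assert d.input.p_alpha > 0.05
        assert d.verdict == "none"

    def test_failing_phenotype_isolated(self, analysis_frame):
        _, df = analysis_frame
        df = df.assign(all_ones=1.0)  # constant binary outcome cannot be fit
        decomps = run_mediation_table(
            df,
            exposure="genotype",
            mediator="log_adiponectin",
            phenotypes=[
                PhenotypeModel("bad", "all_ones", family="logistic"),
                PhenotypeModel("glucose", "glucose_fasting"),
            ],
            covariates=("age", "sex"),
        )
        assert [d.label for d in decomps] == ["glucose"]
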