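"""Synthetic cohort generator with known ground-truth path coefficients.

The generator emulates the statistical structure of a middle-aged East-Asian
health-examination cohort in which a 4-SNP panel in strong pairwise LD shifts
a log-normally distributed circulating biomarker (adiponectin), and metabolic
phenotypes are driven by both the genotype (direct path, gamma') and the
log10 biomarker (mediated path, beta) with opposite signs — the suppression
geometry.  Haplotypes are drawn from a fixed simplex (so every SNP is in HWE
by construction and LD is induced by haplotype sharing), and a binary
syndrome outcome is generated through a logistic link.

Every structural parameter lives in :class:`SyntheticConfig` and is written
to the truth JSON next to the generated files, so parameter-recovery tests
can compare estimates with the exact values used for generation.  A single
:class:`numpy.random.Generator` stream with a fixed draw order (haplotypes,
then covariates, then mediator noise, then phenotypes in declaration order,
then auxiliary marginals) makes output byte-identical for a given seed.

The defaults are a calibration, not data: haplotype frequencies put 97.73%
of gametes on the three major haplotypes and give the exposure SNP a minor
allele frequency of 0.329; the genotype->mediator contrast is −0.137 on the
log10 scale; phenotype path coefficients mirror published adjusted
associations (e.g. glucose beta −16.730 mg/dL per log10 unit, direct effect
−4.183 mg/dL).  See docs/methods.md for what the generator deliberately does
not emulate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .popgen import SnpPanel, code_genotype, panel_to_vcf


@dataclass(frozen=True)
class PhenotypeSpec:
    """Structural equation for one generated phenotype.

    ``scale='log10'`` means the linear predictor lives on the log10 scale and
    the stored column is 10**lp (log-normal raw values).  The mediator enters
    centered at its base mean, so ``intercept`` is the expected value at
    baseline mediator level for an unexposed male nonsmoker of average age
    and BMI.  ``covariate_effects`` keys are ``age``/``bmi`` (per unit,
    centered) and ``sex``/``current_smoker`` (indicator).  ``floor`` clips a
    physiologically impossible lower tail (a few 1e-4 of draws at defaults).
    """

    column: str
    family: str = "linear"  # linear | logistic
    scale: str = "raw"  # raw | log10
    intercept: float = 0.0
    beta: float = 0.0
    gamma_prime: float = 0.0
    noise_sd: float = 1.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    floor: float | None = None


def _default_phenotypes() -> tuple[PhenotypeSpec, ...]:
    return (
        PhenotypeSpec(
            "dbp", intercept=75.0, beta=-1.929, gamma_prime=-1.861, noise_sd=9.5,
            covariate_effects={"sex": -3.9, "age": 0.15, "current_smoker": 1.0}, floor=40.0,
        ),
        PhenotypeSpec(
            "glucose_fasting", intercept=95.0, beta=-16.730, gamma_prime=-4.183,
            noise_sd=15.0, covariate_effects={"age": 0.3}, floor=40.0,
        ),
        PhenotypeSpec(
            "hdl", scale="log10", intercept=1.698, beta=0.164, gamma_prime=0.027,
            noise_sd=0.09, covariate_effects={"sex": 0.094},
        ),
        PhenotypeSpec(
            "triglycerides", scale="log10", intercept=2.10, beta=-0.314,
            gamma_prime=-0.073, noise_sd=0.20,
            covariate_effects={"sex": -0.19, "current_smoker": 0.05},
        ),
        PhenotypeSpec(
            "insulin_fasting", scale="log10", intercept=0.95, beta=-0.30,
            gamma_prime=0.0, noise_sd=0.18, covariate_effects={"bmi": 0.012},
        ),
        PhenotypeSpec(
            "mets_sim", family="logistic", intercept=-1.3, beta=-3.946,
            gamma_prime=-1.136, covariate_effects={"age": 0.03, "bmi": 0.08},
        ),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """All structural parameters of the generator (the ground truth)."""

    n: int = 530
    seed: int = 0
    snp_ids: tuple[str, ...] = ("rs11646213", "rs12444338", "rs4783244", "rs12051272")
    snp_alleles: tuple[tuple[str, str], ...] = (("A", "T"), ("G", "T"), ("G", "T"), ("G", "T"))
    haplotypes: tuple[str, ...] = ("AGGG", "ATTT", "TGGG", "ATTG")
    haplotype_freqs: tuple[float, ...] = (0.4733, 0.329, 0.175, 0.0227)
    exposure_snp: str = "rs12051272"
    # genotype -> mediator path (log10 scale, dominant coding)
    alpha_true: float = -0.137
    mediator_base_mean: float = 0.78  # log10 mg/L for baseline stratum
    mediator_sd: float = 0.25  # residual SD on the log10 scale
    mediator_covariate_effects: tuple[tuple[str, float], ...] = (
        ("sex", 0.22), ("age", 0.002), ("bmi", -0.008), ("current_smoker", -0.04),
    )
    # covariate marginals
    age_mean: float = 44.87
    age_sd: float = 9.38
    female_rate: float = 0.49
    smoking_rate_male: float = 0.348
    smoking_rate_female: float = 0.038
    bmi_mean: float = 24.15
    bmi_sd: float = 3.49
    phenotypes: tuple[PhenotypeSpec, ...] = field(default_factory=_default_phenotypes)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if abs(sum(self.haplotype_freqs) - 1.0) > 1e-9:
            raise ValueError("haplotype_freqs must sum to 1")
        if self.mediator_sd <= 0:
            raise ValueError("mediator_sd must be positive")
        for hap in self.haplotypes:
            if len(hap) != len(self.snp_ids):
                raise ValueError(f"haplotype {hap!r} length != panel size")


def _hap_matrix(config: SyntheticConfig) -> np.ndarray:
    """Haplotypes as 0/1 minor-allele indicator rows."""
    out = np.zeros((len(config.haplotypes), len(config.snp_ids)), dtype=np.int8)
    for h, hap in enumerate(config.haplotypes):
        for j, allele in enumerate(hap):
            major, minor = config.snp_alleles[j]
            if allele == minor:
                out[h, j] = 1
            elif allele != major:
                raise ValueError(f"haplotype {hap!r} has unknown allele {allele!r} at SNP {j}")
    return out


def simulate_genotypes(config: SyntheticConfig, rng: np.random.Generator) -> SnpPanel:
    """Draw two haplotypes per participant; genotypes follow by allele counting."""
    hap = _hap_matrix(config)
    idx = rng.choice(len(config.haplotypes), size=(config.n, 2), p=np.asarray(config.haplotype_freqs))
    geno = hap[idx[:, 0]] + hap[idx[:, 1]]
    samples = tuple(f"P{i+1:05d}" for i in range(config.n))
    return SnpPanel(config.snp_ids, config.snp_alleles, geno, samples)


def _covariate_term(effects, age_c, sex, bmi_c, smoker) -> np.ndarray:
    lookup = {"age": age_c, "sex": sex, "bmi": bmi_c, "current_smoker": smoker}
    out = np.zeros_like(age_c)
    for name, eff in dict(effects).items():
        out = out + eff * lookup[name]
    return out


def simulate_phenotypes(
    panel: SnpPanel, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Covariates, mediator, structured phenotypes and auxiliary marginals."""
    n = config.n
    d = code_genotype(panel.column(config.exposure_snp), "dominant")

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 90.0)
    sex = (rng.random(n) < config.female_rate).astype(float)  # 0 male, 1 female
    smoke_rate = np.where(sex == 1, config.smoking_rate_female, config.smoking_rate_male)
    smoker = (rng.random(n) < smoke_rate).astype(float)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15.0, 45.0)
    age_c = age - config.age_mean
    bmi_c = bmi - config.bmi_mean

    log_adipo = (
        config.mediator_base_mean
        + config.alpha_true * d
        + _covariate_term(config.mediator_covariate_effects, age_c, sex, bmi_c, smoker)
        + rng.normal(0.0, config.mediator_sd, n)
    )
    med_c = log_adipo - config.mediator_base_mean

    df = pd.DataFrame(
        {
            "id": list(panel.samples or (f"P{i+1:05d}" for i in range(n))),
            "age": age,
            "sex": sex,
            "current_smoker": smoker.astype(bool),
            "bmi": bmi,
            "adiponectin": 10.0 ** log_adipo,
        }
    )

    for spec in config.phenotypes:
        cov = _covariate_term(spec.covariate_effects, age_c, sex, bmi_c, smoker)
        lp = spec.intercept + spec.beta * med_c + spec.gamma_prime * d + cov
        if spec.family == "logistic":
            df[spec.column] = rng.random(n) < expit(lp)
        else:
            y = lp + rng.normal(0.0, spec.noise_sd, n)
            if spec.scale == "log10":
                y = 10.0 ** y
            elif spec.floor is not None:
                y = np.maximum(y, spec.floor)
            df[spec.column] = y

    # auxiliary marginals without genotype/mediator structure
    dbp = df["dbp"].to_numpy() if "dbp" in df.columns else np.full(n, 75.0)
    df["sbp"] = dbp + np.maximum(rng.normal(37.8, 10.0, n), 5.0)
    df["total_chol"] = np.maximum(rng.normal(199.25, 36.28, n), 80.0)
    df["ldl"] = np.maximum(rng.normal(116.62, 33.17, n), 30.0)
    waist_base = np.where(sex == 1, 81.61, 87.41)
    df["waist"] = np.maximum(waist_base + 1.5 * bmi_c + rng.normal(0.0, 5.0, n), 55.0)
    for col in ("on_htn_med", "on_dm_med", "on_lipid_med"):
        df[col] = False
    return df


def simulate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, SnpPanel]:
    """Genotypes + phenotypes from one seeded RNG stream."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_genotypes(config, rng)
    return simulate_phenotypes(panel, config, rng), panel


def write_fixture(
    df: pd.DataFrame, panel: SnpPanel, config: SyntheticConfig, outdir: str | Path
) -> dict[str, Path]:
    """Emit phenotype TSV + VCF + ground-truth JSON into ``outdir``.

    Sex is written as M/F so the files round-trip through the standard
    loader without a coding map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / "phenotypes.tsv",
        "genotypes": outdir / "genotypes.vcf",
        "truth": outdir / "truth.json",
    }
    out = df.copy()
    out["sex"] = np.where(out["sex"] == 1, "F", "M")
    out.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.6f")
    panel_to_vcf(panel, paths["genotypes"])
    truth = dataclasses.asdict(config)
    paths["truth"].write_text(json.dumps(truth, indent=2, default=list) + "\n")
    return paths
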