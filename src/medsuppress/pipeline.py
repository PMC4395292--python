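"""End-to-end orchestration: load -> QC -> associations -> mediation table.

The run is driven by a single declarative :class:`RunConfig` (YAML on disk).
Stages execute in the order a reader of the association literature expects:
exclusions and derived phenotypes, SNP QC (HWE, pairwise LD), haplotype
inference, covariate-adjusted association contrasts at two adjustment tiers
(age+sex; age+sex+BMI+smoking), stepwise predictor selection for the
mediator, and finally the four-criterion mediation/suppression table.  Every
stage writes a TSV/JSON artifact into the output directory and the manifest
records versions, filter counts and per-model sample sizes, so each number
in a rendered report traces to a stage artifact.  Runs are deterministic:
same inputs and config give identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, annotate_cohort, apply_exclusions, load_phenotypes, write_cohort
from .mediation import (
    MediationDecomposition,
    PhenotypeModel,
    decompositions_to_frame,
    run_mediation_table,
)
from .popgen import (
    SnpPanel,
    code_genotype,
    em_haplotypes,
    hwe_report,
    ld_report,
    panel_from_tsv,
    panel_from_vcf,
)
from .regression import ModelSpec, fit, stepwise_select

log = logging.getLogger("medsuppress")

DEFAULT_PHENOTYPES = (
    {"label": "diastolic_bp", "column": "dbp", "family": "linear", "scale": "raw"},
    {"label": "glucose", "column": "glucose_fasting", "family": "linear", "scale": "raw"},
    {"label": "quicki", "column": "quicki", "family": "linear", "scale": "raw"},
    {"label": "hdl", "column": "hdl", "family": "linear", "scale": "log10"},
    {"label": "triglycerides", "column": "triglycerides", "family": "linear", "scale": "log10"},
    {"label": "metabolic_syndrome", "column": "mets", "family": "logistic", "scale": "raw"},
)


@dataclass
class RunConfig:
    phenotype_file: str
    genotype_file: str
    outdir: str
    genotype_format: str = "vcf"  # vcf | tsv
    snp_sidecar: str | None = None  # required for tsv genotypes
    exposure_snp: str = "rs12051272"
    genotype_model: str = "dominant"
    mediator: str = "adiponectin"
    mediator_transform: str = "log10"  # log10 | raw
    phenotypes: tuple[dict[str, str], ...] = DEFAULT_PHENOTYPES
    covariates_tier1: tuple[str, ...] = ("age", "sex")
    covariates_tier2: tuple[str, ...] = ("age", "sex", "bmi", "current_smoker")
    alpha_level: float = 0.05
    hwe_warn_p: float = 0.05
    ld_warn_r2: float = 0.2
    min_age: float = 18.0
    drop_medicated: bool = True

    def __post_init__(self) -> None:
        if self.genotype_format not in ("vcf", "tsv"):
            raise ValueError("genotype_format must be 'vcf' or 'tsv'")
        if self.genotype_format == "tsv" and not self.snp_sidecar:
            raise ValueError("tsv genotypes need a snp_sidecar with allele metadata")
        if not self.covariates_tier1 or not self.covariates_tier2:
            raise ValueError("covariate tiers must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        if "phenotypes" in raw:
            raw["phenotypes"] = tuple(dict(p) for p in raw["phenotypes"])
        return cls(**raw)


def _load_panel(config: RunConfig) -> SnpPanel:
    if config.genotype_format == "vcf":
        return panel_from_vcf(config.genotype_file)
    return panel_from_tsv(config.genotype_file, config.snp_sidecar)


def _validate_columns(config: RunConfig, df: pd.DataFrame, panel: SnpPanel) -> None:
    needed = {config.mediator, *config.covariates_tier1, *config.covariates_tier2}
    derived = {"quicki", "homa_ir", "mets", "log_adiponectin"}
    for ph in config.phenotypes:
        if ph["column"] not in derived:
            needed.add(ph["column"])
    missing = sorted(c for c in needed if c not in df.columns)
    if missing:
        raise ValueError(f"config references missing phenotype columns: {missing}")
    if config.exposure_snp not in panel.ids:
        raise ValueError(f"exposure SNP {config.exposure_snp!r} not in genotype panel")


def _align(cohort: Cohort, panel: SnpPanel) -> pd.DataFrame:
    """Attach coded genotype columns to the cohort table by sample id/order."""
    df = cohort.data.reset_index(drop=True)
    gdf = panel.to_frame()
    if panel.samples is not None and "id" in df.columns:
        gdf = gdf.set_axis(list(panel.samples)).reindex(df["id"].astype(str)).reset_index(drop=True)
    elif len(gdf) != len(df):
        raise ValueError("genotype panel and phenotype table sizes differ and no sample ids")
    return pd.concat([df, gdf], axis=1)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"version": __version__, "stages": {}, "config": config.__dict__.copy()}
    manifest["config"]["phenotypes"] = [dict(p) for p in config.phenotypes]

    def stage(name: str):
        t0 = time.perf_counter()

        def done(**info: Any) -> None:
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = info
            log.info("stage %s done: %s", name, info)

        return done

    # 1. load + exclusions + derived columns
    done = stage("cohort")
    cohort = load_phenotypes(config.phenotype_file)
    filtered, flog = apply_exclusions(
        cohort.data, min_age=config.min_age, drop_medicated=config.drop_medicated
    )
    cohort = Cohort(filtered, source=cohort.source, filter_log=flog)
    panel_full = _load_panel(config)
    _validate_columns(config, cohort.data, panel_full)
    cohort = annotate_cohort(cohort)
    write_cohort(cohort, outdir / "cohort.tsv", outdir / "filter_log.json")
    done(n=cohort.n, **flog)

    # 2. SNP QC
    done = stage("snp_qc")
    hwe = hwe_report(panel_full)
    ld = ld_report(panel_full)
    hwe.to_csv(outdir / "hwe.tsv", sep="\t", index=False)
    ld.to_csv(outdir / "ld.tsv", sep="\t", index=False)
    for _, row in hwe.iterrows():
        if row["p_value"] < config.hwe_warn_p:
            log.warning("HWE deviation for %s (p=%.3g)", row["snp"], row["p_value"])
    for _, row in ld.iterrows():
        if row["r2"] is not None and pd.notna(row["r2"]) and row["r2"] < config.ld_warn_r2:
            log.warning("weak LD %s-%s (r2=%.3f)", row["snp_a"], row["snp_b"], row["r2"])
    done(n_snps=panel_full.n_snps)

    # 3. haplotype inference
    done = stage("haplotypes")
    hap = em_haplotypes(panel_full)
    hap.as_series().rename_axis("haplotype").reset_index().to_csv(
        outdir / "haplotypes.tsv", sep="\t", index=False
    )
    done(
        n_haplotypes=len(hap.haplotypes),
        n_iterations=hap.n_iterations,
        converged=hap.converged,
        top=dict(zip(hap.haplotypes[:4], map(float, hap.frequencies[:4]))),
    )

    # 4. merged analysis table
    data = _align(cohort, panel_full)
    exposure_col = f"{config.exposure_snp}_{config.genotype_model}"
    data[exposure_col] = code_genotype(
        data[config.exposure_snp].to_numpy(), config.genotype_model
    )
    mediator_col = config.mediator
    if config.mediator_transform == "log10":
        mediator_col = f"log_{config.mediator}"
        if mediator_col not in data.columns:
            data[mediator_col] = np.log10(data[config.mediator].astype(float))

    # 5. association contrasts at both adjustment tiers
    done = stage("associations")
    assoc_rows = []
    n_models = 0
    for tier_name, covs in (
        ("age_sex", config.covariates_tier1),
        ("age_sex_bmi_smoking", config.covariates_tier2),
    ):
        for ph in config.phenotypes:
            for exp_name, exp_col, adj in (
                ("genotype", exposure_col, ()),
                ("mediator", mediator_col, ()),
                ("genotype_mediator_adj", exposure_col, (mediator_col,)),
                ("mediator_genotype_adj", mediator_col, (exposure_col,)),
            ):
                try:
                    res = fit(
                        ModelSpec(
                            ph["column"], exp_col, tuple(covs) + adj,
                            ph["family"], ph.get("scale", "raw"),
                        ),
                        data,
                    )
                except Exception as exc:
                    log.warning("association fit failed (%s/%s/%s): %s", tier_name, ph["label"], exp_name, exc)
                    continue
                n_models += 1
                lo, hi = res.ci95
                assoc_rows.append(
                    {
                        "tier": tier_name,
                        "phenotype": ph["label"],
                        "exposure": exp_name,
                        "family": ph["family"],
                        "coefficient": res.coefficient,
                        "se": res.se,
                        "ci_low": lo,
                        "ci_high": hi,
                        "odds_ratio": res.odds_ratio,
                        "p_value": res.p_value,
                        "n_used": res.n_used,
                    }
                )
    pd.DataFrame(assoc_rows).to_csv(outdir / "associations.tsv", sep="\t", index=False)
    done(n_models=n_models)

    # 6. stepwise predictors of the mediator
    done = stage("stepwise")
    candidates = [exposure_col] + [c for c in config.covariates_tier2]
    sw = stepwise_select(candidates, mediator_col, data)
    (outdir / "stepwise.json").write_text(
        json.dumps({"selected": list(sw.selected), "trace": sw.trace}, indent=2) + "\n"
    )
    done(selected=list(sw.selected))

    # 7. mediation table
    done = stage("mediation")
    phenos = [
        PhenotypeModel(p["label"], p["column"], p["family"], p.get("scale", "raw"))
        for p in config.phenotypes
    ]
    decomps = run_mediation_table(
        data,
        exposure=exposure_col,
        mediator=mediator_col,
        phenotypes=phenos,
        covariates=config.covariates_tier2,
        alpha_level=config.alpha_level,
    )
    tidy = decompositions_to_frame(decomps)
    tidy.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
    render_table4(decomps).to_csv(outdir / "mediation_criteria.tsv", sep="\t")
    (outdir / "mediation.json").write_text(tidy.to_json(orient="records", indent=2) + "\n")
    done(verdicts={d.label: d.verdict for d in decomps})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def render_table4(
    decomps: Sequence[MediationDecomposition], *, digits: int = 3
) -> pd.DataFrame:
    """Criterion-by-criterion report: one column per phenotype.

    Rows mirror the four-criterion layout: alpha (criterion 1), beta and the
    direct effect gamma' (criterion 2), the total effect (criterion 3), and
    the indirect effect with its Sobel SE and p (criterion 4).  Values are
    rounded for display; upstream artifacts keep full precision.
    """
    if not decomps:
        raise ValueError("no decompositions to render")
    rows = {}
    for d in decomps:
        i = d.input
        rows[d.label] = {
            ("criterion_1_alpha", "coefficient"): i.alpha,
            ("criterion_1_alpha", "se"): i.se_alpha,
            ("criterion_1_alpha", "p"): i.p_alpha,
            ("criterion_2_beta", "coefficient"): i.beta,
            ("criterion_2_beta", "se"): i.se_beta,
            ("criterion_2_beta", "p"): i.p_beta,
            ("criterion_2_gamma_prime", "coefficient"): i.gamma_prime,
            ("criterion_2_gamma_prime", "se"): i.se_gamma_prime,
            ("criterion_2_gamma_prime", "p"): i.p_gamma_prime,
            ("criterion_3_total", "coefficient"): d.total_for_comparison,
            ("criterion_3_total", "se"): i.se_total,
            ("criterion_3_total", "p"): i.p_total,
            ("criterion_4_indirect", "coefficient"): d.indirect,
            ("criterion_4_indirect", "se"): d.se_indirect,
            ("criterion_4_indirect", "p_sobel"): d.p_sobel,
            ("verdict", ""): d.verdict,
        }
    table = pd.DataFrame(rows)
    num = table.drop(index=[("verdict", "")])
    table.loc[num.index] = num.apply(pd.to_numeric).round(digits)
    return table
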