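"""SNP-panel QC and haplotype machinery.

Genotypes are stored as minor-allele counts (0/1/2, -1 for missing) in an
``n_samples x n_snps`` integer matrix.  The module provides

* genotype coding for regression designs (dominant / additive / genotypic),
* a Pearson chi-square (1 df) test of Hardy-Weinberg equilibrium,
* pairwise linkage disequilibrium (D, D', r^2) via two-locus EM, and
* multi-locus haplotype-frequency estimation by EM over unphased genotypes,
  returning per-individual expected haplotype dosages for regression use.

The EM treats each individual's diplotype as latent: the E-step weights every
haplotype pair compatible with the observed multilocus genotype by the product
of current haplotype frequencies, the M-step re-estimates frequencies from
posterior-expected gamete counts.  The observed-data log-likelihood is
monotone non-decreasing across iterations, which the implementation tracks
and tests assert.  Initialization is the linkage-equilibrium product of
allele frequencies, so runs are deterministic; symmetric phase ambiguities
(e.g. a lone double heterozygote) resolve to the symmetric fixed point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, MissingDataError

MISSING = -1

#: EM stops when the log-likelihood improves by less than this.
EM_TOL = 1e-8
EM_MAX_ITER = 1000

#: diplotype enumeration is exponential in panel size; hard guard rail.
MAX_EM_SNPS = 10


@dataclass
class SnpPanel:
    """Ordered SNP panel with per-participant minor-allele counts.

    ``alleles[j] = (major, minor)`` for SNP j; ``genotypes[i, j]`` counts
    minor alleles for participant i (−1 = missing).  Participant order matches
    the cohort table.
    """

    ids: tuple[str, ...]
    alleles: tuple[tuple[str, str], ...]
    genotypes: np.ndarray
    samples: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.ids):
            raise ValueError("genotype matrix must be n_samples x n_snps")
        if not np.isin(self.genotypes, [MISSING, 0, 1, 2]).all():
            raise ValueError("genotypes must be in {0,1,2} or -1 for missing")
        for major, minor in self.alleles:
            if not major or not minor or major == minor:
                raise ValueError("allele labels must be nonempty and distinct")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.ids.index(snp_id)]

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP, ignoring missing genotypes."""
        out = np.empty(self.n_snps)
        for j in range(self.n_snps):
            g = self.genotypes[:, j]
            g = g[g != MISSING]
            out[j] = g.sum() / (2 * len(g)) if len(g) else np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes.astype(float), columns=list(self.ids))
        return df.mask(df < 0)


@dataclass
class HweResult:
    snp_id: str
    observed: tuple[int, int, int]  # (n_AA, n_Aa, n_aa), A = major allele
    expected: tuple[float, float, float]
    chi_square: float
    p_value: float
    monomorphic: bool = False


@dataclass
class LdResult:
    snp_a: str
    snp_b: str
    d: float | None
    d_prime: float | None
    r2: float | None
    reason: str | None = None


@dataclass
class HaplotypeEstimate:
    haplotypes: tuple[str, ...]
    frequencies: np.ndarray
    expected_dosage: np.ndarray  # n_complete_samples x n_haplotypes
    sample_index: np.ndarray  # rows of the panel used (complete cases)
    loglik_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = True

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies, index=list(self.haplotypes), name="frequency")


def code_genotype(genotypes: np.ndarray, model: str = "additive") -> np.ndarray:
    """Numeric design column(s) from minor-allele counts.

    dominant: 0 for major homozygote, 1 for any minor-allele carrier;
    additive: the minor-allele count itself;
    genotypic: two indicator columns (het, minor homozygote).
    Missing genotypes propagate as NaN.
    """
    g = np.asarray(genotypes, dtype=float)
    g[g == MISSING] = np.nan
    if model == "additive":
        return g
    if model == "dominant":
        out = (g > 0).astype(float)
        out[np.isnan(g)] = np.nan
        return out
    if model == "genotypic":
        het = (g == 1).astype(float)
        hom = (g == 2).astype(float)
        het[np.isnan(g)] = np.nan
        hom[np.isnan(g)] = np.nan
        return np.column_stack([het, hom])
    raise ValueError(f"unknown genotype model {model!r}")


def genotype_counts(genotypes: np.ndarray) -> tuple[int, int, int]:
    """(n_major_hom, n_het, n_minor_hom) ignoring missing values."""
    g = np.asarray(genotypes)
    g = g[g != MISSING]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def hwe_test(counts: tuple[int, int, int], snp_id: str = "") -> HweResult:
    """Pearson chi-square (1 df) test of Hardy-Weinberg proportions.

    ``counts`` are genotype counts (n_AA, n_Aa, n_aa) with A the major allele.
    Expected counts are N*(p^2, 2pq, q^2) with p estimated from the data.  A
    monomorphic SNP returns chi-square 0, p 1, flagged.
    """
    n_aa_maj, n_het, n_aa_min = (int(c) for c in counts)
    if min(counts) < 0:
        raise DomainError("genotype counts must be nonnegative")
    n = n_aa_maj + n_het + n_aa_min
    if n < 1:
        raise DomainError("hwe_test needs at least one genotyped participant")
    p = (2 * n_aa_maj + n_het) / (2 * n)
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    if q == 0.0 or p == 0.0:
        return HweResult(snp_id, (n_aa_maj, n_het, n_aa_min), expected, 0.0, 1.0, True)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(snp_id, (n_aa_maj, n_het, n_aa_min), expected, float(chi2), p_value)


def _complete_rows(genotypes: np.ndarray) -> np.ndarray:
    return np.where((genotypes != MISSING).all(axis=1))[0]


def _em_core(
    genotypes: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    """EM over unphased genotypes; haplotypes indexed by bitmask of minor alleles.

    Returns (frequencies over all 2^L haplotypes, dosage matrix, loglik trace,
    n_iter, converged).  Caller guarantees complete data.
    """
    n, loci = genotypes.shape
    if loci > MAX_EM_SNPS:
        raise DomainError(f"EM haplotype inference limited to {MAX_EM_SNPS} SNPs")
    n_hap = 1 << loci

    # compatible unordered haplotype pairs per distinct genotype vector
    uniq, inverse, counts = np.unique(
        genotypes, axis=0, return_inverse=True, return_counts=True
    )
    pair_table: list[list[tuple[int, int, int]]] = []
    for g in uniq:
        het = [j for j in range(loci) if g[j] == 1]
        base = sum(1 << j for j in range(loci) if g[j] == 2)
        pairs: list[tuple[int, int, int]] = []
        if not het:
            pairs.append((base, base, 1))
        else:
            anchor = het[0]  # fix the first het site to avoid double counting
            rest = het[1:]
            for assign in itertools.product((0, 1), repeat=len(rest)):
                h1 = base | (1 << anchor)
                h2 = base
                for j, a in zip(rest, assign):
                    if a:
                        h1 |= 1 << j
                    else:
                        h2 |= 1 << j
                pairs.append((h1, h2, 2))
        pair_table.append(pairs)

    # linkage-equilibrium start: product of per-locus allele frequencies
    maf = genotypes.mean(axis=0) / 2.0
    maf = np.clip(maf, 1e-6, 1 - 1e-6)
    freqs = np.ones(n_hap)
    for j in range(loci):
        bit = (np.arange(n_hap) >> j) & 1
        freqs *= np.where(bit, maf[j], 1 - maf[j])
    freqs /= freqs.sum()

    trace: list[float] = []
    converged = False
    it = 0
    post_cache: list[np.ndarray] = []
    for it in range(1, max_iter + 1):
        counts_acc = np.zeros(n_hap)
        loglik = 0.0
        post_cache = []
        for u, pairs in enumerate(pair_table):
            w = np.array([mult * freqs[h1] * freqs[h2] for h1, h2, mult in pairs])
            s = w.sum()
            if s <= 0:  # numerically extinct; re-seed uniformly over pairs
                w = np.ones(len(pairs))
                s = w.sum()
            post = w / s
            post_cache.append(post)
            loglik += counts[u] * np.log(s)
            for (h1, h2, _), p_ in zip(pairs, post):
                counts_acc[h1] += p_ * counts[u]
                counts_acc[h2] += p_ * counts[u]
        trace.append(float(loglik))
        new_freqs = counts_acc / (2 * n)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            freqs = new_freqs
            converged = True
            break
        freqs = new_freqs

    dosage = np.zeros((n, n_hap))
    for i in range(n):
        u = inverse[i]
        for (h1, h2, _), p_ in zip(pair_table[u], post_cache[u]):
            dosage[i, h1] += p_
            dosage[i, h2] += p_
    return freqs, dosage, trace, it, converged


def _hap_string(mask: int, alleles: tuple[tuple[str, str], ...]) -> str:
    return "".join(alleles[j][(mask >> j) & 1] for j in range(len(alleles)))


def em_haplotypes(
    panel: SnpPanel,
    *,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    min_frequency: float = 1e-10,
) -> HaplotypeEstimate:
    """EM haplotype-frequency estimation over the whole panel.

    Participants missing any panel SNP are excluded (complete-case).  The
    returned estimate lists haplotypes with frequency above ``min_frequency``
    (allele strings in panel SNP order), their frequencies, and each retained
    participant's expected dosage of each haplotype (posterior mean count,
    summing to 2 per participant up to the discarded mass).
    """
    rows = _complete_rows(panel.genotypes)
    if len(rows) < 1:
        raise MissingDataError("no participant has complete genotypes for the panel")
    geno = panel.genotypes[rows].astype(np.int64)
    freqs, dosage, trace, n_iter, converged = _em_core(geno, tol, max_iter)
    keep = np.where(freqs > min_frequency)[0]
    order = keep[np.argsort(-freqs[keep])]
    haps = tuple(_hap_string(int(h), panel.alleles) for h in order)
    return HaplotypeEstimate(
        haplotypes=haps,
        frequencies=freqs[order],
        expected_dosage=dosage[:, order],
        sample_index=rows,
        loglik_trace=trace,
        n_iterations=n_iter,
        converged=converged,
    )


def ld_pair(
    snp_a: np.ndarray,
    snp_b: np.ndarray,
    *,
    id_a: str = "A",
    id_b: str = "B",
) -> LdResult:
    """Pairwise LD (D, D', r^2) from unphased genotypes via two-locus EM.

    D is computed for the minor-minor haplotype: D = f_ab − q_a·q_b.  D' is
    |D| over its admissible maximum; r^2 is D^2 over the product of allele
    variances.  Monomorphic input yields a missing result with a reason.
    """
    g = np.column_stack([np.asarray(snp_a), np.asarray(snp_b)]).astype(np.int64)
    g = g[(g != MISSING).all(axis=1)]
    if len(g) < 2:
        return LdResult(id_a, id_b, None, None, None, "fewer than 2 complete pairs")
    qa = g[:, 0].mean() / 2.0
    qb = g[:, 1].mean() / 2.0
    if qa in (0.0, 1.0) or qb in (0.0, 1.0):
        return LdResult(id_a, id_b, None, None, None, "monomorphic SNP")
    freqs, _, _, _, _ = _em_core(g, EM_TOL, EM_MAX_ITER)
    # haplotype bitmask: bit0 = minor at A, bit1 = minor at B
    f_ab = freqs[0b11]
    qa_h = freqs[0b01] + freqs[0b11]
    qb_h = freqs[0b10] + freqs[0b11]
    d = f_ab - qa_h * qb_h
    if d >= 0:
        d_max = min(qa_h * (1 - qb_h), (1 - qa_h) * qb_h)
    else:
        d_max = min(qa_h * qb_h, (1 - qa_h) * (1 - qb_h))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    r2 = d * d / (qa_h * (1 - qa_h) * qb_h * (1 - qb_h))
    # clamp tiny numerical excursions outside [0, 1]
    return LdResult(id_a, id_b, float(d), float(min(d_prime, 1.0)), float(min(r2, 1.0)))


def hwe_report(panel: SnpPanel) -> pd.DataFrame:
    rows = []
    for j, snp_id in enumerate(panel.ids):
        res = hwe_test(genotype_counts(panel.genotypes[:, j]), snp_id)
        rows.append(
            {
                "snp": snp_id,
                "n_major_hom": res.observed[0],
                "n_het": res.observed[1],
                "n_minor_hom": res.observed[2],
                "chi_square": res.chi_square,
                "p_value": res.p_value,
                "monomorphic": res.monomorphic,
            }
        )
    return pd.DataFrame(rows)


def ld_report(panel: SnpPanel) -> pd.DataFrame:
    rows = []
    for j, k in itertools.combinations(range(panel.n_snps), 2):
        res = ld_pair(
            panel.genotypes[:, j],
            panel.genotypes[:, k],
            id_a=panel.ids[j],
            id_b=panel.ids[k],
        )
        rows.append(
            {
                "snp_a": res.snp_a,
                "snp_b": res.snp_b,
                "D": res.d,
                "D_prime": res.d_prime,
                "r2": res.r2,
                "note": res.reason or "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def panel_from_vcf(path: str | Path) -> SnpPanel:
    """Load a small SNP panel from a VCF; only the GT field is used.

    REF is taken as the major allele label and ALT as the minor; if the cohort
    allele frequency says otherwise the coding is flipped so genotype values
    always count the cohort-minor allele (ties keep the lexicographically
    smaller allele as major).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    ids: list[str] = []
    alleles: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{var.ID or var.POS}: only biallelic SNPs supported")
        gt = np.array(var.genotypes, dtype=object)
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(gt):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                col[i] = a + b
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        major, minor = var.REF, var.ALT[0]
        obs = col[col != MISSING]
        if len(obs):
            alt_freq = obs.sum() / (2 * len(obs))
            flip = alt_freq > 0.5 or (alt_freq == 0.5 and minor < major)
            if flip:
                col[col != MISSING] = 2 - col[col != MISSING]
                major, minor = minor, major
        alleles.append((major, minor))
        columns.append(col)
    return SnpPanel(tuple(ids), tuple(alleles), np.column_stack(columns), samples)


def panel_from_tsv(path: str | Path, sidecar: str | Path) -> SnpPanel:
    """Load genotypes from a TSV (columns per SNP, values 0/1/2/NA) plus a
    sidecar TSV with columns ``snp``, ``major``, ``minor``."""
    meta = pd.read_csv(sidecar, sep="\t", dtype=str)
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    ids = tuple(meta["snp"])
    missing_cols = [s for s in ids if s not in df.columns]
    if missing_cols:
        raise MissingDataError(f"genotype TSV lacks columns {missing_cols}")
    geno = df[list(ids)].to_numpy(dtype=float)
    out = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    samples = tuple(df["id"].astype(str)) if "id" in df.columns else None
    return SnpPanel(ids, tuple(zip(meta["major"], meta["minor"])), out, samples)


def panel_to_vcf(panel: SnpPanel, path: str | Path, *, chrom: str = "16", start_pos: int = 82_600_000) -> None:
    """Write the panel as a minimal uncompressed VCF 4.2 (GT only)."""
    samples = panel.samples or tuple(f"S{i+1}" for i in range(panel.n_samples))
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"##contig=<ID={chrom}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, snp_id in enumerate(panel.ids):
        major, minor = panel.alleles[j]
        gts = "\t".join(gt_code[int(g)] for g in panel.genotypes[:, j])
        lines.append(
            f"{chrom}\t{start_pos + 1000 * j}\t{snp_id}\t{major}\t{minor}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
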