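import numpy as np
import pytest
from scipy import stats

from medsuppress.errors import DomainError
from medsuppress.popgen import (
    SnpPanel,
    code_genotype,
    em_haplotypes,
    genotype_counts,
    hwe_test,
    ld_pair,
    panel_from_tsv,
    panel_from_vcf,
    panel_to_vcf,
)


def _panel(geno, n_snps=None):
    geno = np.atleast_2d(np.asarray(geno, dtype=np.int8))
    if geno.shape[0] == 1 and n_snps is None:
        geno = geno.T
    L = geno.shape[1]
    return SnpPanel(
        tuple(f"snp{j}" for j in range(L)),
        tuple([("G", "T")] * L),
        geno,
    )


class TestGenotypeCoding:
    def test_dominant_contrasts_major_homozygote_vs_carriers(self):
        assert list(code_genotype(np.array([0, 1, 2]), "dominant")) == [0.0, 1.0, 1.0]

    def test_additive_counts_minor_alleles(self):
        assert list(code_genotype(np.array([0, 1, 2]), "additive")) == [0.0, 1.0, 2.0]

    def test_genotypic_two_indicators(self):
        out = code_genotype(np.array([0, 1, 2]), "genotypic")
        assert out.tolist() == [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]

    def test_missing_propagates(self):
        out = code_genotype(np.array([0, -1, 2]), "dominant")
        assert np.isnan(out[1]) and out[2] == 1.0

    def test_degenerate_all_major_is_all_zero(self):
        assert not code_genotype(np.zeros(5, dtype=int), "dominant").any()


def _hwe_oracle(n_aa, n_het, n_bb):
    """Independent expected-count arithmetic for the Pearson HWE statistic."""
    n = n_aa + n_het + n_bb
    p = (2 * n_aa + n_het) / (2 * n)
    exp = [n * p**2, n * 2 * p * (1 - p), n * (1 - p) ** 2]
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n_aa, n_het, n_bb), exp))
    return chi2, stats.chi2.sf(chi2, 1)


class TestHwe:
    def test_exact_hwe_gives_zero_statistic(self):
        res = hwe_test((25, 50, 25))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_cohort_scale_counts(self):
        # genotype counts with a mild heterozygote pattern near equilibrium
        res = hwe_test((235, 229, 57))
        assert res.chi_square == pytest.approx(0.0119, abs=2e-3)
        assert res.p_value == pytest.approx(0.91, abs=0.01)
        assert sum(res.observed) == pytest.approx(sum(res.expected))

    def test_complete_heterozygote_deficit(self):
        res = hwe_test((10, 0, 10))
        assert res.chi_square == pytest.approx(20.0, abs=1e-9)
        assert res.p_value < 1e-4

    def test_monomorphic_flagged_not_error(self):
        res = hwe_test((12, 0, 0))
        assert res.monomorphic and res.chi_square == 0.0 and res.p_value == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            hwe_test((-1, 2, 3))

    def test_matches_bruteforce_oracle_on_random_counts(self, rng):
        for _ in range(1000):
            counts = tuple(int(c) for c in rng.integers(1, 400, size=3))
            res = hwe_test(counts)
            chi2, p = _hwe_oracle(*counts)
            assert res.chi_square == pytest.approx(chi2, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)


class TestLd:
    def test_identical_columns_in_complete_ld(self, rng):
        g = rng.integers(0, 3, size=200)
        res = ld_pair(g, g)
        assert res.r2 == pytest.approx(1.0, abs=1e-6)
        assert res.d_prime == pytest.approx(1.0, abs=1e-6)

    def test_independent_snps_have_near_zero_r2(self, rng):
        n = 10_000
        a = rng.binomial(2, 0.3, size=n)
        b = rng.binomial(2, 0.4, size=n)
        res = ld_pair(a, b)
        assert res.r2 < 0.005

    def test_monomorphic_reported_missing_with_reason(self):
        res = ld_pair(np.zeros(50, dtype=int), np.ones(50, dtype=int))
        assert res.r2 is None and "monomorphic" in res.reason

    def test_r2_le_dprime_le_one_on_random_panels(self, rng):
        for _ in range(30):
            n = 300
            # correlated pair via shared haplotype draws
            h = rng.random((n, 2)) < 0.35
            flip = rng.random((n, 2)) < rng.uniform(0, 0.3)
            a = h.sum(1)
            b = (h ^ flip).sum(1)
            res = ld_pair(a, b)
            if res.r2 is None:
                continue
            assert 0.0 <= res.r2 <= res.d_prime + 1e-9 <= 1.0 + 1e-9


class TestEmHaplotypes:
    def test_phase_unambiguous_equals_gamete_counting(self):
        # every individual has at most one heterozygous site -> no ambiguity
        geno = np.array(
            [[0, 0], [1, 0], [2, 0], [0, 1], [0, 2], [2, 2], [0, 0], [2, 0]]
        )
        est = em_haplotypes(_panel(geno))
        freqs = dict(zip(est.haplotypes, est.frequencies))
        # gametes counted by hand (G = major, T = minor; char j = SNP j)
        expected = {"GG": 6 / 16, "TG": 5 / 16, "GT": 3 / 16, "TT": 2 / 16}
        for hap, f_true in expected.items():
            assert freqs.get(hap, 0.0) == pytest.approx(f_true, abs=1e-6)
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_double_heterozygote_symmetric_fixed_point(self):
        est = em_haplotypes(_panel(np.array([[1, 1]]), n_snps=2))
        assert np.allclose(np.sort(est.frequencies), 0.25)

    def test_loglik_monotone_and_dosages_sum_to_two(self, default_cohort):
        _, _, panel = default_cohort
        est = em_haplotypes(panel)
        assert est.converged
        assert np.all(np.diff(est.loglik_trace) >= -1e-9)
        assert np.allclose(est.expected_dosage.sum(axis=1), 2.0, atol=1e-9)
        assert est.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_recovers_known_frequencies(self, rng):
        true = np.array([0.55, 0.33, 0.10, 0.02])
        haps = np.array([[0, 0, 0, 0], [1, 1, 1, 0], [0, 0, 1, 1], [1, 0, 0, 1]], dtype=np.int8)
        n = 500
        idx = rng.choice(4, size=(n, 2), p=true)
        geno = haps[idx[:, 0]] + haps[idx[:, 1]]
        est = em_haplotypes(_panel(geno, n_snps=4))
        strings = ["".join("T" if b else "G" for b in h) for h in haps]
        freqs = dict(zip(est.haplotypes, est.frequencies))
        for s, f_true in zip(strings, true):
            mc_se = np.sqrt(f_true * (1 - f_true) / (2 * n))
            assert abs(freqs.get(s, 0.0) - f_true) < 3 * mc_se + 1e-3

    def test_missing_rows_excluded(self):
        geno = np.array([[0, 0], [-1, 1], [2, 2]])
        est = em_haplotypes(_panel(geno, n_snps=2))
        assert list(est.sample_index) == [0, 2]
        assert est.expected_dosage.shape[0] == 2

    def test_guard_rail_on_panel_size(self, rng):
        geno = rng.integers(0, 3, size=(5, 11)).astype(np.int8)
        with pytest.raises(DomainError, match="limited"):
            em_haplotypes(_panel(geno, n_snps=11))


class TestPanelIO:
    def test_vcf_round_trip(self, tmp_path, default_cohort):
        _, _, panel = default_cohort
        path = tmp_path / "panel.vcf"
        panel_to_vcf(panel, path)
        back = panel_from_vcf(path)
        assert back.ids == panel.ids
        assert back.alleles == panel.alleles
        np.testing.assert_array_equal(back.genotypes, panel.genotypes)

    def test_tsv_round_trip(self, tmp_path, default_cohort):
        _, _, panel = default_cohort
        df = panel.to_frame()
        df.insert(0, "id", [f"S{i}" for i in range(panel.n_samples)])
        gpath, spath = tmp_path / "g.tsv", tmp_path / "meta.tsv"
        df.to_csv(gpath, sep="\t", index=False, na_rep="NA")
        with open(spath, "w") as fh:
            fh.write("snp\tmajor\tminor\n")
            for snp, (ma, mi) in zip(panel.ids, panel.alleles):
                fh.write(f"{snp}\t{ma}\t{mi}\n")
        back = panel_from_tsv(gpath, spath)
        np.testing.assert_array_equal(back.genotypes, panel.genotypes)

    def test_counts_ignore_missing(self):
        assert genotype_counts(np.array([0, 1, 2, -1, 1])) == (1, 2, 1)
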