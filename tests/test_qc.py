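"""QC cascade: subsampling, missingness/MAF arithmetic, HWE exact test, LD pruning."""

import numpy as np
import pytest

import breedgwas as bg
from breedgwas import qc
from breedgwas.errors import ConfigError, QCStageError

from conftest import toy_genotypes
from oracles import exact_hwe_p, naive_r2


class TestSubsample:
    def test_below_cap_retained_whole(self):
        g = toy_genotypes(np.zeros((25, 2)), breeds=["b"] * 25)
        out = qc.subsample_per_breed(g, cap=30, seed=0)
        assert out.n_samples == 25

    def test_above_cap_reduced_exactly(self):
        g = toy_genotypes(np.zeros((700, 2)), breeds=["lab"] * 700)
        out = qc.subsample_per_breed(g, cap=30, seed=0)
        assert out.n_samples == 30

    def test_counting_identity_over_breeds(self):
        counts = [4, 12, 30, 45, 700]
        breeds = [f"b{i}" for i, c in enumerate(counts) for _ in range(c)]
        g = toy_genotypes(np.zeros((sum(counts), 2)), breeds=breeds)
        out = qc.subsample_per_breed(g, cap=30, seed=1)
        assert out.n_samples == sum(min(30, c) for c in counts)

    def test_deterministic_per_seed(self):
        g = toy_genotypes(np.zeros((100, 2)), breeds=["b"] * 100)
        a = qc.subsample_per_breed(g, 30, seed=5).samples
        b = qc.subsample_per_breed(g, 30, seed=5).samples
        assert a.equals(b)


class TestMissingnessMaf:
    def test_missingness_arithmetic(self):
        d = np.zeros((20, 1))
        d[:3, 0] = np.nan
        g = toy_genotypes(d, breeds=["b"] * 20)
        assert qc.snp_missingness(g)[0] == pytest.approx(0.15)

    def test_maf_counts_alleles_over_chromosomes(self):
        g = toy_genotypes(np.array([[0.0], [0.0], [1.0]]), breeds=["b"] * 3)
        assert qc.snp_maf(g)[0] == pytest.approx(1 / 6)

    def test_monomorphic_maf_zero(self):
        g = toy_genotypes(np.zeros((10, 1)), breeds=["b"] * 10)
        assert qc.snp_maf(g)[0] == 0.0

    def test_all_missing_snp_flagged(self):
        g = toy_genotypes(np.full((5, 1), np.nan), breeds=["b"] * 5)
        assert np.isnan(qc.snp_maf(g)[0])
        assert qc.snp_missingness(g)[0] == 1.0


class TestHWE:
    def test_het_deficit_removed(self):
        """(5, 0, 5): total heterozygote deficiency in 10 samples."""
        p = qc.hwe_exact_test(5, 0, 5)
        assert p == pytest.approx(exact_hwe_p(5, 0, 5), abs=1e-12)
        assert p < 0.01

    def test_all_heterozygous_small_sample(self):
        p = qc.hwe_exact_test(0, 4, 0)
        assert p == pytest.approx(exact_hwe_p(0, 4, 0), abs=1e-12)

    def test_monomorphic_degenerate(self):
        assert qc.hwe_exact_test(17, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            qc.hwe_exact_test(-1, 2, 3)

    def test_matches_enumeration_exhaustively_small_n(self):
        """Agrees with the exact-fraction oracle for every triple with n <= 12."""
        for n in range(1, 13):
            for n1 in range(n + 1):
                for n2 in range(n - n1 + 1):
                    n3 = n - n1 - n2
                    assert qc.hwe_exact_test(n1, n2, n3) == pytest.approx(
                        exact_hwe_p(n1, n2, n3), abs=1e-10
                    ), (n1, n2, n3)


class TestLD:
    def test_identical_vectors_r2_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 40).astype(float)
        g = toy_genotypes(np.column_stack([x, x]), breeds=["b"] * 40)
        assert qc.ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_sign_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 40).astype(float)
        g = toy_genotypes(np.column_stack([x, 2 - x]), breeds=["b"] * 40)
        assert qc.ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_monomorphic_pair_undefined(self):
        x = np.zeros(10)
        y = np.arange(10) % 3
        g = toy_genotypes(np.column_stack([x, y]).astype(float), breeds=["b"] * 10)
        assert np.isnan(qc.ld_r2(g, 0, 1))

    def test_matches_naive_oracle(self):
        cfg = bg.SimulationConfig(
            n_breeds=4, samples_per_breed=12, n_snps=50, missing_rate=0.05, seed=5
        )
        g = bg.simulate_genotypes(cfg)
        maf = qc.snp_maf(g)
        cols = [j for j in range(g.n_snps) if maf[j] > 0][:50]
        for a in cols[:10]:
            for b in cols[10:20]:
                got = qc.ld_r2(g, a, b)
                want = naive_r2(g.dosages[:, a], g.dosages[:, b])
                assert got == pytest.approx(want, abs=1e-12)

    def test_null_mean_r2_near_one_over_n(self):
        """Independent SNPs: E[r^2] ~ 1/n under the null."""
        n = 1000
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, size=(n, 60)).astype(float)
        g = toy_genotypes(d, breeds=["b"] * n)
        vals = [qc.ld_r2(g, a, b) for a in range(30) for b in range(30, 60)]
        assert np.mean(vals) == pytest.approx(1 / n, rel=0.25)

    def test_prune_removes_later_of_pair(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 50).astype(float)
        y = rng.integers(0, 3, 50).astype(float)
        g = toy_genotypes(np.column_stack([x, y, x]), breeds=["b"] * 50)
        out, removed = qc.ld_prune(g, r2_max=0.9, window_snps=5)
        assert removed == ["s2"]
        assert list(out.snps["snp"]) == ["s0", "s1"]

    def test_pruned_output_has_no_offending_pair(self):
        cfg = bg.SimulationConfig(
            n_breeds=5, samples_per_breed=10, n_snps=120, duplicate_snps=15,
            missing_rate=0.0, seed=8,
        )
        g = bg.simulate_genotypes(cfg)
        out, _ = qc.ld_prune(g, r2_max=0.9, window_snps=10)
        chroms = out.snps["chrom"].to_numpy()
        for c in np.unique(chroms):
            cols = np.flatnonzero(chroms == c)
            for i_local, a in enumerate(cols):
                for b in cols[i_local + 1 : i_local + 10]:
                    r2 = qc.ld_r2(out, a, b)
                    assert not (r2 > 0.9)


class TestCascade:
    def test_sex_chromosome_snps_removed(self):
        g = toy_genotypes(
            np.tile([0.0, 1.0, 2.0, 1.0], (12, 1)),
            chroms=["1", "39", "X", "2"],
            breeds=["b1"] * 6 + ["b2"] * 6,
        )
        auto = g.is_autosomal()
        assert list(auto) == [True, False, False, True]

    def test_clean_cohort_prunes_only_planted_duplicates(self):
        """With no differentiation and no missingness, the cascade's only
        SNP removals are sex-chromosome SNPs and the planted duplicate pairs."""
        cfg = bg.SimulationConfig(
            n_breeds=8, samples_per_breed=25, n_snps=250, duplicate_snps=10,
            differentiation=0.0, missing_rate=0.0,
            ancestral_maf_range=(0.2, 0.5), seed=12,
        )
        g, _, truth = bg.simulate_cohort(cfg)
        out, report = bg.run_qc(g, bg.QCConfig(hwe_alpha=0.001, seed=1))
        stages = {s.name: s for s in report.stages}
        assert stages["missingness"].removed_snps == []
        assert stages["maf"].removed_snps == []
        assert stages["hwe"].removed_snps == []
        autosomal_dups = set(truth[truth["kind"] == "duplicate"]["snp"]) - set(
            stages["autosomes"].removed_snps
        )
        assert set(stages["ld_prune"].removed_snps) == autosomal_dups

    def test_report_telescopes(self, small_cohort):
        g = small_cohort[0]
        _, report = bg.run_qc(g, bg.QCConfig(seed=3))
        frame = report.to_frame()
        for k in range(1, len(frame)):
            assert frame.loc[k, "samples_in"] == frame.loc[k - 1, "samples_out"]
            assert frame.loc[k, "snps_in"] == frame.loc[k - 1, "snps_out"]

    def test_removed_snps_violate_their_stage_threshold(self, small_cohort):
        g = small_cohort[0]
        cfg = bg.QCConfig(seed=3)
        g1 = qc.subsample_per_breed(g, cfg.per_breed_cap, cfg.seed)
        g2 = g1.take_snps(np.flatnonzero(g1.is_autosomal()))
        _, report = bg.run_qc(g, cfg)
        stages = {s.name: s for s in report.stages}
        miss = qc.snp_missingness(g2)
        by_id = dict(zip(g2.snps["snp"], miss))
        for snp in stages["missingness"].removed_snps:
            assert by_id[snp] > cfg.max_missing

    def test_empty_stage_raises(self):
        g = toy_genotypes(np.tile([0.0, 1.0], (10, 1)), chroms=["39", "X"], breeds=["b"] * 10)
        with pytest.raises(QCStageError, match="autosomes"):
            bg.run_qc(g, bg.QCConfig(seed=0))

    def test_ten_percent_removal_accounting(self):
        assert qc.remove_fraction(1274, 0.10) == 1147
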