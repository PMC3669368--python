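"""Genotype simulators: HWE, correlation targeting, pools, and file I/O."""

import numpy as np
import pytest

import genepower as gp
from genepower.errors import ParameterError
from genepower.genotypes import correlation_bounds, read_vcf
from genepower.settests import pairwise_ld


def _mean_offdiag(values):
    r = np.corrcoef(values, rowvar=False)
    m = r.shape[0]
    return r[np.triu_indices(m, 1)].mean()


class TestIndependent:
    def test_maf_targeting_and_independence(self):
        g = gp.simulate_independent(1000, [0.05, 0.30], seed=42)
        se = np.sqrt(np.array([0.05, 0.30]) * np.array([0.95, 0.70]) / (2 * 1000))
        assert np.all(np.abs(g.empirical_mafs() - [0.05, 0.30]) < 4 * se)
        r = np.corrcoef(g.values, rowvar=False)[0, 1]
        assert abs(r) < 4 / np.sqrt(1000)

    def test_vanishing_maf_gives_zero_column(self):
        g = gp.simulate_independent(100, [1e-9], seed=0)
        assert (g.values == 0).all()

    def test_hwe_genotype_frequencies(self):
        # (1-m)^2, 2m(1-m), m^2 at m=0.30
        g = gp.simulate_independent(50_000, [0.30], seed=7)
        freqs = np.bincount(g.values[:, 0], minlength=3) / 50_000
        assert np.allclose(freqs, [0.49, 0.42, 0.09], atol=0.01)

    @pytest.mark.parametrize("n,mafs", [(0, [0.3]), (10, [0.0]), (10, [0.6])])
    def test_invalid_parameters_rejected(self, n, mafs):
        with pytest.raises(ParameterError):
            gp.simulate_independent(n, mafs, seed=0)


class TestExchangeableBlock:
    def test_zero_correlation_reduces_to_independent(self):
        g = gp.simulate_exchangeable_block(20_000, 0.30, 4, 0.0, seed=3)
        assert abs(_mean_offdiag(g.values)) < 0.02
        assert np.allclose(g.empirical_mafs(), 0.30, atol=0.01)

    @pytest.mark.parametrize("maf,m_snps,r,tol", [(0.30, 8, 0.9, 0.03),
                                                  (0.05, 4, 0.5, 0.05)])
    def test_correlation_targeting(self, maf, m_snps, r, tol):
        # empirical-correlation oracle averaged over 10 seeds
        vals = [
            _mean_offdiag(gp.simulate_exchangeable_block(4000, maf, m_snps, r,
                                                         seed=s).values)
            for s in range(10)
        ]
        assert abs(np.mean(vals) - r) < tol
        g = gp.simulate_exchangeable_block(4000, maf, m_snps, r, seed=99)
        se = np.sqrt(maf * (1 - maf) / (2 * 4000))
        assert np.all(np.abs(g.empirical_mafs() - maf) < 4 * se)

    def test_hwe_preserved_under_ld(self):
        g = gp.simulate_exchangeable_block(50_000, 0.30, 4, 0.9, seed=11)
        for j in range(4):
            freqs = np.bincount(g.values[:, j], minlength=3) / 50_000
            assert np.allclose(freqs, [0.49, 0.42, 0.09], atol=0.01)


class TestCausalAnchoredBlock:
    def test_anchor_and_member_correlations(self):
        # anchor-member correlation targets r, member pairs target r^2
        anchor_r, member_r = [], []
        for s in range(10):
            g = gp.simulate_causal_anchored_block(4000, 0.30, 4, 0.9, seed=s)
            r = np.corrcoef(g.values, rowvar=False)
            anchor_r.append(r[0, 1:].mean())
            member_r.append(r[1:, 1:][np.triu_indices(4, 1)].mean())
        assert abs(np.mean(anchor_r) - 0.9) < 0.03
        assert abs(np.mean(member_r) - 0.81) < 0.05

    def test_low_ld_member_correlation_is_rsquared(self):
        member_r = []
        for s in range(10):
            g = gp.simulate_causal_anchored_block(4000, 0.30, 4, 0.5, seed=s)
            r = np.corrcoef(g.values, rowvar=False)
            member_r.append(r[1:, 1:][np.triu_indices(4, 1)].mean())
        assert abs(np.mean(member_r) - 0.25) < 0.05

    def test_zero_correlation_gives_independence(self):
        g = gp.simulate_causal_anchored_block(20_000, 0.30, 3, 0.0, seed=1)
        assert np.all(np.abs(
            np.corrcoef(g.values, rowvar=False) - np.eye(4)) < 0.03)


class TestFeasibility:
    def test_equal_marginals_admit_high_correlation(self):
        assert gp.check_correlation_feasibility(0.3, 0.3, 0.9)

    def test_unequal_marginals_cap_correlation(self):
        # upper bound sqrt(0.05*0.70/(0.30*0.95)) ~ 0.35 < 0.9
        assert not gp.check_correlation_feasibility(0.05, 0.30, 0.9)
        _, upper = correlation_bounds(0.05, 0.30)
        assert upper == pytest.approx(np.sqrt(0.05 * 0.70 / (0.30 * 0.95)))

    @pytest.mark.parametrize("p1,p2", [(0.05, 0.3), (0.5, 0.5), (0.01, 0.99)])
    def test_independence_always_feasible(self, p1, p2):
        assert gp.check_correlation_feasibility(p1, p2, 0.0)

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ParameterError):
            gp.simulate_exchangeable_block(100, 0.3, 4, 1.0, seed=0)
        with pytest.raises(ParameterError):
            gp.simulate_causal_anchored_block(100, 0.3, 4, -0.2, seed=0)


class TestHaplotypePool:
    def test_degenerate_single_haplotype(self):
        pool = gp.HaplotypePool(np.ones((1, 5), dtype=np.int8), [1.0],
                                np.arange(5) * 100, (100, 300))
        g = gp.sample_from_pool(pool, 50, seed=0)
        assert (g.values == 2).all()

    def test_two_complementary_haplotypes(self):
        haps = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8)
        pool = gp.HaplotypePool(haps, [0.5, 0.5], [1, 2, 3], (1, 3))
        g = gp.sample_from_pool(pool, 20_000, seed=4)
        assert np.allclose(g.empirical_mafs(), 0.5, atol=0.02)
        r = np.corrcoef(g.values, rowvar=False)
        assert np.all(np.abs(np.abs(r)) > 0.99)  # perfect haplotype-level LD

    def test_sampled_mafs_match_pool_implied(self, realistic_pool):
        g = gp.sample_from_pool(realistic_pool, 2000, seed=5)
        implied = realistic_pool.implied_mafs()
        se = np.sqrt(implied * (1 - implied) / (2 * 2000))
        assert np.all(np.abs(g.empirical_mafs() - implied) < 4 * se)

    def test_file_round_trip(self, realistic_pool, tmp_path):
        path = tmp_path / "pool.txt"
        realistic_pool.to_file(path)
        back = gp.HaplotypePool.from_file(path)
        assert np.array_equal(back.haplotypes, realistic_pool.haplotypes)
        assert np.allclose(back.frequencies, realistic_pool.frequencies)
        assert back.gene_interval == realistic_pool.gene_interval
        assert np.array_equal(back.causal_indices, realistic_pool.causal_indices)


class TestRealisticFixture:
    def test_composition(self, realistic_pool):
        pos = realistic_pool.positions
        start, stop = realistic_pool.gene_interval
        intra = (pos >= start) & (pos <= stop)
        assert intra.sum() == 33
        assert (pos < start).sum() == 23
        assert (pos > stop).sum() == 24
        causal = realistic_pool.causal_indices
        assert len(causal) == 6
        assert intra[causal].sum() == 4  # 4 intragenic + 2 intergenic causal
        assert (~intra[causal]).sum() == 2

    def test_maf_band(self, realistic_pool):
        mafs = realistic_pool.implied_mafs()
        assert mafs.min() >= 0.06 and mafs.max() <= 0.50

    def test_determinism(self, realistic_pool):
        again = gp.make_realistic_fixture(seed=0)
        assert np.array_equal(again.haplotypes, realistic_pool.haplotypes)
        assert np.allclose(again.frequencies, realistic_pool.frequencies)

    def test_ld_block_crosses_gene_boundary(self, realistic_pool):
        # a multi-SNP block with pairwise r^2 > 0.5 straddling the gene stop
        g = gp.sample_from_pool(realistic_pool, 4000, seed=6)
        pos = realistic_pool.positions
        stop = realistic_pool.gene_interval[1]
        block = np.arange(52, 60)
        assert pos[block].min() < stop < pos[block].max()
        r2 = pairwise_ld(g).r2[np.ix_(block, block)]
        assert r2[np.triu_indices(len(block), 1)].min() > 0.5


class TestDeterminismAndIO:
    @pytest.mark.parametrize("sim", [
        lambda s: gp.simulate_independent(200, [0.1, 0.4], seed=s),
        lambda s: gp.simulate_exchangeable_block(200, 0.2, 3, 0.5, seed=s),
        lambda s: gp.simulate_causal_anchored_block(200, 0.2, 3, 0.5, seed=s),
    ])
    def test_seed_determinism(self, sim):
        assert np.array_equal(sim(17).values, sim(17).values)
        assert not np.array_equal(sim(17).values, sim(18).values)

    def test_genotype_tsv_round_trip(self, tmp_path):
        g = gp.simulate_independent(50, [0.2, 0.4], seed=9)
        path = tmp_path / "geno.tsv"
        gp.genotypes.write_genotype_tsv(g, path)
        back = gp.genotypes.read_genotype_tsv(path)
        assert np.array_equal(back.values, g.values)
        assert back.snp_ids == ["snp1", "snp2"]

    def test_vcf_read(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t0/0\t0/0\n"
        )
        g = read_vcf(vcf)
        assert g.values.tolist() == [[0, 1], [1, 0], [2, 0]]
        assert g.snp_ids == ["rs1", "rs2"]
        assert g.positions.tolist() == [100, 200]

    def test_vcf_multiallelic_rejected(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(ParameterError):
            read_vcf(vcf)
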