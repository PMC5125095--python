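"""Haplotype strategy: LD, block partitioning, EM phasing, block tests."""

import numpy as np
import pandas as pd
import pytest

from multigwas import hapblock, mlm, simdata
from multigwas.containers import SNP_COLUMNS, GenotypeMatrix, VarianceComponents

from oracles import two_snp_em_grid_loglik, two_snp_loglik_from_freqs


def matrix_from(dosages, pos=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "G",
        },
        columns=SNP_COLUMNS,
    )
    return GenotypeMatrix(dosages, [f"i{i}" for i in range(n)], snps)


class TestBlockLength:
    @pytest.mark.parametrize(
        "start, end, expected",
        [
            (38704872, 38707716, 2844),
            (38711873, 38734752, 22879),
            (38735901, 38736441, 540),
            (38737206, 38837159, 99953),
            (89890121, 89893239, 3118),
            (1000, 1001, 1),
        ],
    )
    def test_end_minus_start(self, start, end, expected):
        assert hapblock.block_length(start, end) == expected

    def test_inverted_coordinates_rejected(self):
        with pytest.raises(ValueError):
            hapblock.block_length(100, 100)


class TestPairwiseLd:
    def test_snp_with_itself_is_perfect(self, rng):
        g = rng.binomial(2, 0.4, size=4000)
        ld = hapblock.pairwise_ld(g, g)
        assert ld.r2 == pytest.approx(1.0, abs=1e-9)
        assert abs(ld.dprime) == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps_show_no_ld(self, rng):
        gA = rng.binomial(2, 0.5, size=5000)
        gB = rng.binomial(2, 0.5, size=5000)
        assert hapblock.pairwise_ld(gA, gB).r2 < 0.01

    def test_monomorphic_pair_flagged_undefined(self):
        g = np.ones(100, dtype=int)
        h = np.random.default_rng(0).binomial(2, 0.3, 100)
        assert not hapblock.pairwise_ld(g, h).defined

    def test_em_recovers_known_founder_frequencies(self):
        pool = np.array([[0, 0], [1, 1]], dtype=np.int8)
        cfg = simdata.SimConfig(
            n_samples=5000, n_blocks=1, snps_per_block=2, seed=5,
            founder_pools=[pool], founder_freqs=[np.array([0.7, 0.3])],
        )
        G, _ = simdata.simulate_genotypes(cfg)
        ld = hapblock.pairwise_ld(G.dosages[:, 0], G.dosages[:, 1])
        # D = pAB - pA pB with hap freqs (0.7, 0, 0, 0.3) -> r2 = 1
        assert ld.r2 == pytest.approx(1.0, abs=0.01)
        assert ld.dprime == pytest.approx(1.0, abs=0.01)

    def test_r2_matches_plugin_formula_at_moderate_ld(self):
        # founders giving partial LD: haplotypes 00, 01, 11
        pool = np.array([[0, 0], [0, 1], [1, 1]], dtype=np.int8)
        freqs = np.array([0.5, 0.2, 0.3])
        cfg = simdata.SimConfig(
            n_samples=8000, n_blocks=1, snps_per_block=2, seed=8,
            founder_pools=[pool], founder_freqs=[freqs],
        )
        G, _ = simdata.simulate_genotypes(cfg)
        ld = hapblock.pairwise_ld(G.dosages[:, 0], G.dosages[:, 1])
        pA, pB = 0.3, 0.5  # derived-allele freqs at the two SNPs
        D = 0.3 - pA * pB  # pAB = freq(hap 11)
        r2_true = D**2 / (pA * (1 - pA) * pB * (1 - pB))
        assert ld.r2 == pytest.approx(r2_true, abs=0.02)


class TestPartitionBlocks:
    def test_planted_pair_recovered_among_equilibrium_snps(self, rng):
        n = 2000
        cols = [rng.binomial(2, 0.5, n) for _ in range(2)]
        core = rng.binomial(1, 0.4, (n, 2)).sum(axis=1)
        cols += [core, core]  # perfect-LD pair
        cols += [rng.binomial(2, 0.5, n) for _ in range(2)]
        pos = np.array([1000, 30000, 60000, 61000, 90000, 120000])
        G = matrix_from(np.column_stack(cols), pos=pos)
        blocks = hapblock.partition_blocks(G, window_kb=100)
        assert len(blocks) == 1
        assert blocks[0].snp_ids == ["s2", "s3"]
        assert blocks[0].length_bp == 1000

    def test_window_cap_prevents_long_range_merge(self, rng):
        core = rng.binomial(1, 0.4, (3000, 2)).sum(axis=1)
        G = matrix_from(
            np.column_stack([core, core]), pos=np.array([1000, 151000])
        )
        assert hapblock.partition_blocks(G, window_kb=100) == []

    def test_unsorted_positions_rejected(self, rng):
        d = rng.binomial(2, 0.5, size=(100, 2))
        G = matrix_from(d, pos=np.array([5000, 1000]))
        with pytest.raises(ValueError, match="not position-sorted"):
            hapblock.partition_blocks(G)

    def test_simulated_boundaries_recovered(self):
        cfg = simdata.SimConfig(n_samples=2000, n_blocks=15, seed=11)
        G, truth = simdata.simulate_genotypes(cfg)
        blocks = hapblock.partition_blocks(G, window_kb=100)
        pos_to_idx = {
            (c, p): i
            for i, (c, p) in enumerate(zip(G.snps["chrom"], G.snps["pos"]))
        }
        hits = 0
        for rec in truth.block_bounds.itertuples(index=False):
            ts = pos_to_idx[(rec.chrom, rec.start)]
            te = pos_to_idx[(rec.chrom, rec.end)]
            for b in blocks:
                if b.chrom != rec.chrom:
                    continue
                bs = pos_to_idx[(b.chrom, b.start)]
                be = pos_to_idx[(b.chrom, b.end)]
                if abs(bs - ts) <= 1 and abs(be - te) <= 1:
                    hits += 1
                    break
        assert hits / len(truth.block_bounds) >= 0.9


class TestEmPhase:
    def test_all_homozygous_is_exact(self):
        d = np.array([[0, 0], [2, 2], [2, 2], [0, 0]], dtype=np.int8)
        blk = hapblock.em_phase(matrix_from(d))
        assert sorted(blk.haplotypes) == ["AA", "GG"]
        np.testing.assert_allclose(np.sort(blk.frequencies), [0.5, 0.5])
        assert np.all(blk.posteriors == 1.0)

    def test_single_snp_frequencies_equal_allele_frequencies(self, rng):
        d = rng.binomial(2, 0.3, size=(500, 1)).astype(np.int8)
        blk = hapblock.em_phase(matrix_from(d))
        p = d.mean() / 2
        freq_alt = dict(zip(blk.haplotypes, blk.frequencies)).get("A", 0.0)
        assert freq_alt == pytest.approx(p, abs=1e-9)

    def test_em_beats_grid_search_on_double_het_mixture(self):
        # mixture with double heterozygotes: EM likelihood must match the
        # best of a 101-point grid over the cis-coupling fraction
        pool = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        freqs = np.array([0.4, 0.15, 0.1, 0.35])
        cfg = simdata.SimConfig(
            n_samples=400, n_blocks=1, snps_per_block=2, seed=21,
            founder_pools=[pool], founder_freqs=[freqs],
        )
        G, _ = simdata.simulate_genotypes(cfg)
        blk = hapblock.em_phase(G, check_monotone=True)
        counts = np.zeros((3, 3))
        np.add.at(counts, (G.dosages[:, 0], G.dosages[:, 1]), 1.0)
        grid_ll = max(
            two_snp_em_grid_loglik(counts, c) for c in np.linspace(0, 1, 101)
        )
        m = dict(zip(blk.haplotypes, blk.frequencies))
        # hap strings use 'A' for the counted allele, 'G' otherwise
        f_em = [m.get("AA", 0.0), m.get("AG", 0.0), m.get("GA", 0.0), m.get("GG", 0.0)]
        em_ll = two_snp_loglik_from_freqs(counts, np.array(f_em))
        assert em_ll >= grid_ll - 1e-6
        # and the fitted frequencies sit within grid resolution of the best
        assert em_ll - grid_ll < 0.5

    def test_frequencies_sum_to_one_after_pruning(self):
        cfg = simdata.SimConfig(n_samples=300, n_blocks=1, snps_per_block=6,
                                founder_haplotypes_per_block=5, seed=33)
        G, _ = simdata.simulate_genotypes(cfg)
        blk = hapblock.em_phase(G)
        assert blk.frequencies.sum() == pytest.approx(1.0, abs=1e-6)
        assert blk.hap_dosages.sum(axis=1) == pytest.approx(2.0, abs=1e-6)

    def test_phasing_recovers_founder_pool(self):
        cfg = simdata.SimConfig(n_samples=1000, n_blocks=1, seed=44)
        G, truth = simdata.simulate_genotypes(cfg)
        blk = hapblock.em_phase(G)
        pool_strings = {
            "".join("A" if b else "G" for b in h) for h in truth.founder_pools[0]
        }
        est = dict(zip(blk.haplotypes, blk.frequencies))
        common = {h for h, f in est.items() if f > 0.02}
        assert common <= pool_strings
        true_freqs = {}
        for h, f in zip(truth.founder_pools[0], truth.founder_freqs[0]):
            s = "".join("A" if b else "G" for b in h)
            true_freqs[s] = true_freqs.get(s, 0.0) + f
        for h in common:
            assert est[h] == pytest.approx(true_freqs[h], abs=0.05)

    def test_enumeration_bound_enforced(self, rng):
        d = rng.binomial(2, 0.5, size=(10, 30)).astype(np.int8)
        with pytest.raises(ValueError, match="split the block"):
            hapblock.em_phase(matrix_from(d))


class TestBlockAssoc:
    def test_null_block_p_roughly_uniform(self):
        import warnings

        cfg = simdata.SimConfig(n_samples=300, n_blocks=30, seed=55)
        G, truth = simdata.simulate_genotypes(cfg)
        K = mlm.compute_kinship(G, seed=0)
        blk = hapblock.em_phase(G.take_snps(np.arange(5)))
        rng_ = np.random.default_rng(56)
        ps = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(60):
                y = rng_.normal(0.98, 0.16, size=300)
                W = np.ones((300, 1))
                vc = mlm.reml_variance_components(y, W, K)
                ps.append(hapblock.block_assoc(y, W, blk, K, vc).p)
        ps = np.array(ps)
        # max-|effect| selection makes the 1-df reference conservative at
        # the tail but P should still spread over (0, 1]
        assert 0.2 < np.mean(ps) < 0.85
        assert np.min(ps) > 1e-4

    def test_monomorphic_block_degenerate(self):
        d = np.zeros((50, 2), dtype=np.int8)
        blk = hapblock.em_phase(matrix_from(d))
        res = hapblock.block_assoc(
            np.random.default_rng(0).normal(size=50),
            np.ones((50, 1)),
            blk,
            mlm.compute_kinship(matrix_from(np.random.default_rng(1).binomial(2, .4, (50, 10)).astype(np.int8))),
            VarianceComponents(0.1, 0.9, 0.1, 0.0),
        )
        assert res.degenerate and res.p == 1.0

    def test_strong_planted_haplotype_detected(self):
        freqs = [np.array([0.60, 0.06, 0.17, 0.17])] + [None] * 59
        cfg = simdata.SimConfig(
            n_samples=1000, n_blocks=60, seed=66, founder_freqs=freqs,
            causal_spec=(simdata.CausalEffect("haplotype", 0, 1, 0.45),),
        )
        G, truth = simdata.simulate_genotypes(cfg)
        pheno = simdata.simulate_phenotype(G, truth, cfg)
        y = pheno["adg"].to_numpy()
        K = mlm.compute_kinship(G, seed=0)
        W = mlm.design_matrix(pheno)
        vc = mlm.reml_variance_components(y, W, K)
        blk = hapblock.em_phase(G.take_snps(np.arange(5)))
        res = hapblock.block_assoc(y, W, blk, K, vc)
        assert res.p < 1e-5
        assert abs(res.beta) == pytest.approx(0.45, abs=0.15)

    def test_perfect_ld_pair_equals_snp_scan(self):
        # a 2-SNP block in perfect LD carries exactly one SNP's information
        pool = np.array([[0, 0], [1, 1]], dtype=np.int8)
        cfg = simdata.SimConfig(
            n_samples=500, n_blocks=12, seed=77,
            founder_pools=[pool] * 12,
            founder_freqs=[np.array([0.6, 0.4])] * 12,
            snps_per_block=2,
        )
        G, truth = simdata.simulate_genotypes(cfg)
        pheno = simdata.simulate_phenotype(G, truth, cfg)
        y = pheno["adg"].to_numpy()
        K = mlm.compute_kinship(G, seed=0)
        W = mlm.design_matrix(pheno)
        vc = mlm.reml_variance_components(y, W, K)
        blk = hapblock.em_phase(G.take_snps([0, 1]))
        block_res = hapblock.block_assoc(y, W, blk, K, vc)
        snp_res = mlm.snp_scan(y, W, G.take_snps([0]), K, vc)[0]
        assert block_res.chi2 == pytest.approx(snp_res.chi2, abs=1e-6)


class TestBlockVarianceExplained:
    def _phased_two_hap_block(self, n=600, q=0.5, beta=0.12, seed=0):
        pool = np.array([[0, 0], [1, 1]], dtype=np.int8)
        cfg = simdata.SimConfig(
            n_samples=n, n_blocks=1, snps_per_block=2, seed=seed,
            founder_pools=[pool], founder_freqs=[np.array([1 - q, q])],
        )
        G, truth = simdata.simulate_genotypes(cfg)
        blk = hapblock.em_phase(G)
        rng_ = np.random.default_rng(seed + 1)
        carrier = (truth.hap_indices[:, 0, :] == 1).sum(axis=1)
        y = 0.98 + beta * carrier + rng_.normal(0, 0.1, n)
        return blk, y, carrier

    def test_biallelic_equivalence_with_snp_formula(self):
        from multigwas.mlm import snp_variance_explained

        blk, y, carrier = self._phased_two_hap_block()
        sigma_p2 = float(np.var(y))
        out = hapblock.block_variance_explained(y, blk, sigma_p2)
        xc = carrier - carrier.mean()
        beta_hat = float(xc @ (y - y.mean()) / (xc @ xc))
        q_hat = float(blk.frequencies[[h != blk.haplotypes[0] for h in blk.haplotypes]].sum())
        expected = snp_variance_explained(1 - q_hat, q_hat, beta_hat, sigma_p2)
        assert out.value == pytest.approx(expected, abs=1e-9)

    def test_null_effects_give_zero(self):
        blk, y, _ = self._phased_two_hap_block(beta=0.0, seed=5)
        rng_ = np.random.default_rng(9)
        y = rng_.normal(size=y.size)
        out = hapblock.block_variance_explained(y, blk, float(np.var(y)))
        assert out.value < 0.02

    def test_three_haplotype_two_step_matches_hand_oracle(self):
        # planted effects {0, 0.01, 0.40}: two-means must split {0, .01} | {.40}
        pool = np.array([[0, 0], [0, 1], [1, 1]], dtype=np.int8)
        freqs = np.array([0.5, 0.3, 0.2])
        cfg = simdata.SimConfig(
            n_samples=2000, n_blocks=1, snps_per_block=2, seed=91,
            founder_pools=[pool], founder_freqs=[freqs],
        )
        G, truth = simdata.simulate_genotypes(cfg)
        blk = hapblock.em_phase(G)
        effects = {0: 0.0, 1: 0.01, 2: 0.40}
        rng_ = np.random.default_rng(92)
        idx = truth.hap_indices[:, 0, :]
        y = 0.98 + np.vectorize(effects.get)(idx).sum(axis=1) + rng_.normal(0, 0.05, 2000)
        sigma_p2 = float(np.var(y))
        out = hapblock.block_variance_explained(y, blk, sigma_p2)
        # hand-run oracle: G2 = carriers of founder 2; indicator = copy count
        g2_count = (idx == 2).sum(axis=1).astype(float)
        xc = g2_count - g2_count.mean()
        beta = float(xc @ (y - y.mean()) / (xc @ xc))
        q = 0.2
        expected = 2 * q * (1 - q) * beta**2 / sigma_p2
        assert out.value == pytest.approx(expected, rel=0.1)

    def test_identical_effects_flagged_degenerate(self):
        blk, y, _ = self._phased_two_hap_block(seed=7)
        # constant phenotype -> identical (zero) effect estimates
        out = hapblock.block_variance_explained(np.ones(y.size), blk, 1.0)
        assert out.degenerate and out.value == 0.0
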