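"""Quality-control operations against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxemig.qc import (
    QcReport, QcThresholds, compute_pcs, heterozygosity_outliers,
    hwe_chi2_test, hwe_exact_test, ibd_filter, iterative_missingness_filter,
    ld_prune, pi_hat_matrix, run_qc,
)
from gxemig.synthetic_cohort import BlockSpec, CohortConfig, simulate_cohort, simulate_genotypes
from conftest import make_genotypes


def hwe_exact_oracle(n_AA, n_Aa, n_aa):
    """Direct enumeration with exact rational arithmetic: probability of
    each heterozygote count conditional on allele counts, via math.comb."""
    n = n_AA + n_Aa + n_aa
    n_a = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    probs = {}
    denom = math.comb(2 * n, n_a)
    for h in range(n_a % 2, n_a + 1, 2):
        hom_rare = (n_a - h) // 2
        hom_common = n - h - hom_rare
        # multinomial count of genotype configurations x 2^h phasings
        probs[h] = (math.comb(n, hom_rare) * math.comb(n - hom_rare, h)
                    * 2**h) / denom
    obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


class TestHwe:
    def test_perfect_proportions(self):
        assert hwe_chi2_test(25, 50, 25) == pytest.approx(1.0)
        assert hwe_exact_test(25, 50, 25) == pytest.approx(
            hwe_exact_oracle(25, 50, 25))

    def test_total_het_deficit_is_extreme(self):
        assert hwe_exact_test(50, 0, 50) < 1e-5

    def test_monomorphic(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @pytest.mark.parametrize("counts", [
        (5, 10, 5), (12, 2, 1), (0, 7, 13), (20, 20, 10), (3, 1, 0),
        (10, 25, 15), (1, 1, 1), (0, 50, 0),
    ])
    def test_exact_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_exact_oracle(*counts), rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 20), st.integers(0, 20),
                     st.integers(0, 20)).filter(lambda c: sum(c) > 0))
    def test_exact_p_in_unit_interval_and_matches_oracle(self, counts):
        p = hwe_exact_test(*counts)
        assert 0 < p <= 1
        assert p == pytest.approx(hwe_exact_oracle(*counts), rel=1e-9)


class TestMissingness:
    def test_fully_observed_unchanged(self):
        G = make_genotypes(np.ones((4, 3)))
        G2, rep = iterative_missingness_filter(G)
        assert G2.n_snps == 3 and G2.n_individuals == 4
        assert rep.total_snps_removed == 0

    def test_snp_removed_at_first_step(self):
        dos = np.ones((10, 3))
        dos[:2, 0] = np.nan          # SNP 0: 20% missing
        G2, rep = iterative_missingness_filter(make_genotypes(dos))
        assert list(G2.snp_ids) == ["s1", "s2"]
        assert rep.steps[0]["snps_removed"] == 1

    def test_individual_removed_after_snp_removal(self):
        # Hand-computed 100x31 matrix: SNP 0 is 30% missing and is dropped
        # at the 0.1 step.  Individual 0 is then missing 2 of the 30
        # remaining SNPs (6.7%): it survives the 0.1 step but falls at
        # 0.05, where each of those SNPs (2% missing) survives.
        dos = np.ones((100, 31))
        dos[:30, 0] = np.nan
        dos[0, 1] = np.nan
        dos[0, 2] = np.nan
        dos[1, 3] = np.nan
        G2, rep = iterative_missingness_filter(make_genotypes(dos))
        assert "s0" not in G2.snp_ids
        assert "i0" not in G2.individual_ids
        # s1/s2 are rescued by i0's removal; s3 (1/99 = 1.01% missing)
        # falls at the final 0.01 step.
        assert {"s1", "s2"} <= set(G2.snp_ids)
        assert "s3" not in G2.snp_ids
        by_name = {s["step"]: s for s in rep.steps}
        assert by_name["missingness<= 0.1"]["snps_removed"] == 1
        assert by_name["missingness<= 0.1"]["individuals_removed"] == 0
        assert by_name["missingness<= 0.05"]["individuals_removed"] == 1

    def test_empty_result_raises(self):
        dos = np.full((3, 2), np.nan)
        with pytest.raises(ValueError, match="empty"):
            iterative_missingness_filter(make_genotypes(dos))


def brute_force_prune(dosages, maf, positions, r2_max):
    """Independent re-statement of the pruning rule on one window."""
    active = list(range(dosages.shape[1]))
    while True:
        corr = np.corrcoef(dosages.T) ** 2
        for a, b in itertools.combinations(range(len(active)), 2):
            i, j = active[a], active[b]
            if corr[i, j] > r2_max:
                if (maf[i], -positions[i]) < (maf[j], -positions[j]):
                    active.remove(i)
                else:
                    active.remove(j)
                break
        else:
            return active


class TestLdPrune:
    def test_identical_snps_keep_one(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
        G = make_genotypes(np.column_stack([col, col]))
        assert len(ld_prune(G, 0.2)) == 1

    def test_uncorrelated_all_survive(self, null_genotypes):
        sub = null_genotypes.subset(snps=np.arange(20))
        assert len(ld_prune(sub, 0.99)) == 20

    def test_matches_brute_force_on_hand_matrix(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 3, 60).astype(float)
        noisy = base.copy(); noisy[:12] = rng.integers(0, 3, 12)
        other = rng.integers(0, 3, 60).astype(float)
        other2 = other.copy(); other2[:10] = rng.integers(0, 3, 10)
        indep = rng.integers(0, 3, 60).astype(float)
        dos = np.column_stack([base, noisy, other, other2, indep])
        G = make_genotypes(dos)
        maf = np.minimum(G.allele_frequencies(), 1 - G.allele_frequencies())
        expected = brute_force_prune(dos, maf, G.snp_meta["pos"].to_numpy(), 0.2)
        assert ld_prune(G, 0.2) == [f"s{j}" for j in expected]

    def test_survivors_below_threshold(self, null_genotypes):
        ids = ld_prune(null_genotypes, 0.2, window=50, step=5)
        sub = null_genotypes.select_snps(ids[:50])
        r2 = np.corrcoef(sub.dosages.T) ** 2
        np.fill_diagonal(r2, 0)
        assert r2.max() <= 0.2 + 1e-12


class TestIbd:
    def test_duplicate_detected_and_removed(self):
        # π̂ noise scales as 1/sqrt(m): use a 1000-SNP panel so unrelated
        # pairs stay clear of the threshold.
        cfg = CohortConfig(n_per_population=(100, 100), seed=19,
                           missing_rate=0.0, stratification_divergence=0.0)
        G = simulate_genotypes([BlockSpec(1000, (0.1, 0.4), 0.0)], cfg)
        G.dosages[1, :] = G.dosages[0, :]
        assert pi_hat_matrix(G)[0, 1] > 0.95
        removed = ibd_filter(G)
        assert len(removed) == 1 and removed[0] in (
            str(G.individual_ids[0]), str(G.individual_ids[1]))

    def test_unrelated_none_removed(self):
        cfg = CohortConfig(n_per_population=(100, 100), seed=11,
                           missing_rate=0.0, stratification_divergence=0.0)
        G = simulate_genotypes([BlockSpec(1000, (0.1, 0.4), 0.0)], cfg)
        assert ibd_filter(G) == []

    def test_parent_offspring_half(self):
        cfg = CohortConfig(n_per_population=(100, 100), seed=13,
                           missing_rate=0.0, stratification_divergence=0.0)
        G = simulate_genotypes([BlockSpec(1000, (0.2, 0.4), 0.0)], cfg)
        rng = np.random.default_rng(17)
        parent = G.dosages[0]
        freqs = G.allele_frequencies()
        transmitted = np.where(parent == 1,
                               rng.integers(0, 2, G.n_snps), parent / 2)
        child = transmitted + (rng.random(G.n_snps) < freqs)
        G.dosages[5, :] = child
        assert pi_hat_matrix(G)[0, 5] == pytest.approx(0.5, abs=0.07)

    def test_fewer_than_two_individuals(self, null_genotypes):
        single = null_genotypes.subset(individuals=np.arange(1))
        assert ibd_filter(single) == []


class TestHeterozygosity:
    def test_identical_individuals_none_flagged(self):
        G = make_genotypes(np.tile([0, 1, 2, 1], (20, 1)))
        assert heterozygosity_outliers(G) == []

    def test_all_het_individual_flagged(self, null_genotypes):
        G = null_genotypes.subset()
        G.dosages[3, :] = 1.0
        assert str(G.individual_ids[3]) in heterozygosity_outliers(G)

    def test_infinite_threshold_flags_nothing(self, null_genotypes):
        assert heterozygosity_outliers(null_genotypes, np.inf) == []


class TestPca:
    def test_pc1_separates_divergent_populations(self):
        cfg = CohortConfig(n_per_population=(200, 200), seed=3,
                           missing_rate=0.0, stratification_divergence=0.1)
        G = simulate_genotypes([BlockSpec(500, (0.1, 0.4), 0.0)], cfg)
        pcs = compute_pcs(G, 2)
        pop = np.array([0] * 200 + [1] * 200)
        r = np.corrcoef(pcs[:, 0], pop)[0, 1]
        assert abs(r) > 0.9

    def test_null_divergence_no_separation(self):
        cfg = CohortConfig(n_per_population=(200, 200), seed=4,
                           missing_rate=0.0, stratification_divergence=0.0)
        G = simulate_genotypes([BlockSpec(500, (0.1, 0.4), 0.0)], cfg)
        pcs = compute_pcs(G, 1)
        pop = np.array([0] * 200 + [1] * 200)
        assert abs(np.corrcoef(pcs[:, 0], pop)[0, 1]) < 0.3

    def test_scores_orthogonal_and_deterministic(self, null_genotypes):
        pcs = compute_pcs(null_genotypes, 4)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()
        np.testing.assert_array_equal(pcs, compute_pcs(null_genotypes, 4))

    def test_rank_error(self):
        G = make_genotypes(np.array([[0, 1.], [1, 0.], [0, 1.]]))
        with pytest.raises(ValueError, match="rank"):
            compute_pcs(G, 3)


class TestCascade:
    def test_report_counts_reconcile(self, small_cohort):
        G, pheno = small_cohort
        G_qc, pheno_qc, report = run_qc(G, pheno, QcThresholds(n_pcs=4))
        assert G.n_snps - report.total_snps_removed == G_qc.n_snps
        assert (G.n_individuals - report.total_individuals_removed
                == G_qc.n_individuals)
        assert len(pheno_qc) == G_qc.n_individuals
        assert {"PC1", "PC4"} <= set(pheno_qc.columns)
        steps = [s["step"] for s in report.steps]
        assert steps[0].startswith("maf") and steps[-1].startswith("pca")

    def test_thresholds_validation(self):
        with pytest.raises(ValueError):
            QcThresholds(missingness_steps=(0.01, 0.05))
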