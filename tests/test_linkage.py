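"""LD statistics: brute-force haplotype-count oracles, EM-vs-phased
agreement, window aggregation and the co-segregation verdict."""

import numpy as np
import pandas as pd
import pytest

import symbiostrain as st
from symbiostrain.linkage import (
    em_haplotype_freqs,
    genotype_r2,
    haplotype_r2,
    scaffold_r2,
    window_ld,
)


def haplotypes_from_counts(n_nn, n_ns, n_sn, n_ss):
    """Chromosome matrix for two sites from the four haplotype counts."""
    rows = (
        [[0, 0]] * n_nn + [[0, 1]] * n_ns + [[1, 0]] * n_sn + [[1, 1]] * n_ss
    )
    return np.array(rows)


def brute_force_r2(n_nn, n_ns, n_sn, n_ss):
    """r2 straight from the haplotype-frequency definition."""
    n = n_nn + n_ns + n_sn + n_ss
    f = np.array([n_nn, n_ns, n_sn, n_ss]) / n
    pa = f[2] + f[3]
    pb = f[1] + f[3]
    d = f[3] - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


class TestHaplotypeR2:
    def test_perfect_cosegregation(self):
        h = haplotypes_from_counts(50, 0, 0, 50)
        assert haplotype_r2(h[:, 0], h[:, 1]) == pytest.approx(1.0)

    def test_equilibrium_counts_give_zero(self):
        h = haplotypes_from_counts(25, 25, 25, 25)
        assert haplotype_r2(h[:, 0], h[:, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_known_count_table(self):
        # 40 NN, 10 NS, 10 SN, 40 SS: D = 0.4 - 0.25 = 0.15, r2 = 0.36
        assert brute_force_r2(40, 10, 10, 40) == pytest.approx(0.36)
        h = haplotypes_from_counts(40, 10, 10, 40)
        assert haplotype_r2(h[:, 0], h[:, 1]) == pytest.approx(0.36)

    @pytest.mark.parametrize(
        "counts", [(30, 20, 5, 45), (1, 50, 40, 9), (70, 10, 15, 5)]
    )
    def test_agrees_with_brute_force_oracle(self, counts):
        h = haplotypes_from_counts(*counts)
        assert haplotype_r2(h[:, 0], h[:, 1]) == pytest.approx(
            brute_force_r2(*counts), abs=1e-12
        )

    def test_monomorphic_site_undefined(self):
        h = haplotypes_from_counts(50, 0, 50, 0)  # site j always N
        assert np.isnan(haplotype_r2(h[:, 0], h[:, 1]))

    def test_too_few_informative_chromosomes(self):
        assert np.isnan(haplotype_r2([0.0], [1.0]))


class TestEmGenotypeR2:
    @pytest.mark.parametrize(
        "counts", [(40, 10, 10, 40), (25, 25, 25, 25), (30, 20, 5, 45), (50, 0, 0, 50)]
    )
    def test_em_equals_phased_when_phase_unambiguous(self, counts):
        # individuals carrying two copies of the same haplotype have no
        # double heterozygotes, so EM recovers the phased frequencies
        # exactly (the haplotype pool, hence r2, is unchanged)
        h = haplotypes_from_counts(*counts)
        g = 2 * h
        phased = haplotype_r2(np.repeat(h[:, 0], 2), np.repeat(h[:, 1], 2))
        em = genotype_r2(g[:, 0], g[:, 1])
        assert em == pytest.approx(phased, abs=1e-9)

    @pytest.mark.parametrize("counts", [(40, 10, 10, 40), (30, 20, 5, 45), (1, 50, 40, 9)])
    def test_em_approximates_phased_under_random_pairing(self, counts):
        # random union of chromosomes creates double heterozygotes whose
        # phase is genuinely lost; EM (the MLE under random pairing)
        # tracks the phased value up to finite-sample error
        h = haplotypes_from_counts(*counts)
        rng = np.random.default_rng(1)
        rng.shuffle(h)
        g = h[0::2] + h[1::2]
        phased = haplotype_r2(h[:, 0], h[:, 1])
        em = genotype_r2(g[:, 0], g[:, 1])
        assert em == pytest.approx(phased, abs=0.1)

    def test_em_exact_without_double_heterozygotes(self):
        # individuals homozygous at site i: phase is fully determined
        g_i = np.array([0, 0, 2, 2, 2, 0])
        g_j = np.array([0, 1, 2, 2, 1, 0])
        f = em_haplotype_freqs(g_i, g_j)
        assert f.sum() == pytest.approx(1.0)
        # count haplotypes by hand: NN x5, NS x1, SS x5, SN x1
        assert f == pytest.approx(np.array([5, 1, 1, 5]) / 12)

    def test_em_deterministic(self):
        g_i = np.array([1, 1, 2, 0, 1, 2, 0, 1])
        g_j = np.array([1, 1, 2, 0, 0, 2, 1, 1])
        assert np.allclose(
            em_haplotype_freqs(g_i, g_j), em_haplotype_freqs(g_i, g_j)
        )

    def test_clonal_mixture_em_r2_is_one(self):
        g = np.array([0] * 12 + [2] * 8)
        assert genotype_r2(g, g) == pytest.approx(1.0)


def _sites(positions, scaffold="s1"):
    return pd.DataFrame({"scaffold": scaffold, "pos": positions})


class TestWindowLd:
    def test_complete_ld_gives_mean_one(self):
        h = np.array([[0, 0, 0], [1, 1, 1]] * 10)
        w = window_ld(_sites([100, 200, 300]), h, window=5000, step=5000)
        assert len(w) == 1
        assert w["mean_r2"].iloc[0] == pytest.approx(1.0)
        assert w["n_pairs"].iloc[0] == 3

    def test_single_site_window_omitted(self):
        h = np.array([[0, 0], [1, 1]] * 10)
        w = window_ld(_sites([100, 7000]), h, window=1000, step=1000)
        assert len(w) == 0

    def test_mean_of_known_pairwise_values(self):
        # three sites: pair (1,2) r2=1; pairs (1,3),(2,3) r2=0.36
        h12 = haplotypes_from_counts(40, 0, 0, 60)
        h3 = haplotypes_from_counts(40, 10, 10, 40)[:, 1]
        # rebuild site 3 against site 1's alleles
        order = np.argsort(h12[:, 0], kind="stable")
        h = np.column_stack([h12, np.sort(h3)[np.argsort(order)]])
        r12 = haplotype_r2(h[:, 0], h[:, 1])
        r13 = haplotype_r2(h[:, 0], h[:, 2])
        r23 = haplotype_r2(h[:, 1], h[:, 2])
        w = window_ld(_sites([10, 20, 30]), h, window=100, step=100)
        assert w["mean_r2"].iloc[0] == pytest.approx(np.mean([r12, r13, r23]))

    def test_two_strain_simulation_in_complete_ld(self, strain_pair):
        _, hap, _ = st.simulate_individuals(
            25, (0.5, 0.5, 0.0), strain_pair.sites, seed=51
        )
        chrom = hap.reshape(-1, hap.shape[2])
        w = window_ld(strain_pair.sites, chrom)
        assert np.allclose(w["mean_r2"], 1.0)


class TestCosegregation:
    def _freqs_and_ld(self, seed, shuffle=False, n=30):
        pair = st.gen_strain_pair(st.StrainPairModel(2, 20_000, 0.65, seed=seed))
        _, hap, _ = st.simulate_individuals(
            n, (0.5, 0.5, 0.0), pair.sites, seed=seed + 1
        )
        chrom = hap.reshape(-1, hap.shape[2])
        if shuffle:
            rng = np.random.default_rng(seed)
            for j in range(chrom.shape[1]):
                rng.shuffle(chrom[:, j])
        pileup = st.simulate_pool_pileup(
            pair.sites, st.PoolSpec("s", 0.47, 40, seed=seed + 2)
        )
        freqs = st.allele_frequencies(pileup)
        ld = window_ld(pair.sites, chrom)
        return freqs, ld

    def test_clonal_two_strain_verdict_true(self):
        freqs, ld = self._freqs_and_ld(seed=60)
        v = st.cosegregation_test(freqs, ld)
        assert v.single_strain
        assert v.min_scaffold_median_r2 == pytest.approx(1.0)

    def test_shuffled_sites_verdict_false(self):
        freqs, ld = self._freqs_and_ld(seed=61, shuffle=True)
        v = st.cosegregation_test(freqs, ld)
        assert not v.single_strain
        assert v.min_scaffold_median_r2 < 0.33

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_verdict_true_across_mixture_fractions_and_seeds(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.2, 0.8)
        pair = st.gen_strain_pair(st.StrainPairModel(1, 15_000, 0.65, seed=seed))
        _, hap, _ = st.simulate_individuals(
            20, (1 - f, f, 0.0), pair.sites, seed=seed + 100
        )
        chrom = hap.reshape(-1, hap.shape[2])
        if chrom[:, 0].mean() in (0.0, 1.0):
            pytest.skip("degenerate draw: one strain absent from the sample")
        pileup = st.simulate_pool_pileup(
            pair.sites, st.PoolSpec("s", f, 60, seed=seed + 200)
        )
        v = st.cosegregation_test(
            st.allele_frequencies(pileup), window_ld(pair.sites, chrom)
        )
        assert v.single_strain

    def test_no_usable_scaffold_rejected(self):
        freqs = pd.DataFrame(
            {"scaffold": ["s1"], "pos": [1], "depth": [50], "s_count": [25],
             "freq": [0.5], "passed": [True]}
        )
        with pytest.raises(ValueError):
            st.cosegregation_test(freqs, pd.DataFrame(columns=["scaffold", "mean_r2"]))


def test_scaffold_r2_summary(strain_pair):
    _, hap, _ = st.simulate_individuals(
        20, (0.5, 0.5, 0.0), strain_pair.sites, seed=70
    )
    chrom = hap.reshape(-1, hap.shape[2])
    s = scaffold_r2(strain_pair.sites, chrom)
    assert len(s) == 1
    assert s["median_r2"].iloc[0] == pytest.approx(1.0)
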