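import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fstgrm.fst import (
    SubpopulationSplit,
    fst_scores,
    partition_tails,
    subpop_freqs,
    top_k,
)


def _split_from_freqs(p1, p2, n1, n2, rng):
    """Dosage matrix with tails drawn at the given frequencies (HWE sampling)."""
    d1 = rng.binomial(2, p1, size=(n1, len(p1)))
    d2 = rng.binomial(2, p2, size=(n2, len(p2)))
    dos = np.vstack([d1, d2]).astype(np.int8)
    split = SubpopulationSplit(
        s1=np.arange(n1), s2=np.arange(n1, n1 + n2), s0=np.array([], dtype=int),
        q_low=0.05, q_high=0.95,
    )
    return dos, split


def _exact_split(p1_dosages, p2_dosages):
    dos = np.vstack([p1_dosages, p2_dosages]).astype(np.int8)
    n1 = len(p1_dosages)
    split = SubpopulationSplit(
        s1=np.arange(n1), s2=np.arange(n1, len(dos)), s0=np.array([], dtype=int),
        q_low=0.05, q_high=0.95,
    )
    return dos, split


class TestPartitionTails:
    def test_exact_tail_counts_on_distinct_values(self, rng):
        y = rng.permutation(100).astype(float)
        split = partition_tails(y, 0.05, 0.95)
        assert len(split.s1) == 5 and len(split.s2) == 5
        assert y[split.s1].max() < y[split.s0].min()
        assert y[split.s2].min() > y[split.s0].max()

    def test_large_population_tail_union(self, rng):
        y = rng.normal(size=15000)
        split = partition_tails(y, 0.05, 0.95)
        assert len(split.s1) + len(split.s2) == 1500

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        y = rng.normal(size=473)
        split = partition_tails(y)
        merged = np.concatenate([split.s1, split.s0, split.s2])
        assert np.array_equal(np.sort(merged), np.arange(473))

    def test_degenerate_identical_phenotypes_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            split = partition_tails(np.ones(100))
        assert len(np.intersect1d(split.s1, split.s2)) == 0

    def test_rejects_bad_quantiles_and_small_tails(self):
        with pytest.raises(ValueError):
            partition_tails(np.arange(100.0), 0.95, 0.05)
        with pytest.raises(ValueError):
            partition_tails(np.arange(10.0), 0.05, 0.95)  # 0 per tail
        with pytest.raises(ValueError):
            partition_tails(np.array([1.0, np.nan, 2.0] * 20))


class TestSubpopFreqs:
    def test_simple_dosage_means(self):
        dos = np.array([[0], [1], [2]], dtype=np.int8)
        assert subpop_freqs(dos, np.arange(3))[0] == 0.5
        dos2 = np.full((4, 3), 2, dtype=np.int8)
        np.testing.assert_allclose(subpop_freqs(dos2, np.arange(4)), 1.0)

    def test_matches_allele_counting_oracle(self, rng):
        dos = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        rows = rng.choice(50, size=17, replace=False)
        freqs = subpop_freqs(dos, rows)
        counted = np.array(
            [sum(dos[r, l] for r in rows) / (2 * len(rows)) for l in range(20)]
        )
        np.testing.assert_allclose(freqs, counted)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            subpop_freqs(np.zeros((3, 2), dtype=np.int8), np.array([], dtype=int))


class TestFstScores:
    def test_equal_frequencies_give_zero(self):
        # p_S1 = p_S2 = 0.3 (dosages engineered exactly), equal n
        tail = np.array([[0], [0], [0], [0], [1], [1], [1], [1], [1], [1]])
        dos, split = _exact_split(tail, tail)
        s = fst_scores(dos, split)
        assert s.p_s1[0] == pytest.approx(0.3)
        assert s.fst[0] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternative_alleles_give_one(self):
        dos, split = _exact_split(np.full((5, 1), 2), np.zeros((5, 1), dtype=int))
        s = fst_scores(dos, split)
        assert s.p_total[0] == pytest.approx(0.5)
        assert s.h_t[0] == pytest.approx(0.5)
        assert s.h_s[0] == pytest.approx(0.0)
        assert s.fst[0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_intermediate_case(self):
        # p_S1 = 0.8, p_S2 = 0.4, equal n: p=0.6, H_T=0.48, H_S=0.40, F_ST=1/6
        tail1 = np.array([[2], [2], [2], [1], [1]])  # p = 0.8 over 5 individuals
        tail2 = np.array([[2], [1], [1], [0], [0]])  # p = 0.4
        dos, split = _exact_split(tail1, tail2)
        s = fst_scores(dos, split)
        assert s.h_t[0] == pytest.approx(0.48, abs=1e-12)
        assert s.h_s[0] == pytest.approx(0.40, abs=1e-12)
        assert s.fst[0] == pytest.approx(1.0 / 6.0, abs=1e-12)

    def test_census_weighting_of_unequal_tails(self):
        # n1=2 (p=1), n2=8 (p=0.5): p=0.6, H_T=0.48, H_S=0.4, F_ST=1/6
        dos, split = _exact_split(np.full((2, 1), 2), np.tile([[2], [0]], (4, 1)))
        s = fst_scores(dos, split)
        assert s.fst[0] == pytest.approx((0.48 - 0.4) / 0.48, abs=1e-12)

    def test_monomorphic_locus_scores_zero(self):
        dos, split = _exact_split(np.zeros((4, 1), dtype=int), np.zeros((4, 1), dtype=int))
        assert fst_scores(dos, split).fst[0] == 0.0

    def test_bounded_on_random_loci(self, rng):
        p1 = rng.uniform(0, 1, size=100_000)
        p2 = rng.uniform(0, 1, size=100_000)
        dos, split = _split_from_freqs(p1, p2, 40, 60, rng)
        s = fst_scores(dos, split)
        assert np.all(s.fst >= 0.0) and np.all(s.fst <= 1.0)
        assert np.all(s.h_s <= s.h_t + 1e-12)

    def test_permuting_individuals_leaves_scores_unchanged(self, rng):
        dos = rng.integers(0, 3, size=(60, 40)).astype(np.int8)
        split = SubpopulationSplit(
            np.arange(10), np.arange(50, 60), np.arange(10, 50), 0.05, 0.95
        )
        base = fst_scores(dos, split).fst
        perm1 = np.random.default_rng(1).permutation(10)
        shuffled = SubpopulationSplit(
            split.s1[perm1], split.s2[::-1], split.s0, 0.05, 0.95
        )
        np.testing.assert_allclose(fst_scores(dos, shuffled).fst, base)

    def test_swapping_tail_labels_leaves_scores_unchanged(self, rng):
        dos = rng.integers(0, 3, size=(60, 40)).astype(np.int8)
        split = SubpopulationSplit(
            np.arange(12), np.arange(40, 60), np.arange(12, 40), 0.05, 0.95
        )
        swapped = SubpopulationSplit(split.s2, split.s1, split.s0, 0.05, 0.95)
        np.testing.assert_allclose(
            fst_scores(dos, swapped).fst, fst_scores(dos, split).fst
        )

    def test_null_mean_fst_decreases_with_tail_size(self, rng):
        # phenotype independent of genotype: differentiation is sampling noise,
        # shrinking as the tails grow
        dos = rng.binomial(2, rng.uniform(0.1, 0.9, 500), size=(2000, 500)).astype(np.int8)
        y = rng.normal(size=2000)
        small = fst_scores(dos, partition_tails(y, 0.05, 0.95)).fst.mean()
        large = fst_scores(dos, partition_tails(y, 0.25, 0.75)).fst.mean()
        assert small < 0.05
        assert large < small

    def test_all_population_total_option(self, rng):
        dos = rng.integers(0, 3, size=(60, 30)).astype(np.int8)
        split = SubpopulationSplit(
            np.arange(6), np.arange(54, 60), np.arange(6, 54), 0.1, 0.9
        )
        s = fst_scores(dos, split, total="all")
        np.testing.assert_allclose(s.p_total, dos.mean(axis=0) / 2.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_scores_always_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        dos = r.integers(0, 3, size=(30, 25)).astype(np.int8)
        split = SubpopulationSplit(
            np.arange(8), np.arange(22, 30), np.arange(8, 22), 0.05, 0.95
        )
        s = fst_scores(dos, split)
        assert np.all((s.fst >= 0) & (s.fst <= 1))


class TestTopK:
    def test_small_example(self):
        assert list(top_k(np.array([0.1, 0.9, 0.5]), 2)) == [1, 2]

    def test_k_equals_all(self):
        assert list(top_k(np.array([0.3, 0.1, 0.2]), 3)) == [0, 1, 2]

    def test_matches_full_sort_oracle(self, rng):
        fst = rng.uniform(0, 1, size=1000)
        got = top_k(fst, 50)
        expected = np.sort(np.argsort(-fst, kind="stable")[:50])
        np.testing.assert_array_equal(got, expected)

    def test_ties_broken_by_genome_order(self):
        fst = np.array([0.5, 0.5, 0.5, 0.1])
        chrom = np.array([2, 1, 1, 1])
        pos = np.array([1.0, 9.0, 2.0, 3.0])
        got = top_k(fst, 2, chrom, pos)
        # the two chr-1 ties at positions 2.0 and 9.0 win over chr 2
        np.testing.assert_array_equal(got, [1, 2])

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            top_k(np.array([0.1]), 0)
        with pytest.raises(ValueError):
            top_k(np.array([0.1]), 2)


def test_fst_enriched_near_large_qtl_under_selection():
    """Selection drags allele frequencies apart around big QTL, so markers
    within 1 cM of the largest QTL score higher on average (over replicates)
    than distant markers."""
    from fstgrm.sim import qtl_variance_shares, simulate
    from conftest import tiny_config

    near_means, far_means = [], []
    for seed in range(1, 6):
        res = simulate(tiny_config(seed=seed))
        g6 = res.generations[6]
        lm = res.locus_map
        snp_idx = np.flatnonzero(~lm["is_qtl"].to_numpy())
        split = partition_tails(g6.phenotype, 0.05, 0.95)
        scores = fst_scores(g6.dosages[:, snp_idx], split)
        base_freq = res.generations[0].dosages.mean(axis=0) / 2.0
        shares = qtl_variance_shares(base_freq[res.qtl.index], res.qtl.signed_effects)
        big = res.qtl.index[np.argsort(-shares)[:5]]
        chrom, pos = lm["chrom"].to_numpy(), lm["pos_cM"].to_numpy()
        near = np.zeros(len(snp_idx), dtype=bool)
        for q in big:
            near |= (chrom[snp_idx] == chrom[q]) & (np.abs(pos[snp_idx] - pos[q]) <= 1.0)
        near_means.append(scores.fst[near].mean())
        far_means.append(scores.fst[~near].mean())
    assert np.mean(near_means) > np.mean(far_means)
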