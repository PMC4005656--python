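"""Expression normalization and specificity measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cageprom import expression_metrics as em
from cageprom import synthetic_data as sd


class TestTpm:
    def test_unit_and_zero(self):
        assert em.tpm(np.array([1]), np.array([10**6]))[0] == 1.0
        assert em.tpm(np.array([0]), np.array([5]))[0] == 0.0

    def test_matches_elementwise_recomputation(self, rng):
        x = rng.integers(0, 50, size=(6, 9))
        N = rng.integers(10_000, 1_000_000, size=9)
        e = em.tpm(x, N)
        for i in range(6):
            for j in range(9):
                assert e[i, j] == pytest.approx(1e6 * x[i, j] / N[j])


class TestEntropy:
    def test_single_sample_promoter_is_zero_bits(self):
        x = np.zeros(100, dtype=int)
        x[3] = 57
        assert em.entropy(x, np.full(100, 10**6)) == 0.0

    def test_uniform_over_four_samples_is_two_bits(self):
        assert em.entropy(np.array([5, 5, 5, 5]), np.full(4, 10**6)) == pytest.approx(2.0)

    def test_mostly_uniform_promoter_close_to_max_entropy(self):
        # 50 ppm in one sample, 20 ppm in the 99 others, equal depths:
        # direct formula evaluation gives 6.6328 bits (max is log2 100)
        x = np.array([50] + [20] * 99)
        assert em.entropy(x, np.full(100, 10**6)) == pytest.approx(6.632776, abs=1e-5)

    def test_unequal_library_sizes_matter(self):
        # equal counts but a 10x library difference -> unequal tpm -> H < 1
        h = em.entropy(np.array([10, 10]), np.array([10**5, 10**6]))
        assert h < 1.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            em.entropy(np.zeros(4), np.full(4, 100))

    @given(st.integers(2, 40), st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_entropy_bounded_by_log2_t(self, t, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 100, size=t)
        if x.sum() == 0:
            x[0] = 1
        h = em.entropy(x, rng.integers(10**4, 10**6, size=t))
        assert 0.0 <= h <= math.log2(t) + 1e-9

    def test_permutation_invariant_at_equal_depth(self, rng):
        x = rng.integers(0, 30, size=12)
        x[0] += 1
        N = np.full(12, 10**5)
        perm = rng.permutation(12)
        assert em.entropy(x, N) == pytest.approx(em.entropy(x[perm], N))


class TestEntropyPseudo:
    def test_all_zero_equal_depth_is_uniform(self):
        h = em.entropy_pseudo(np.zeros(8, dtype=int), np.full(8, 10**5), 100)
        assert h == pytest.approx(3.0)

    def test_hand_computed_small_case(self):
        # two samples, counts (3, 0), N = (10, 20), N_g = 5:
        # e' = (4/15, 1/25); p = normalized; H by hand
        e = np.array([4 / 15, 1 / 25])
        p = e / e.sum()
        expected = -(p * np.log2(p)).sum()
        assert em.entropy_pseudo(
            np.array([3, 0]), np.array([10, 20]), 5
        ) == pytest.approx(expected)

    def test_still_decreases_with_subsample_size(self, rng):
        # pseudocounts do not remove the depth bias: the pseudo entropy of
        # a deep broad promoter exceeds that of its 100-tag subsample
        m = sd.generate_bias_counts(n_promoters=30, tags_per_promoter=10_000, seed=3)
        diffs = []
        for g in range(30):
            full = em.entropy_pseudo(m.counts[g], m.library_sizes, m.n_promoters)
            subs = [
                em.entropy_pseudo(
                    em.downsample_counts(m.counts[g], 100, rng),
                    m.library_sizes,
                    m.n_promoters,
                )
                for _ in range(50)
            ]
            diffs.append(full - np.median(subs))
        assert np.median(diffs) > 0


class TestMaxOverMedian:
    def test_uniform_is_one(self):
        assert em.max_over_median(np.full(7, 3.3)) == pytest.approx(1.0)

    def test_sparse_tags_over_many_samples_is_infinite(self):
        # 100 tags spread over 517 samples: the median count is necessarily 0
        rng = np.random.default_rng(1)
        x = rng.multinomial(100, np.full(517, 1 / 517))
        assert np.median(x) == 0.0
        e = em.tpm(x, np.full(517, 10**6))
        assert em.max_over_median(e) == math.inf

    def test_hand_value(self):
        assert em.max_over_median(np.array([10.0, 2.0, 4.0])) == pytest.approx(2.5)


class TestDownsampledEntropy:
    def test_single_sample_is_zero_for_any_seed(self):
        x = np.zeros(20, dtype=int)
        x[4] = 1000
        N = np.full(20, 10**5)
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            assert em.downsampled_entropy(x, N, 100, rng) == 0.0

    def test_median_matches_exact_binomial_expectation(self):
        # uniform over two equal-depth samples: the subsampled count is
        # Binomial(100, 1/2); the exact expectation of the plug-in entropy
        # is computable by enumeration
        exact = sum(
            math.comb(100, k)
            * 0.5**100
            * (
                0.0
                if k in (0, 100)
                else -(k / 100) * math.log2(k / 100)
                - (1 - k / 100) * math.log2(1 - k / 100)
            )
            for k in range(101)
        )
        x = np.array([5000, 5000])
        N = np.full(2, 10**6)
        vals = [
            em.downsampled_entropy(x, N, 100, np.random.default_rng(s))
            for s in range(200)
        ]
        assert abs(np.median(vals) - exact) < 0.05

    def test_support_bound(self, rng):
        x = rng.integers(0, 40, size=300)
        x[0] += 1
        N = rng.integers(10**4, 10**6, size=300)
        h = em.downsampled_entropy(x, N, 100, rng)
        assert h <= math.log2(100) + 1e-9

    def test_without_replacement_requires_enough_tags(self, rng):
        with pytest.raises(ValueError):
            em.downsample_counts(np.array([10, 10]), 100, rng, replace=False)
        sub = em.downsample_counts(np.array([60, 60]), 100, rng, replace=False)
        assert sub.sum() == 100 and (sub <= 60).all()


class TestRichness:
    def test_one_active_sample(self):
        x = np.zeros(50)
        x[7] = 123
        for n in (1, 10, 100):
            assert em.richness(x, n) == pytest.approx(1.0)

    def test_one_tag_one_sample(self):
        assert em.richness(np.array([5, 5]), 1) == pytest.approx(1.0)

    def test_uniform_closed_form(self):
        x = np.ones(500)
        assert em.richness(x, 10) == pytest.approx(500 * (1 - (1 - 1 / 500) ** 10))

    def test_monotone_in_n_and_bounded(self, rng):
        x = rng.integers(0, 20, size=40)
        x[0] += 1
        vals = [em.richness(x, n) for n in (1, 5, 20, 100, 1000)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] <= 40


class TestBiasExperiment:
    def test_three_measures_drift_with_subsample_size(self):
        m = sd.generate_bias_counts(n_promoters=60, seed=2)
        _, summary = em.bias_experiment(m, seed=2)
        s = summary.set_index("size")
        assert s.loc[100, "entropy"] < s.loc[1000, "entropy"] < s.loc[10000, "entropy"]
        assert (
            s.loc[100, "entropy_pseudo"]
            < s.loc[1000, "entropy_pseudo"]
            < s.loc[10000, "entropy_pseudo"]
        )
        assert (
            s.loc[100, "max_over_median"]
            > s.loc[1000, "max_over_median"]
            > s.loc[10000, "max_over_median"]
        )

    def test_requires_a_deep_promoter(self):
        m = sd.generate_bias_counts(n_promoters=3, tags_per_promoter=1000, seed=0)
        with pytest.raises(ValueError):
            em.bias_experiment(m, min_total=10**5)


class TestSimulateUniformBreadth:
    def test_totals_conserved_exactly(self, rng):
        m = sd.generate_bias_counts(n_promoters=20, tags_per_promoter=777, seed=4)
        for f in (1.0, 0.5, 0.25, 0.1):
            sim = em.simulate_uniform_breadth(m, f, rng)
            assert (sim.counts.sum(axis=1) == m.counts.sum(axis=1)).all()

    def test_active_sample_count(self, rng):
        m = sd.generate_bias_counts(n_promoters=10, tags_per_promoter=50_000, seed=4)
        sim = em.simulate_uniform_breadth(m, 0.25, rng)
        assert ((sim.counts > 0).sum(axis=1) == round(0.25 * m.n_samples)).all()

    def test_assignment_proportional_to_library_size(self):
        # f=1, equal N_t: marginal assignment uniform (chi-square GOF)
        from scipy.stats import chisquare

        m = em.ExpressionMatrix(
            counts=np.array([[100_000] + [0] * 19]),
            library_sizes=np.full(20, 10**6),
            sample_ids=[f"s{i}" for i in range(20)],
        )
        sim = em.simulate_uniform_breadth(m, 1.0, np.random.default_rng(5))
        res = chisquare(sim.counts[0])
        assert res.pvalue > 0.01

    def test_entropy_ordering_across_breadth_fractions(self):
        m = sd.generate_bias_counts(n_promoters=200, tags_per_promoter=2000, seed=5)
        rng = np.random.default_rng(7)
        meds = []
        for f in (1.0, 0.5, 0.25, 0.10):
            sim = em.simulate_uniform_breadth(m, f, rng)
            spec = em.specificity_table(sim, seed=11)
            meds.append(spec.entropy_100.median())
        assert meds[0] > meds[1] > meds[2] > meds[3]


class TestSummarize:
    def test_uniform_promoter_avg_equals_max(self):
        m = em.ExpressionMatrix(
            counts=np.full((1, 10), 50),
            library_sizes=np.full(10, 10**6),
            sample_ids=[f"s{i}" for i in range(10)],
        )
        s = em.summarize_expression(m)
        assert s.avg_tpm[0] == pytest.approx(s.max_tpm[0])

    def test_single_sample_promoter_avg_is_max_over_t(self):
        counts = np.zeros((1, 20), dtype=int)
        counts[0, 3] = 40
        m = em.ExpressionMatrix(
            counts=counts,
            library_sizes=np.full(20, 10**6),
            sample_ids=[f"s{i}" for i in range(20)],
        )
        s = em.summarize_expression(m)
        assert s.avg_tpm[0] == pytest.approx(s.max_tpm[0] / 20)

    def test_bounds_and_germ_average(self, rng):
        counts = rng.integers(0, 100, size=(30, 12))
        germ = np.zeros(12, dtype=bool)
        germ[[2, 5]] = True
        N = rng.integers(10**5, 10**6, size=12)
        m = em.ExpressionMatrix(
            counts=counts,
            library_sizes=N,
            sample_ids=[f"s{i}" for i in range(12)],
            is_germ=germ,
        )
        s = em.summarize_expression(m)
        e = em.tpm(counts, N)
        assert np.allclose(s.germ_avg_tpm, e[:, germ].mean(axis=1))
        assert ((s.max_tpm / 12 <= s.avg_tpm + 1e-12) & (s.avg_tpm <= s.max_tpm + 1e-12)).all()
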