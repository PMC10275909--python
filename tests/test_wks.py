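import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uniconsig import (
    NullDistribution,
    RankedList,
    UntestableSetError,
    ValidationError,
    WksEngine,
    adjust_pvalues,
    normalize_es,
    permutation_null,
    running_sum_es,
)


def wks_bruteforce(genes, weights, gene_set, exponent):
    """Independent full-scan oracle: enumerate the running sum step by step
    and take the first element of maximal absolute deviation."""
    n = len(genes)
    hits = [g in gene_set for g in genes]
    n_hit = sum(hits)
    denom = sum(abs(w) ** exponent for w, h in zip(weights, hits) if h)
    run, cur = [], 0.0
    for w, h in zip(weights, hits):
        if h:
            cur += (abs(w) ** exponent) / denom if denom > 0 else 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        run.append(cur)
    if n_hit == n:
        return 1.0
    best = 0
    for i in range(1, n):
        if abs(run[i]) > abs(run[best]):
            best = i
    return run[best]


def bh_stepup(pvals):
    """Hand-written Benjamini–Hochberg step-up oracle."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


@pytest.fixture
def four_gene_list():
    return RankedList.from_weights({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})


class TestRunningSum:
    def test_top_gene_hits_es_one(self, four_gene_list):
        stat = running_sum_es(four_gene_list, {"g1"}, exponent=1.0)
        assert stat.es == pytest.approx(1.0)
        assert stat.leading_edge == {"g1"}
        np.testing.assert_allclose(stat.running_sum, [1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_bottom_gene_hits_es_minus_one(self, four_gene_list):
        stat = running_sum_es(four_gene_list, {"g4"}, exponent=1.0)
        assert stat.es == pytest.approx(-1.0)
        np.testing.assert_allclose(stat.running_sum, [-1 / 3, -2 / 3, -1.0, 0.0])
        assert stat.leading_edge == {"g4"}

    def test_all_genes_hit_es_one_by_convention(self, four_gene_list):
        stat = running_sum_es(four_gene_list, {"g1", "g2", "g3", "g4"})
        assert stat.es == 1.0

    def test_empty_intersection_raises(self, four_gene_list):
        with pytest.raises(UntestableSetError):
            running_sum_es(four_gene_list, {"absent"})

    def test_running_sum_conserved_to_zero(self):
        """The walk returns exactly to 0 when both step kinds apply."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            genes = [f"g{i}" for i in range(n)]
            weights = {g: float(w) for g, w in zip(genes, sorted(rng.normal(size=n))[::-1])}
            ranked = RankedList.from_weights(weights)
            k = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=k, replace=False))
            stat = running_sum_es(ranked, gene_set)
            assert stat.running_sum[-1] == pytest.approx(0.0, abs=1e-9)

    def test_exponent_zero_ignores_weight_scale(self):
        """With exponent 0 the ES depends only on ranks, so any
        order-preserving weight transform leaves it unchanged."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        base = np.sort(rng.normal(size=30))[::-1]
        ranked_a = RankedList.from_weights(dict(zip(genes, base)))
        ranked_b = RankedList.from_weights(dict(zip(genes, np.exp(3 * base))))
        gene_set = set(genes[3:9])
        a = running_sum_es(ranked_a, gene_set, exponent=0.0)
        b = running_sum_es(ranked_b, gene_set, exponent=0.0)
        assert a.es == pytest.approx(b.es, abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(5, 50))
            genes = [f"g{i}" for i in range(n)]
            w = np.sort(rng.normal(size=n))[::-1]
            ranked = RankedList(genes=tuple(genes), weights=w)
            k = int(rng.integers(1, min(10, n)))
            gene_set = set(rng.choice(genes, size=k, replace=False))
            exponent = float(rng.choice([0.0, 1.0, 2.0]))
            got = running_sum_es(ranked, gene_set, exponent).es
            want = wks_bruteforce(genes, w, gene_set, exponent)
            assert got == pytest.approx(want, abs=1e-12)


class TestPermutationNull:
    def test_fixed_seed_reproducible(self, four_gene_list):
        a = permutation_null(four_gene_list, 2, n_perm=100, seed=9)
        b = permutation_null(four_gene_list, 2, n_perm=100, seed=9)
        np.testing.assert_array_equal(a.es_samples, b.es_samples)

    def test_full_size_subset_always_one(self, four_gene_list):
        null = permutation_null(four_gene_list, 4, n_perm=25, seed=1)
        np.testing.assert_array_equal(null.es_samples, np.ones(25))

    def test_single_gene_samples_enumerate_four_values(self, four_gene_list):
        """Only 4 single-gene subsets exist; brute-force their ES values."""
        expected = set()
        for g in four_gene_list.genes:
            expected.add(round(running_sum_es(four_gene_list, {g}).es, 9))
        null = permutation_null(four_gene_list, 1, n_perm=400, seed=2)
        observed = {round(float(v), 9) for v in null.es_samples}
        assert observed <= expected
        assert observed == expected  # 400 draws of 4 values hit them all

    def test_oversized_set_rejected(self, four_gene_list):
        with pytest.raises(ValidationError):
            permutation_null(four_gene_list, 5, n_perm=10, seed=0)

    def test_null_matches_direct_running_sum(self):
        """Sampled ES values agree with the full-scan statistic recomputed
        on the same subsets (fast path vs reference path)."""
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(40)]
        w = np.sort(rng.normal(size=40))[::-1]
        ranked = RankedList(genes=tuple(genes), weights=w)
        null = permutation_null(ranked, 7, n_perm=50, seed=33)
        rng2 = np.random.default_rng(33)
        for es in null.es_samples:
            subset = {genes[i] for i in rng2.choice(40, size=7, replace=False)}
            assert es == pytest.approx(running_sum_es(ranked, subset).es, abs=1e-12)


class TestNormalizeEs:
    def test_nes_is_es_over_positive_null_mean(self):
        null = NullDistribution(np.array([0.25, 0.25, -0.5]), seed=0)
        nes, _ = normalize_es(0.5, null)
        assert nes == pytest.approx(2.0)

    def test_zero_es_gives_zero_nes(self):
        null = NullDistribution(np.array([0.3, -0.2]), seed=0)
        assert normalize_es(0.0, null) == (0.0, 1.0)

    def test_pvalue_add_one_smoothing(self):
        """ES above all 99 same-sign samples: p = (0+1)/(99+1)."""
        null = NullDistribution(np.linspace(0.01, 0.5, 99), seed=0)
        _, p = normalize_es(0.9, null)
        assert p == pytest.approx(1 / 100)

    def test_negative_es_uses_negative_pool(self):
        null = NullDistribution(np.array([-0.2, -0.4, 0.3]), seed=0)
        nes, p = normalize_es(-0.6, null)
        assert nes == pytest.approx(-0.6 / 0.3)
        assert p == pytest.approx(1 / 3)

    def test_no_same_sign_samples_warns_and_zeroes(self):
        null = NullDistribution(np.array([0.1, 0.2]), seed=0)
        with pytest.warns(UserWarning):
            nes, p = normalize_es(-0.5, null)
        assert (nes, p) == (0.0, 1.0)


class TestAdjustPvalues:
    @pytest.mark.parametrize(
        "pvals, method, expected",
        [
            ([0.01, 0.02], "bonferroni", [0.02, 0.04]),
            ([0.01], "bonferroni", [0.01]),
            ([0.01], "benjamini_hochberg", [0.01]),
            ([0.01, 0.04, 0.03], "benjamini_hochberg", [0.03, 0.04, 0.04]),
        ],
    )
    def test_worked_examples(self, pvals, method, expected):
        np.testing.assert_allclose(adjust_pvalues(pvals, method), expected, atol=1e-12)

    def test_bh_agrees_with_stepup_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 15))).tolist()
            np.testing.assert_allclose(
                adjust_pvalues(p, "benjamini_hochberg"), bh_stepup(p), atol=1e-12
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.1, 1.5], "bonferroni")


class TestCalibration:
    def test_random_set_pvalues_uniform(self):
        """On exchangeable random weights, permutation p-values of random
        sets are uniform to within Monte-Carlo error."""
        from scipy import stats

        rng = np.random.default_rng(99)
        genes = [f"g{i}" for i in range(200)]
        w = np.sort(rng.normal(size=200))[::-1]
        ranked = RankedList(genes=tuple(genes), weights=w)
        null = permutation_null(ranked, 10, n_perm=1000, seed=7)
        pvals = []
        for _ in range(200):
            subset = {genes[i] for i in rng.choice(200, size=10, replace=False)}
            es = running_sum_es(ranked, subset).es
            _, p = normalize_es(es, null)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


class TestWksEngine:
    def test_shared_null_reused_across_equal_sizes(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        w = np.sort(rng.normal(size=50))[::-1]
        engine = WksEngine(RankedList(genes=tuple(genes), weights=w), seed=4, n_perm=100)
        n1 = engine.null_for(8)
        n2 = engine.null_for(8)
        assert n1 is n2

    def test_per_set_null_independent_of_call_order(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        w = np.sort(rng.normal(size=50))[::-1]
        ranked = RankedList(genes=tuple(genes), weights=w)
        set_a, set_b = frozenset(genes[:6]), frozenset(genes[10:16])
        e1 = WksEngine(ranked, seed=4, n_perm=50, null_mode="per_set")
        e2 = WksEngine(ranked, seed=4, n_perm=50, null_mode="per_set")
        a_then_b = (e1.test(set_a).p_value, e1.test(set_b).p_value)
        b_then_a = (e2.test(set_b).p_value, e2.test(set_a).p_value)
        assert a_then_b == (b_then_a[1], b_then_a[0])
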