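"""Aggregation methods: worked examples, Monte-Carlo oracles, invariances."""

import math

import numpy as np
import pytest

from toxrank.aggregate import (
    BirraParams,
    RankMatrix,
    aggregate_all,
    aggregate_ar,
    aggregate_birra,
    aggregate_mean,
    aggregate_nc,
    aggregate_rra,
    aggregate_stuart,
)
from toxrank.aggregate import _stuart_q
from toxrank.ranking import RankedList
from toxrank.stats import midrank


def _matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    return RankMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        values=values,
        list_labels=labels or [f"L{j}" for j in range(values.shape[1])],
    )


def _ranked(genes, ranks, modulated=()):
    return RankedList(list(genes), np.asarray(ranks, float), frozenset(modulated))


class TestMean:
    def test_score_is_mean(self):
        M = _matrix([[0.1, 0.2, 0.3], [0.5, 0.5, 0.5]])
        res = aggregate_mean(M)
        assert res.scores[0] == pytest.approx(0.2)
        assert res.ranks.tolist() == [1, 2]

    def test_irwin_hall_pvalue(self):
        M = _matrix([[0.1, 0.4], [0.5, 0.5]])
        res = aggregate_mean(M)
        assert res.pvalues[0] == pytest.approx(0.125)  # P(U1+U2 <= 0.5)

    def test_identical_rows_all_tied(self):
        M = _matrix([[0.3, 0.4]] * 5)
        res = aggregate_mean(M)
        assert np.all(res.ranks == 3.0)


class TestNC:
    def test_counts_order(self):
        genes = [f"g{i}" for i in range(10)]
        lists = {}
        for c in range(6):
            mod = {"g0"} if c < 5 else set()
            if c < 3:
                mod = mod | {"g1"}
            lists[f"L{c}"] = _ranked(genes, np.full(10, 5.5), mod)
        res = aggregate_nc(lists)
        assert res.scores[0] == 5 and res.scores[1] == 3
        assert res.ranks[0] < res.ranks[1] < res.ranks[2]

    def test_nothing_modulated_all_tied(self):
        genes = [f"g{i}" for i in range(4)]
        lists = {"a": _ranked(genes, [2.5] * 4), "b": _ranked(genes, [2.5] * 4)}
        res = aggregate_nc(lists)
        assert np.all(res.ranks == 2.5)

    def test_modulated_everywhere_is_rank_one(self):
        genes = ["g0", "g1", "g2"]
        lists = {
            f"L{c}": _ranked(genes, [1, 2.5, 2.5], {"g0"}) for c in range(4)
        }
        assert aggregate_nc(lists).ranks[0] == 1


class TestRRA:
    def test_single_list_identity(self):
        M = _matrix([[0.25], [0.8]])
        res = aggregate_rra(M)
        assert res.scores[0] == pytest.approx(0.25)

    def test_worked_example(self):
        # ranks 1,2,3 of N=10 -> beta tails 0.271, 0.104, 0.027
        M = _matrix([[0.1, 0.2, 0.3], [0.5, 0.6, 0.7]])
        res = aggregate_rra(M)
        assert res.scores[0] == pytest.approx(3 * 0.027, abs=1e-12)

    def test_last_everywhere_scores_one(self):
        M = _matrix([[1.0, 1.0], [0.2, 0.3]])
        res = aggregate_rra(M)
        assert res.scores[0] == 1.0

    def test_monte_carlo_oracle(self, rng):
        # beta order-statistic CDF vs empirical order statistics of uniforms
        m = 4
        draws = np.sort(rng.random((100_000, m)), axis=1)
        for k in (1, 2, 4):
            for r in (0.1, 0.35):
                from toxrank.stats import beta_order_cdf

                emp = (draws[:, k - 1] <= r).mean()
                se = math.sqrt(emp * (1 - emp) / draws.shape[0]) + 1e-12
                assert abs(beta_order_cdf(r, k, m) - emp) <= 3 * se + 1e-4


class TestStuart:
    def test_single_list_identity(self):
        M = _matrix([[0.3], [0.9]])
        res = aggregate_stuart(M)
        assert res.scores[0] == pytest.approx(0.3)

    def test_two_list_closed_form(self):
        # P(min<=0.1, max<=0.2) = 0.2^2 - (0.2-0.1)^2 = 0.03
        M = _matrix([[0.1, 0.2], [0.5, 0.6]])
        res = aggregate_stuart(M)
        assert res.scores[0] == pytest.approx(0.03, abs=1e-12)

    def test_all_ones_full_support(self):
        M = _matrix([[1.0, 1.0, 1.0], [0.1, 0.2, 0.3]])
        assert aggregate_stuart(M).scores[0] == pytest.approx(1.0)

    def test_factorial_flag_is_rank_invariant(self, rng):
        M = _matrix(rng.random((20, 5)))
        a = aggregate_stuart(M, include_factorial=True)
        b = aggregate_stuart(M, include_factorial=False)
        assert np.array_equal(a.ranks, b.ranks)
        assert np.allclose(a.scores, np.array(b.scores) * math.factorial(5))

    def test_monte_carlo_oracle(self, rng):
        m = 3
        draws = np.sort(rng.random((200_000, m)), axis=1)
        for r in ([0.2, 0.5, 0.9], [0.05, 0.1, 0.3]):
            r = np.asarray(r)
            emp = np.all(draws <= r, axis=1).mean()
            se = math.sqrt(emp * (1 - emp) / draws.shape[0]) + 1e-12
            q = _stuart_q(r[None, :])[0]
            assert abs(q - emp) <= 3 * se + 1e-4

    def test_large_m_stays_finite(self, rng):
        M = _matrix(np.clip(rng.random((5, 65)), 0.01, 1.0))
        q = aggregate_stuart(M).scores
        assert np.all(np.isfinite(q)) and np.all(q >= 0)


class TestBirra:
    def test_single_list_preserves_order(self, rng):
        # a monotone Bayes factor cannot invert the input order; ties are
        # allowed where the monotonized BF is flat (top bins)
        r = np.arange(1, 41) / 40.0
        rng.shuffle(r)
        M = _matrix(r[:, None])
        res = aggregate_birra(M, BirraParams(prior=0.1))
        order = np.argsort(r)
        assert np.all(np.diff(res.ranks[order]) >= 0)  # no inversions
        assert np.all(np.diff(res.scores[order]) <= 1e-12)  # BF monotone

    def test_planted_recovery(self, rng):
        n, m, n_planted = 1000, 10, 50
        values = rng.random((n, m))
        informative = rng.random((n_planted, m)) < 0.8
        beta_draws = rng.beta(1, 25, size=(n_planted, m))
        values[:n_planted][informative] = beta_draws[informative]
        M = _matrix(values)
        res = aggregate_birra(M)
        top100 = set(np.argsort(res.ranks, kind="mergesort")[:100])
        assert len(top100 & set(range(n_planted))) >= 0.9 * n_planted

    def test_null_top_set_is_random(self, rng):
        # overlap of the final top-pi set with a fixed set matches the
        # hypergeometric expectation under an uninformative matrix
        n, m = 500, 10
        n_top = 25
        fixed = set(range(n_top))
        overlaps = []
        for _ in range(30):
            M = _matrix(rng.random((n, m)))
            res = aggregate_birra(M)
            top = set(np.argsort(res.ranks, kind="mergesort")[:n_top])
            overlaps.append(len(top & fixed))
        expected = n_top * n_top / n  # 1.25
        assert np.mean(overlaps) < 4 * expected

    def test_prior_too_small_rejected(self):
        M = _matrix(np.random.default_rng(0).random((5, 3)))
        with pytest.raises(ValueError):
            aggregate_birra(M, BirraParams(prior=0.01))


class TestAR:
    def _identical(self, ranks):
        genes = [f"g{i}" for i in range(len(ranks))]
        return {
            m: type("R", (), {"method": m, "gene_ids": genes,
                              "scores": np.asarray(ranks, float),
                              "ranks": np.asarray(ranks, float)})()
            for m in ("MEAN", "NC", "RRA", "STUART", "BIRRA")
        }

    def test_median_robustness(self):
        from toxrank.aggregate import AggregationResult

        genes = ["a", "b"]
        results = {}
        for m, ranks in zip(
            ("MEAN", "NC", "RRA", "STUART", "BIRRA"),
            ([1, 2], [2, 1], [3, 4], [4, 3], [100, 5]),
        ):
            results[m] = AggregationResult(m, genes, np.asarray(ranks, float),
                                           np.asarray(ranks, float))
        res = aggregate_ar(results)
        assert res.scores[0] == 3  # median of 1,2,3,4,100

    def test_idempotent_on_identical_methods(self):
        results = self._identical([3, 1, 2, 4])
        res = aggregate_ar(results)
        assert res.ranks.tolist() == [3, 1, 2, 4]

    def test_missing_method_named(self):
        results = self._identical([1, 2])
        del results["BIRRA"]
        with pytest.raises(ValueError, match="BIRRA"):
            aggregate_ar(results)


class TestInvariances:
    def _small_lists(self, rng, n=30, m=5):
        genes = [f"g{i}" for i in range(n)]
        lists = {}
        for c in range(m):
            scores = rng.random(n)
            ranks = midrank(scores, "lower")
            lists[f"L{c}"] = _ranked(genes, ranks, set(np.array(genes)[scores < 0.3]))
        return lists

    def test_permutation_equivariance(self, rng):
        lists = self._small_lists(rng)
        res = aggregate_all(lists)
        perm = rng.permutation(30)
        permuted = {
            lab: _ranked(
                [rl.gene_ids[i] for i in perm],
                rl.ranks[perm],
                rl.modulated,
            )
            for lab, rl in lists.items()
        }
        res_p = aggregate_all(permuted)
        for m in res:
            ranks_by_gene = dict(zip(res[m].gene_ids, res[m].ranks))
            ranks_by_gene_p = dict(zip(res_p[m].gene_ids, res_p[m].ranks))
            assert ranks_by_gene == pytest.approx(ranks_by_gene_p)

    def test_list_order_invariance(self, rng):
        lists = self._small_lists(rng)
        res = aggregate_all(lists)
        reordered = dict(reversed(list(lists.items())))
        res_r = aggregate_all(reordered)
        for m in res:
            assert np.allclose(res[m].ranks, res_r[m].ranks)

    def test_rank_sum_conservation(self, rng):
        lists = self._small_lists(rng)
        n = 30
        for m, res in aggregate_all(lists).items():
            assert res.ranks.sum() == pytest.approx(n * (n + 1) / 2), m

    def test_planted_recovery_ordering(self, rng):
        # planted Beta(1,25) ranks in 8 of 10 lists: robust methods find them
        from toxrank.evaluate import roc_auc

        n, m, n_planted = 1000, 10, 50
        values = rng.random((n, m))
        informative = rng.random((n_planted, m)) < 0.8
        beta_draws = rng.beta(1, 25, size=(n_planted, m))
        values[:n_planted][informative] = beta_draws[informative]
        genes = [f"g{i}" for i in range(n)]
        lists = {
            f"L{c}": _ranked(genes, midrank(values[:, c], "lower"),
                             set(np.array(genes)[values[:, c] < 0.05]))
            for c in range(m)
        }
        res = aggregate_all(lists)
        planted = set(genes[:n_planted])
        aucs = {m: roc_auc(r, planted).auc for m, r in res.items()}
        for m in ("RRA", "STUART", "AR"):
            assert aucs[m] >= 0.95, aucs
        assert aucs["MEAN"] > 0.5
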