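"""Statistical primitives against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toxrank.stats import (
    ContingencyCounts,
    beta_order_cdf,
    bh_fdr,
    fisher_one_tailed,
    irwin_hall_cdf,
    midrank,
)


def bh_brute_force(p):
    """Literal step-up definition: q_(i) = min_{j>=i} min(1, m p_(j)/j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, i in enumerate(order, start=1):
        q[i] = min(
            min(1.0, m * p[order[j - 1]] / j) for j in range(pos, m + 1)
        )
    return q


def hypergeom_tail_enumeration(a, gene_total, topic_total, universe):
    """Exact tail P(X >= a) by summing the hypergeometric pmf."""
    denom = math.comb(universe, gene_total)
    total = 0
    for k in range(a, min(gene_total, topic_total) + 1):
        if gene_total - k > universe - topic_total:
            continue
        total += math.comb(topic_total, k) * math.comb(
            universe - topic_total, gene_total - k
        )
    return total / denom


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.5,), (0.5,)),
            ((1.0, 1.0), (1.0, 1.0)),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert bh_fdr(np.array(p)) == pytest.approx(expected)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50),
        st.integers(0, 10_000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force(self, p, _):
        q = bh_fdr(np.array(p))
        assert np.allclose(q, bh_brute_force(p), atol=1e-12)

    def test_monotone_in_sorted_p(self, rng):
        p = rng.random(200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestFisherOneTailed:
    def test_zero_overlap_is_one(self):
        c = ContingencyCounts(a=0, gene_total=5, topic_total=13, universe=1000)
        assert fisher_one_tailed(c) == pytest.approx(1.0)

    def test_forced_overlap_is_one(self):
        c = ContingencyCounts(a=3, gene_total=3, topic_total=3, universe=3)
        assert fisher_one_tailed(c) == pytest.approx(1.0)

    def test_enrichment_example(self):
        c = ContingencyCounts(a=3, gene_total=5, topic_total=13, universe=1000)
        expected = hypergeom_tail_enumeration(3, 5, 13, 1000)
        assert fisher_one_tailed(c) == pytest.approx(expected, rel=1e-10)
        assert fisher_one_tailed(c) == pytest.approx(1.7e-5, rel=0.05)

    @given(st.data())
    @settings(max_examples=200, derandomize=True)
    def test_matches_enumeration_small_universes(self, data):
        universe = data.draw(st.integers(1, 60))
        gene_total = data.draw(st.integers(0, universe))
        topic_total = data.draw(st.integers(0, universe))
        a = data.draw(st.integers(0, min(gene_total, topic_total)))
        # a must be feasible: at least gene_total - (universe - topic_total)
        a = max(a, gene_total - (universe - topic_total))
        c = ContingencyCounts(a, gene_total, topic_total, universe)
        expected = hypergeom_tail_enumeration(a, gene_total, topic_total, universe)
        assert fisher_one_tailed(c) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_invariant_violations(self):
        with pytest.raises(ValueError):
            ContingencyCounts(a=4, gene_total=3, topic_total=10, universe=100)
        with pytest.raises(ValueError):
            ContingencyCounts(a=0, gene_total=200, topic_total=10, universe=100)


class TestBetaOrderCdf:
    def test_minimum_of_uniforms(self):
        assert beta_order_cdf(0.1, 1, 3) == pytest.approx(1 - 0.9**3)

    def test_full_support(self):
        for k, m in [(1, 1), (2, 5), (5, 5)]:
            assert beta_order_cdf(1.0, k, m) == pytest.approx(1.0)

    def test_maximum_of_two(self):
        assert beta_order_cdf(0.2, 2, 2) == pytest.approx(0.04)

    def test_order_index_validation(self):
        with pytest.raises(ValueError):
            beta_order_cdf(0.5, 0, 3)
        with pytest.raises(ValueError):
            beta_order_cdf(0.5, 4, 3)

    def test_matches_binomial_tail(self):
        # P(U_(k) <= r) = P(Binomial(m, r) >= k)
        from scipy.stats import binom

        for m in (2, 4, 6):
            for k in range(1, m + 1):
                for r in (0.05, 0.3, 0.77):
                    assert beta_order_cdf(r, k, m) == pytest.approx(
                        binom.sf(k - 1, m, r), rel=1e-9
                    )


class TestIrwinHall:
    @pytest.mark.parametrize(
        "s, m, expected",
        [
            (0.5, 2, 0.125),
            (2.0, 2, 1.0),
            (1.0, 1, 1.0),
            (0.3, 1, 0.3),
        ],
    )
    def test_worked_examples(self, s, m, expected):
        assert irwin_hall_cdf(s, m) == pytest.approx(expected)

    def test_monte_carlo_small_m(self, rng):
        for m in (2, 3, 5):
            draws = rng.random((200_000, m)).sum(axis=1)
            for s in (0.5 * m, 0.8 * m, 0.3 * m):
                emp = (draws <= s).mean()
                se = math.sqrt(emp * (1 - emp) / draws.size) + 1e-9
                assert abs(irwin_hall_cdf(s, m) - emp) < 4 * se

    def test_continuous_at_normal_switchover(self):
        # exact (m=50) and approximate (m=51) agree near the centre
        assert irwin_hall_cdf(25.0, 50) == pytest.approx(0.5, abs=1e-8)
        assert irwin_hall_cdf(25.5, 51) == pytest.approx(0.5, abs=1e-3)

    def test_non_decreasing(self):
        for m in (3, 20, 60):
            vals = [irwin_hall_cdf(s, m) for s in np.linspace(0, m, 101)]
            assert np.all(np.diff(vals) >= -1e-9)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            irwin_hall_cdf(-0.1, 3)
        with pytest.raises(ValueError):
            irwin_hall_cdf(3.1, 3)


class TestMidrank:
    def test_better_is_higher(self):
        assert midrank([10, 8, 8, 2], "higher").tolist() == [1, 2.5, 2.5, 4]

    def test_all_equal(self):
        assert midrank([7] * 5, "higher").tolist() == [3, 3, 3, 3, 3]

    def test_better_is_lower(self):
        assert midrank([0.2, 0.1, 0.3], "lower").tolist() == [2, 1, 3]

    def test_nan_tied_worst(self):
        r = midrank([1.0, np.nan, 2.0, np.nan], "higher")
        assert r[0] == 2 and r[2] == 1 and r[1] == r[3] == 3.5

    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=60),
        st.sampled_from(["higher", "lower"]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_rank_sum_conservation(self, scores, direction):
        r = midrank(np.array(scores, dtype=float), direction)
        n = len(scores)
        assert r.sum() == pytest.approx(n * (n + 1) / 2)
        assert np.all((r >= 1) & (r <= n))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            midrank([], "higher")
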