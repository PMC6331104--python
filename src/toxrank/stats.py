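"""Shared statistical primitives for the prioritization pipeline.

All downstream stages (differential-expression screening, rank aggregation,
literature co-occurrence testing) reduce their inferential steps to the small
set of pure functions in this module:

* Benjamini–Hochberg step-up FDR adjustment (:func:`bh_fdr`),
* the one-tailed (enrichment) Fisher exact test on a 2x2 co-occurrence table
  (:func:`fisher_one_tailed`),
* the CDF of the k-th order statistic of m iid uniforms — a Beta(k, m-k+1)
  law — which is the null model of robust rank aggregation
  (:func:`beta_order_cdf`),
* the Irwin–Hall CDF of a sum of m iid uniforms, used to attach a
  significance level to a mean of normalized ranks (:func:`irwin_hall_cdf`),
* midrank (average-rank) tie handling (:func:`midrank`).

Everything here is deterministic and oracle-verifiable by enumeration,
closed forms, or Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyCounts",
    "bh_fdr",
    "fisher_one_tailed",
    "beta_order_cdf",
    "irwin_hall_cdf",
    "midrank",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts for a gene-vs-topic abstract co-occurrence table.

    Parameters
    ----------
    a:
        Abstracts linked to the gene AND belonging to the topic.
    gene_total:
        Abstracts linked to the gene.
    topic_total:
        Abstracts belonging to the topic.
    universe:
        Total abstracts in the background set.
    """

    a: int
    gene_total: int
    topic_total: int
    universe: int

    def __post_init__(self) -> None:
        for name in ("a", "gene_total", "topic_total", "universe"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.a > min(self.gene_total, self.topic_total):
            raise ValueError("overlap a exceeds a marginal total")
        if self.gene_total > self.universe or self.topic_total > self.universe:
            raise ValueError("marginal total exceeds the universe")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, m * p_(j) / j), mapped back to input order.
    Length and order of the input are preserved.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fisher_one_tailed(counts: ContingencyCounts) -> float:
    """One-tailed (enrichment) Fisher exact test p-value.

    Returns P(X >= a) for X ~ Hypergeometric(universe, topic_total,
    gene_total): the upper tail, i.e. the probability of observing at least
    the seen gene/topic overlap when abstracts are drawn at random from the
    background.
    """
    c = counts
    return float(_sps.hypergeom.sf(c.a - 1, c.universe, c.topic_total, c.gene_total))


def beta_order_cdf(r, k: int, m: int):
    """P(U_(k) <= r) for the k-th order statistic of m iid Uniform(0,1).

    This is the Beta(k, m - k + 1) CDF evaluated at ``r``; it is the null
    distribution against which robust rank aggregation compares the k-th
    smallest normalized rank of a gene across m lists. ``r`` may be a scalar
    or an array.
    """
    if not 1 <= k <= m:
        raise ValueError(f"order index k={k} outside 1..m={m}")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > 1):
        raise ValueError("normalized rank r must lie in [0, 1]")
    out = _sps.beta.cdf(r_arr, k, m - k + 1)
    return float(out) if np.isscalar(r) else out


_IH_EXACT_MAX = 50


def irwin_hall_cdf(s: float, m: int) -> float:
    """CDF of the sum of m iid Uniform(0,1) variables, evaluated at ``s``.

    Exact alternating-sum formula for m <= 50; for larger m a normal
    approximation N(m/2, m/12) is used (continuous, non-decreasing, and
    accurate to ~1e-3 at m > 50). Attaches a significance level to a sum (or
    mean) of normalized ranks.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= s <= m:
        raise ValueError(f"s={s} outside [0, m={m}]")
    if m > _IH_EXACT_MAX:
        return float(_sps.norm.cdf(s, loc=m / 2.0, scale=math.sqrt(m / 12.0)))
    # F(s) = (1/m!) * sum_{k=0}^{floor(s)} (-1)^k C(m,k) (s-k)^m.
    # The density is symmetric about m/2; evaluating on the lower half via
    # F(s) = 1 - F(m - s) keeps the alternating terms small (cancellation
    # otherwise costs ~8 digits near s = m for large m).
    if s > m / 2.0:
        return float(1.0 - irwin_hall_cdf(m - s, m))
    terms = [
        (-1.0) ** k * math.comb(m, k) * (s - k) ** m
        for k in range(int(math.floor(s)) + 1)
    ]
    val = math.fsum(terms) / math.factorial(m)
    return float(min(1.0, max(0.0, val)))


def midrank(scores, direction: str = "higher") -> np.ndarray:
    """Ranks with average-rank (midrank) tie resolution.

    Rank 1 is best. ``direction`` states whether larger scores are better
    ("higher") or smaller scores are better ("lower"). NaN scores are treated
    as explicitly tied-worst: they share the midrank of the trailing block.
    The output always sums to N(N+1)/2.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("empty score vector")
    if direction not in ("higher", "lower"):
        raise ValueError(f"unknown direction {direction!r}")
    key = -x if direction == "higher" else x.copy()
    nan_mask = np.isnan(key)
    if nan_mask.any():
        # rankdata puts NaN last under 'average' only with explicit handling
        key = key.copy()
        key[nan_mask] = np.inf
        # tie all NaNs together at the bottom
        ranks = _sps.rankdata(key, method="average")
        n = x.size
        n_nan = int(nan_mask.sum())
        ranks[nan_mask] = (2 * n - n_nan + 1) / 2.0
        return ranks
    return _sps.rankdata(key, method="average")
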