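"""Cross-compound rank aggregation.

Six aggregators combine the per-compound extended partial rankings of a
shared gene universe into one consensus ranking per model system:

MEAN
    Average of normalized ranks; an Irwin–Hall significance level for the
    rank sum is attached and BH-adjusted across genes (a monotone transform,
    so the ordering equals ordering by the mean itself).
NC
    Number of compounds in which the gene was modulated (i.e. outside the
    tied bottom block); more compounds is better.
RRA
    Robust rank aggregation: for each gene the sorted normalized ranks
    r_(1) <= ... <= r_(m) are compared to the Beta(k, m-k+1) null of uniform
    order statistics; the minimum of the m tail probabilities, Bonferroni
    multiplied by m (capped at 1), is the gene score. Smaller is better.
STUART
    The joint probability Q = P(U_(1) <= r_(1), ..., U_(m) <= r_(m)) that m
    iid uniform order statistics jointly dominate the observed sorted ranks,
    computed by the exact alternating recursion. Smaller is better.
BIRRA
    Bayesian iterative rank reweighting: starting from the rank-average
    consensus, each list is scored by bin-wise Bayes factors of membership
    in the putative positive class (top prior-fraction of the consensus),
    log Bayes factors are monotonized across bins and summed over lists per
    gene, and the consensus is re-ranked until it is stable or an iteration
    cap is hit. Larger scores are better.
AR
    The per-gene median of the five aggregated ranks above, re-ranked.

All final rankings resolve ties by midrank, so every output rank vector
sums to N(N+1)/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ranking import RankedList
from .stats import bh_fdr, beta_order_cdf, irwin_hall_cdf, midrank

__all__ = [
    "RankMatrix",
    "AggregationResult",
    "BirraParams",
    "aggregate_mean",
    "aggregate_nc",
    "aggregate_rra",
    "aggregate_stuart",
    "aggregate_birra",
    "aggregate_ar",
    "aggregate_all",
    "AGGREGATION_METHODS",
]

AGGREGATION_METHODS = ("MEAN", "NC", "RRA", "STUART", "BIRRA", "AR")


@dataclass
class RankMatrix:
    """Gene x list matrix of normalized ranks in (0, 1]."""

    gene_ids: list[str]
    values: np.ndarray  # shape (N, m)
    list_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.list_labels),
        ):
            raise ValueError("rank matrix shape does not match labels")
        if self.values.shape[1] == 0:
            raise ValueError("rank matrix needs at least one list")
        if np.any(self.values <= 0) or np.any(self.values > 1):
            raise ValueError("normalized ranks must lie in (0, 1]")

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_ranked_lists(cls, lists: dict[str, RankedList]) -> "RankMatrix":
        # canonical column order: float summations are then independent of
        # the order the lists were supplied in (exact list-order invariance)
        labels = sorted(lists)
        if not labels:
            raise ValueError("no ranked lists given")
        universe = lists[labels[0]].gene_ids
        cols = []
        for lab in labels:
            rl = lists[lab]
            if rl.gene_ids != universe:
                raise ValueError(f"list {lab!r} has a different gene universe")
            cols.append(rl.normalized())
        return cls(gene_ids=list(universe), values=np.column_stack(cols), list_labels=labels)


@dataclass
class AggregationResult:
    """One method's consensus: per-gene score and midrank-tied rank."""

    method: str
    gene_ids: list[str]
    scores: np.ndarray
    ranks: np.ndarray
    pvalues: np.ndarray | None = None
    qvalues: np.ndarray | None = None

    def rank_of(self, gene: str) -> float:
        return float(self.ranks[self.gene_ids.index(gene)])


@dataclass(frozen=True)
class BirraParams:
    """BIRRA settings: bins, iteration cap, positive-class prior, smoothing."""

    bins: int = 50
    max_iter: int = 10
    prior: float = 0.05
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("need at least two bins")
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def aggregate_mean(M: RankMatrix) -> AggregationResult:
    """Average normalized rank, with Irwin–Hall significance, BH-adjusted."""
    mean = M.values.mean(axis=1)
    sums = M.values.sum(axis=1)
    pvals = np.array([irwin_hall_cdf(min(s, M.m), M.m) for s in sums])
    qvals = bh_fdr(pvals)
    # Ranking by the mean itself: identical order to the (monotone) p/q
    # transforms but free of the tie plateaus BH adjustment introduces.
    ranks = midrank(mean, direction="lower")
    return AggregationResult("MEAN", list(M.gene_ids), mean, ranks, pvals, qvals)


def aggregate_nc(lists: dict[str, RankedList]) -> AggregationResult:
    """Rank by the number of compounds that modulated the gene."""
    labels = list(lists)
    if not labels:
        raise ValueError("no ranked lists given")
    universe = lists[labels[0]].gene_ids
    counts = np.zeros(len(universe))
    for lab in labels:
        rl = lists[lab]
        if rl.gene_ids != universe:
            raise ValueError(f"list {lab!r} has a different gene universe")
        mod = rl.modulated
        counts += np.fromiter((g in mod for g in universe), dtype=float, count=len(universe))
    ranks = midrank(counts, direction="higher")
    return AggregationResult("NC", list(universe), counts, ranks)


def aggregate_rra(M: RankMatrix) -> AggregationResult:
    """Robust rank aggregation (beta order-statistic minimum, Bonferroni)."""
    m = M.m
    sorted_r = np.sort(M.values, axis=1)
    p = np.empty_like(sorted_r)
    for k in range(1, m + 1):
        p[:, k - 1] = beta_order_cdf(sorted_r[:, k - 1], k, m)
    rho = p.min(axis=1)
    score = np.minimum(1.0, m * rho)
    qvals = bh_fdr(score)
    # Rank by the uncapped Bonferroni product: same ordering as the capped
    # score wherever the cap is not binding, but without the artificial tie
    # block that capping at 1 would create among weak genes.
    ranks = midrank(m * rho, direction="lower")
    return AggregationResult("RRA", list(M.gene_ids), score, ranks, score, qvals)


def _stuart_q(sorted_r: np.ndarray, include_factorial: bool = True) -> np.ndarray:
    """Joint order-statistic probability Q per row of sorted ranks.

    Uses the scaled recursion w_k = sum_{j<k} (-1)^(k-1-j) C(k,j) w_j
    b_{j+1}^{k-j} with w_0 = 1, for which w_m = m! * V_m =
    P(U_(1) <= b_1, ..., U_(m) <= b_m). Binomial coefficients replace the
    explicit factorials so the recursion stays finite for large m.
    """
    n, m = sorted_r.shape
    w = [np.ones(n)]
    for k in range(1, m + 1):
        acc = np.zeros(n)
        for j in range(k):
            sign = -1.0 if (k - 1 - j) % 2 else 1.0
            acc += sign * math.comb(k, j) * w[j] * sorted_r[:, j] ** (k - j)
        w.append(acc)
    q = np.clip(w[m], 0.0, 1.0)
    if not include_factorial:
        q = q / math.factorial(m)
    return q


def aggregate_stuart(M: RankMatrix, include_factorial: bool = True) -> AggregationResult:
    """Joint uniform order-statistic dominance probability, smaller better.

    ``include_factorial=True`` (default) reports the actual probability
    Q = m! * V_m; with False the raw simplex volume V_m is reported. The
    ranking is invariant to this scaling.
    """
    sorted_r = np.sort(M.values, axis=1)
    q = _stuart_q(sorted_r, include_factorial=include_factorial)
    ranks = midrank(q, direction="lower")
    return AggregationResult("STUART", list(M.gene_ids), q, ranks)


def aggregate_birra(M: RankMatrix, params: BirraParams = BirraParams()) -> AggregationResult:
    """Bayesian iterative rank reweighting of the input lists."""
    N, m = M.n, M.m
    B = params.bins
    if params.prior * N < 1:
        raise ValueError("prior * N is below one gene; increase the prior")
    n_pos = int(math.ceil(params.prior * N))
    pc = params.pseudo_count
    bins = np.clip(np.ceil(M.values * B).astype(int), 1, B)  # (N, m), 1-based
    ranks = midrank(M.values.mean(axis=1), direction="lower")
    scores = np.zeros(N)
    for _ in range(params.max_iter):
        pos_idx = np.argsort(ranks, kind="mergesort")[:n_pos]
        pos_mask = np.zeros(N, dtype=bool)
        pos_mask[pos_idx] = True
        log_bf = np.empty((m, B))
        for c in range(m):
            pos_counts = np.bincount(bins[pos_mask, c], minlength=B + 1)[1:]
            neg_counts = np.bincount(bins[~pos_mask, c], minlength=B + 1)[1:]
            cpos = np.cumsum(pos_counts)
            cneg = np.cumsum(neg_counts)
            bf = ((cpos + pc) / (params.prior * N + pc)) / (
                (cneg + pc) / ((1.0 - params.prior) * N + pc)
            )
            lb = np.log(bf)
            # enforce monotone non-increasing evidence across bins
            log_bf[c] = np.maximum.accumulate(lb[::-1])[::-1]
        scores = np.zeros(N)
        for c in range(m):
            scores += log_bf[c, bins[:, c] - 1]
        new_ranks = midrank(scores, direction="higher")
        if np.array_equal(new_ranks, ranks):
            ranks = new_ranks
            break
        ranks = new_ranks
    return AggregationResult("BIRRA", list(M.gene_ids), scores, ranks)


def aggregate_ar(results: dict[str, AggregationResult]) -> AggregationResult:
    """Median of the MEAN, NC, RRA, STUART and BIRRA ranks, re-ranked."""
    required = ("MEAN", "NC", "RRA", "STUART", "BIRRA")
    missing = [r for r in required if r not in results]
    if missing:
        raise ValueError(f"AR aggregation is missing method(s): {missing}")
    universe = results[required[0]].gene_ids
    stack = []
    for name in required:
        res = results[name]
        if res.gene_ids != universe:
            raise ValueError(f"method {name} has a different gene universe")
        stack.append(res.ranks)
    med = np.median(np.column_stack(stack), axis=1)
    ranks = midrank(med, direction="lower")
    return AggregationResult("AR", list(universe), med, ranks)


def aggregate_all(
    lists: dict[str, RankedList],
    methods: tuple[str, ...] = AGGREGATION_METHODS,
    birra_params: BirraParams = BirraParams(),
    stuart_include_factorial: bool = True,
) -> dict[str, AggregationResult]:
    """Run the requested aggregation methods over one set of ranked lists."""
    unknown = [m for m in methods if m not in AGGREGATION_METHODS]
    if unknown:
        raise ValueError(f"unknown aggregation method(s): {unknown}")
    M = RankMatrix.from_ranked_lists(lists)
    out: dict[str, AggregationResult] = {}
    need = set(methods)
    if "MEAN" in need:
        out["MEAN"] = aggregate_mean(M)
    if "NC" in need:
        out["NC"] = aggregate_nc(lists)
    if "RRA" in need:
        out["RRA"] = aggregate_rra(M)
    if "STUART" in need:
        out["STUART"] = aggregate_stuart(M, include_factorial=stuart_include_factorial)
    if "BIRRA" in need:
        out["BIRRA"] = aggregate_birra(M, birra_params)
    if "AR" in need:
        out["AR"] = aggregate_ar(out)
    return {m: out[m] for m in methods}
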