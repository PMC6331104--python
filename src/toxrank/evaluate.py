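"""Evaluation of gene rankings and comparison between model systems.

A ranking is scored against a positive gene set by the ROC curve and its
area (AUC), with tied rank blocks traversed as single diagonal segments —
the straight-line stretches characteristic of extended partial rankings.
AUC equals the midrank-corrected Mann–Whitney statistic: the probability
that a random positive outranks a random negative, ties counted half.

Rankings from different model systems are compared by Spearman's rho, and
combined either by summing ranks (genes consistently perturbed everywhere)
or by rank differences (genes perturbed in one system and not another: the
ascending head of rank_a - rank_b is a-specific, the descending tail
b-specific).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import midrank

__all__ = [
    "RocResult",
    "CombinedRanking",
    "roc_auc",
    "spearman",
    "combine_sum",
    "combine_diff",
    "top_k",
]


@dataclass
class RocResult:
    """ROC points (monotone, (0,0) to (1,1)) and the area under them."""

    points: pd.DataFrame  # columns: fpr, tpr
    auc: float


@dataclass
class CombinedRanking:
    """A ranking combined across systems (sum or difference of ranks)."""

    gene_ids: list[str]
    scores: np.ndarray
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=float)


def _extract_ranks(r) -> tuple[list[str], np.ndarray]:
    """Accept an AggregationResult/RankedList/CombinedRanking-like object."""
    return list(r.gene_ids), np.asarray(r.ranks, dtype=float)


def roc_auc(r, positives) -> RocResult:
    """ROC curve and AUC of a ranking against a positive gene set.

    Lower rank = more positive-like. Tied blocks produce single straight
    segments; AUC is the trapezoidal area, identical to the tie-corrected
    Mann–Whitney statistic.
    """
    genes, ranks = _extract_ranks(r)
    positives = set(positives)
    unknown = positives - set(genes)
    if unknown:
        raise ValueError(f"positives outside the ranked universe: {sorted(unknown)[:5]}")
    is_pos = np.array([g in positives for g in genes])
    n_pos = int(is_pos.sum())
    n_neg = len(genes) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("positive set must be non-empty and proper")
    order = np.argsort(ranks, kind="mergesort")
    sorted_ranks = ranks[order]
    sorted_pos = is_pos[order]
    # traverse tied blocks as single segments
    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    i = 0
    n = len(genes)
    auc = 0.0
    while i < n:
        j = i
        while j < n and sorted_ranks[j] == sorted_ranks[i]:
            j += 1
        block_pos = int(sorted_pos[i:j].sum())
        block_neg = (j - i) - block_pos
        # trapezoid over the block's diagonal segment
        auc += block_neg / n_neg * (tp + block_pos / 2.0) / n_pos
        tp += block_pos
        fp += block_neg
        fpr.append(fp / n_neg)
        tpr.append(tp / n_pos)
        i = j
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return RocResult(points=points, auc=float(auc))


def spearman(a, b) -> tuple[float, float]:
    """Spearman's rho between two rankings of the same universe.

    rho is the Pearson correlation of the midrank vectors; the p-value uses
    the large-sample t approximation. Constant rankings have undefined
    correlation and return (nan, nan).
    """
    genes_a, ranks_a = _extract_ranks(a)
    genes_b, ranks_b = _extract_ranks(b)
    if set(genes_a) != set(genes_b):
        raise ValueError("rankings cover different gene universes")
    idx = {g: i for i, g in enumerate(genes_b)}
    rb = ranks_b[[idx[g] for g in genes_a]]
    if np.all(ranks_a == ranks_a[0]) or np.all(rb == rb[0]):
        return float("nan"), float("nan")
    rho, p = _sps.spearmanr(ranks_a, rb)
    return float(rho), float(p)


def combine_sum(rankings) -> CombinedRanking:
    """Sum of ranks across systems; low sums = consistently perturbed."""
    rankings = list(rankings)
    if not rankings:
        raise ValueError("no rankings to combine")
    genes, total = _extract_ranks(rankings[0])
    total = total.copy()
    for r in rankings[1:]:
        g2, r2 = _extract_ranks(r)
        if g2 != genes:
            if set(g2) != set(genes):
                raise ValueError("rankings cover different gene universes")
            idx = {g: i for i, g in enumerate(g2)}
            r2 = r2[[idx[g] for g in genes]]
        total += r2
    return CombinedRanking(
        gene_ids=genes, scores=total, ranks=midrank(total, direction="lower")
    )


def combine_diff(a, b) -> CombinedRanking:
    """rank_a - rank_b; ascending order highlights a-specific genes."""
    genes_a, ranks_a = _extract_ranks(a)
    genes_b, ranks_b = _extract_ranks(b)
    if set(genes_a) != set(genes_b):
        raise ValueError("rankings cover different gene universes")
    idx = {g: i for i, g in enumerate(genes_b)}
    diff = ranks_a - ranks_b[[idx[g] for g in genes_a]]
    return CombinedRanking(
        gene_ids=genes_a, scores=diff, ranks=midrank(diff, direction="lower")
    )


def top_k(r, k: int) -> tuple[list[str], int]:
    """The k best-ranked genes; a tie block straddling the cut is kept whole.

    Returns (genes, realized size) — the realized size exceeds k exactly
    when a tied block straddles the boundary.
    """
    genes, ranks = _extract_ranks(r)
    n = len(genes)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    order = np.argsort(ranks, kind="mergesort")
    cutoff_rank = ranks[order[k - 1]]
    keep = [i for i in order if ranks[i] <= cutoff_rank]
    return [genes[i] for i in keep], len(keep)
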