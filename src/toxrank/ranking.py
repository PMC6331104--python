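"""Extended partial ranking of a gene universe from per-compound screens.

A screened compound yields, per gene, an R^2 and a model p-value for
selected genes and nothing for the rest. The ranking convention is:

* selected genes are fully ordered by R^2 of the adjusted model
  (descending), ties resolved by the model p-value (ascending), residual
  ties by midrank;
* all remaining genes — the ones that failed the global F-test, retained no
  significant treatment coefficient, or fell under the R^2 floor — share one
  tied bottom block.

The bottom block's shared rank defaults to the midrank of the positions it
spans, which conserves the rank sum N(N+1)/2 and keeps mean aggregation
unbiased; the alternative convention (shared rank = N) is available via
``bottom="max"``. Normalized ranks r = rank/N map into (0, 1] and are the
aggregation input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEResult

__all__ = ["RankedList", "rank_compound", "normalize", "write_ranked_list", "read_ranked_list"]


@dataclass
class RankedList:
    """An extended partial ranking over a fixed gene universe.

    ``ranks`` aligns with ``gene_ids``; rank 1 is the strongest evidence.
    ``modulated`` is the set of genes outside the tied bottom block.
    """

    gene_ids: list[str]
    ranks: np.ndarray
    modulated: frozenset[str]

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if self.ranks.shape != (len(self.gene_ids),):
            raise ValueError("rank vector does not match gene universe")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def normalized(self) -> np.ndarray:
        """Normalized ranks r = rank / N in (0, 1], order preserved."""
        return self.ranks / self.n


def rank_compound(results: list[DEResult], bottom: str = "midrank") -> RankedList:
    """Build the extended partial ranking from one compound's screen results.

    ``bottom`` chooses the shared rank of the non-selected block: "midrank"
    (default; average of the positions the block spans) or "max" (rank = N).
    """
    if bottom not in ("midrank", "max"):
        raise ValueError(f"unknown bottom-block convention {bottom!r}")
    genes = [r.gene for r in results]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene in screen results")
    n = len(genes)
    if n == 0:
        raise ValueError("empty result list")
    sel_idx = [i for i, r in enumerate(results) if r.selected]
    ranks = np.empty(n, dtype=float)
    n_sel = len(sel_idx)
    if n_sel:
        r2 = np.array([results[i].r2 for i in sel_idx])
        pv = np.array([results[i].adjusted_p for i in sel_idx])
        # order by r2 desc, then p asc; midrank on exact (r2, p) ties
        order = np.lexsort((pv, -r2))
        pos = np.empty(n_sel)
        pos[order] = np.arange(1, n_sel + 1)
        # average positions over exact key ties
        keys = {}
        for i in range(n_sel):
            keys.setdefault((r2[i], pv[i]), []).append(i)
        sel_ranks = pos.copy()
        for idx in keys.values():
            if len(idx) > 1:
                sel_ranks[idx] = pos[idx].mean()
        for j, i in enumerate(sel_idx):
            ranks[i] = sel_ranks[j]
    bottom_rank = float(n) if bottom == "max" else (n_sel + 1 + n) / 2.0
    for i, r in enumerate(results):
        if not r.selected:
            ranks[i] = bottom_rank
    return RankedList(
        gene_ids=genes,
        ranks=ranks,
        modulated=frozenset(results[i].gene for i in sel_idx),
    )


def normalize(ranked: RankedList) -> np.ndarray:
    """Normalized ranks (rank / N) aligned with ``ranked.gene_ids``."""
    return ranked.normalized()


def write_ranked_list(path, ranked: RankedList) -> None:
    df = pd.DataFrame(
        {
            "gene": ranked.gene_ids,
            "rank": ranked.ranks,
            "modulated": [int(g in ranked.modulated) for g in ranked.gene_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_ranked_list(path) -> RankedList:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return RankedList(
        gene_ids=df["gene"].tolist(),
        ranks=df["rank"].to_numpy(dtype=float),
        modulated=frozenset(df.loc[df["modulated"] == 1, "gene"]),
    )
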