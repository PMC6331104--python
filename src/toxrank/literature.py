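"""Literature-derived organ-toxicity positive gene sets.

Candidate toxicity genes are defined by gene-vs-topic co-occurrence in
abstract annotations: for every gene with at least one annotated abstract,
a one-tailed Fisher exact test asks whether the gene's abstracts are
enriched for topic abstracts (e.g. abstracts matching a hepatotoxicity or
nephrotoxicity query) against a declared background universe of abstracts.
P-values are BH-adjusted across tested genes; candidates must pass the FDR
cut (default 0.05), be supported by a minimum number of topic abstracts
(default 3), and — for cross-species use — have a one-to-one ortholog in
the partner taxon.

The package consumes pre-resolved abstract-id sets; executing literature
queries is outside its scope. The query strings used to build the organ
topics are documented here as constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneAbstractMap
from .orthology import OrthologPairs
from .stats import ContingencyCounts, bh_fdr, fisher_one_tailed

__all__ = [
    "TOPIC_QUERIES",
    "CandidateSet",
    "gene_topic_association",
    "select_candidates",
]

#: Documented topic queries for the two organ toxicity topics.
TOPIC_QUERIES = {
    "hepatotoxicity": "hepatotoxicity OR [toxicity AND liver]",
    "nephrotoxicity": "nephrotoxicity OR [toxicity AND kidney]",
}


@dataclass
class CandidateSet:
    """Per-gene co-occurrence statistics and the resulting selection."""

    topic: str
    table: pd.DataFrame  # columns: gene, p, q, support, selected
    fdr_cut: float | None = None
    min_support: int | None = None
    #: selection before the ortholog filter (None until select_candidates ran)
    selected_pre_ortholog: frozenset[str] | None = None

    @property
    def selected(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["selected"] == 1, "gene"])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def gene_topic_association(
    gmap: GeneAbstractMap,
    topic: frozenset[int],
    universe_size: int,
    topic_label: str = "topic",
    restrict_universe_to_annotated: bool = False,
) -> CandidateSet:
    """Test every annotated gene for topic enrichment (unselected result).

    The contingency table per gene is (|G ∩ T|, |G|, |T|, universe) with G
    the gene's abstracts and T the topic's. With
    ``restrict_universe_to_annotated`` the background is shrunk to the
    abstracts annotated to at least one gene (and the topic set intersected
    with it) instead of the full declared universe.
    """
    gmap.validate_universe(universe_size)
    if universe_size < len(topic):
        raise ValueError("universe smaller than the topic set")
    if restrict_universe_to_annotated:
        annotated = frozenset().union(*gmap.by_gene.values()) if gmap.by_gene else frozenset()
        topic = topic & annotated
        universe_size = len(annotated)
    genes = sorted(g for g, abstracts in gmap.by_gene.items() if abstracts)
    pvals, support = [], []
    for gene in genes:
        abstracts = gmap.by_gene[gene]
        a = len(abstracts & topic)
        c = ContingencyCounts(
            a=a,
            gene_total=len(abstracts),
            topic_total=len(topic),
            universe=universe_size,
        )
        pvals.append(fisher_one_tailed(c))
        support.append(a)
    q = bh_fdr(np.array(pvals)) if genes else np.array([])
    table = pd.DataFrame(
        {
            "gene": genes,
            "p": pvals,
            "q": q,
            "support": support,
            "selected": 0,
        }
    )
    return CandidateSet(topic=topic_label, table=table)


def select_candidates(
    assoc: CandidateSet,
    fdr_cut: float = 0.05,
    min_support: int = 3,
    pairs: OrthologPairs | None = None,
) -> CandidateSet:
    """Apply the FDR, abstract-support, and ortholog filters.

    selected = (q <= fdr_cut) AND (support >= min_support) AND (the gene has
    a one-to-one ortholog pair, when ``pairs`` is given). The pre-ortholog
    selection is kept on the result for reporting.
    """
    table = assoc.table.copy()
    base = (table["q"] <= fdr_cut) & (table["support"] >= min_support)
    pre = frozenset(table.loc[base, "gene"])
    if pairs is not None:
        paired = set(pairs.a_to_b())
        final = base & table["gene"].isin(paired)
    else:
        final = base
    table["selected"] = final.astype(int)
    return CandidateSet(
        topic=assoc.topic,
        table=table,
        fdr_cut=fdr_cut,
        min_support=min_support,
        selected_pre_ortholog=pre,
    )
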