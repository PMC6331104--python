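"""Probeset-to-gene collapse and one-to-one ortholog mapping.

Microarray probesets that map to more than one gene are discarded as
non-specific; when several probesets map to the same gene, the one with the
largest interquartile range of expression across all samples is kept as the
most informative. Cross-species work is restricted to homolog groups with
exactly one member in each of the two taxa (one-to-one orthologs), which
makes id translation of rankings and gene sets unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionPanel, HomologTable, SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologPairs",
    "collapse_probesets",
    "one_to_one_orthologs",
    "map_ranking_to_taxon",
    "map_gene_set_to_taxon",
]


@dataclass
class OrthologPairs:
    """One-to-one gene pairs between taxon A and taxon B."""

    taxon_a: int
    taxon_b: int
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_genes = [a for a, _ in self.pairs]
        b_genes = [b for _, b in self.pairs]
        if len(set(a_genes)) != len(a_genes) or len(set(b_genes)) != len(b_genes):
            raise ValueError("a gene appears in more than one ortholog pair")

    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def transposed(self) -> "OrthologPairs":
        return OrthologPairs(
            taxon_a=self.taxon_b,
            taxon_b=self.taxon_a,
            pairs=[(b, a) for a, b in self.pairs],
        )

    def __len__(self) -> int:
        return len(self.pairs)


def _iqr(row: np.ndarray) -> float:
    q75, q25 = np.percentile(row, [75, 25])  # linear-interpolation quartiles
    return float(q75 - q25)


def collapse_probesets(
    matrix: np.ndarray,
    probeset_ids: list[str],
    samples: list[SampleMeta],
    pmap: dict[str, frozenset[str]],
) -> ExpressionPanel:
    """Collapse a probeset x sample matrix to one row per gene.

    Probesets mapping to more than one gene are removed as non-specific.
    For a gene measured by several probesets, the probeset with the largest
    IQR of expression across all samples is retained (ties broken by
    lexicographically smallest probeset id, for deterministic builds).
    Retained rows are verbatim copies of input rows.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(probeset_ids), len(samples)):
        raise ValueError("matrix shape does not match probeset/sample lists")
    unknown = [p for p in probeset_ids if p not in pmap]
    if unknown:
        raise ValueError(f"probeset(s) missing from the map: {unknown[:5]}")
    best: dict[str, tuple[float, str, int]] = {}  # gene -> (-iqr?, probeset, row)
    for i, probeset in enumerate(probeset_ids):
        genes = pmap[probeset]
        if len(genes) != 1:
            continue  # non-specific probeset
        (gene,) = genes
        iqr = _iqr(matrix[i])
        key = (iqr, probeset)
        if gene not in best:
            best[gene] = (iqr, probeset, i)
        else:
            cur_iqr, cur_ps, _ = best[gene]
            # larger IQR wins; on an exact tie the lexicographically first id
            if iqr > cur_iqr or (iqr == cur_iqr and probeset < cur_ps):
                best[gene] = (iqr, probeset, i)
    order = sorted(best)  # stable, deterministic gene order
    rows = [best[g][2] for g in order]
    return ExpressionPanel(
        gene_ids=order, samples=list(samples), values=matrix[rows, :]
    )


def one_to_one_orthologs(table: HomologTable, taxon_a: int, taxon_b: int) -> OrthologPairs:
    """Pairs from homolog groups with exactly one gene in each taxon."""
    df = table.rows
    sub = df[df["taxon_id"].isin([taxon_a, taxon_b])]
    pairs: list[tuple[str, str]] = []
    for _, grp in sub.groupby("group_id", sort=True):
        a = grp.loc[grp["taxon_id"] == taxon_a, "gene_id"].tolist()
        b = grp.loc[grp["taxon_id"] == taxon_b, "gene_id"].tolist()
        if len(a) == 1 and len(b) == 1:
            pairs.append((a[0], b[0]))
    return OrthologPairs(taxon_a=taxon_a, taxon_b=taxon_b, pairs=pairs)


def map_ranking_to_taxon(result, pairs: OrthologPairs, direction: str = "a_to_b"):
    """Translate a ranking's gene ids through one-to-one ortholog pairs.

    Genes without a pair are dropped (their count is logged). Scores and
    ranks are preserved; only identifiers change. Works on any object with
    ``gene_ids``, ``scores`` and ``ranks`` (AggregationResult-like); returns
    the same type.
    """
    mapping = pairs.a_to_b() if direction == "a_to_b" else pairs.b_to_a()
    keep = [i for i, g in enumerate(result.gene_ids) if g in mapping]
    dropped = len(result.gene_ids) - len(keep)
    if dropped:
        logger.warning("map_ranking_to_taxon: dropped %d unpaired genes", dropped)
    new_ids = [mapping[result.gene_ids[i]] for i in keep]
    if len(set(new_ids)) != len(new_ids):
        raise RuntimeError("one-to-one mapping produced duplicate targets")
    kwargs = dict(
        gene_ids=new_ids,
        scores=np.asarray(result.scores)[keep],
        ranks=np.asarray(result.ranks)[keep],
    )
    if hasattr(result, "method"):
        kwargs["method"] = result.method
    return type(result)(**kwargs)


def map_gene_set_to_taxon(
    genes, pairs: OrthologPairs, direction: str = "a_to_b"
) -> tuple[set[str], int]:
    """Translate a gene set; returns (mapped set, dropped-gene count)."""
    mapping = pairs.a_to_b() if direction == "a_to_b" else pairs.b_to_a()
    mapped = {mapping[g] for g in genes if g in mapping}
    dropped = sum(1 for g in genes if g not in mapping)
    if dropped:
        logger.warning("map_gene_set_to_taxon: dropped %d unpaired genes", dropped)
    return mapped, dropped
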