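"""Readers and writers for the tabular formats the pipeline touches.

All tables are TSV. Floating point values are written with 12 significant
digits so that write -> read round-trips are stable. Readers validate
strictly and raise :class:`FormatError` rather than silently repairing
malformed inputs.

Dialects
--------
* expression matrix: header ``gene_id<TAB>sample...``, one row per gene;
* sample metadata: columns ``sample_id compound dose time replicate system``;
* gene->abstract map: gene2pubmed dialect ``taxon_id TAB GeneID TAB
  PubMed_ID`` with an optional ``#`` header line;
* homolog table: HomoloGene dialect ``HID TAB taxon TAB GeneID`` (extra
  columns ignored);
* topic abstract set: one abstract id per line;
* rankings: ``gene_id TAB score TAB rank`` sorted by rank.

Gene identifiers are opaque strings (Entrez-style integers in practice); the
species context is carried by the tables, never encoded in the id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DOSE_LEVELS",
    "SampleMeta",
    "ExpressionPanel",
    "GeneAbstractMap",
    "HomologTable",
    "read_expression_panel",
    "write_expression_panel",
    "read_gene_abstract_map",
    "write_gene_abstract_map",
    "read_homolog_table",
    "write_homolog_table",
    "read_topic_set",
    "write_topic_set",
    "read_probeset_map",
    "read_ranking",
    "write_ranking",
]

FLOAT_FMT = "%.12g"

DOSE_LEVELS = ("control", "low", "middle", "high")

META_COLUMNS = ("sample_id", "compound", "dose", "time", "replicate", "system")


class FormatError(ValueError):
    """A malformed input file (or an inconsistent pair of files)."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one expression sample."""

    sample_id: str
    compound: str
    dose: str
    time: float
    replicate: int
    system: str = ""

    def __post_init__(self) -> None:
        if self.dose not in DOSE_LEVELS:
            raise FormatError(
                f"sample {self.sample_id!r}: dose {self.dose!r} not one of {DOSE_LEVELS}"
            )
        if self.time < 0:
            raise FormatError(f"sample {self.sample_id!r}: negative time {self.time}")
        if self.replicate < 1:
            raise FormatError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


@dataclass
class ExpressionPanel:
    """A gene x sample log2 expression matrix with per-sample metadata."""

    gene_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in expression panel")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must all be finite")
        for compound in {s.compound for s in self.samples}:
            doses = {s.dose for s in self.samples if s.compound == compound}
            if "control" not in doses:
                raise FormatError(f"compound {compound!r} has no control dose group")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def compounds(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.compound, None)
        return list(seen)

    def subset_compound(self, compound: str) -> "ExpressionPanel":
        idx = [i for i, s in enumerate(self.samples) if s.compound == compound]
        if not idx:
            raise KeyError(f"compound {compound!r} not present in panel")
        return ExpressionPanel(
            gene_ids=list(self.gene_ids),
            samples=[self.samples[i] for i in idx],
            values=self.values[:, idx],
        )


@dataclass
class GeneAbstractMap:
    """Mapping gene id -> set of abstract (PubMed) ids."""

    by_gene: dict[str, frozenset[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.by_gene)

    def n_pairs(self) -> int:
        return sum(len(v) for v in self.by_gene.values())

    def validate_universe(self, universe: set[int] | int) -> None:
        """Check every abstract id is a member of the declared universe."""
        if isinstance(universe, int):
            bad = [g for g, a in self.by_gene.items() if a and (max(a) > universe or min(a) < 1)]
        else:
            bad = [g for g, a in self.by_gene.items() if not a <= universe]
        if bad:
            raise FormatError(
                f"{len(bad)} genes reference abstracts outside the universe "
                f"(first: {bad[0]!r})"
            )


@dataclass
class HomologTable:
    """Rows of (group_id, taxon_id, gene_id) homology assignments."""

    rows: pd.DataFrame  # columns: group_id (int), taxon_id (int), gene_id (str)

    def __post_init__(self) -> None:
        expected = ["group_id", "taxon_id", "gene_id"]
        if list(self.rows.columns) != expected:
            raise FormatError(f"homolog table must have columns {expected}")
        if self.rows.duplicated(subset=expected).any():
            raise FormatError("duplicate (group, taxon, gene) row in homolog table")

    @property
    def n_groups(self) -> int:
        return int(self.rows["group_id"].nunique())


# ---------------------------------------------------------------------------
# expression panels


def read_expression_panel(matrix_path, metadata_path) -> ExpressionPanel:
    """Read a gene x sample TSV matrix and its sample metadata table.

    The first matrix column is the gene id; the header carries sample ids.
    Metadata row order is irrelevant: samples are matched by id, and a sample
    present on only one side is an error.
    """
    mat = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if mat.shape[1] < 2:
        raise FormatError(f"{matrix_path}: matrix needs a gene column and >=1 sample")
    gene_col = mat.columns[0]
    genes = mat[gene_col].astype(str).tolist()
    if len(set(genes)) != len(genes):
        dup = pd.Series(genes)[pd.Series(genes).duplicated()].iloc[0]
        raise FormatError(f"{matrix_path}: duplicate gene id {dup!r}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"{metadata_path}: missing metadata columns {missing_cols}")
    meta_by_id = {}
    for _, row in meta.iterrows():
        try:
            sm = SampleMeta(
                sample_id=str(row["sample_id"]),
                compound=str(row["compound"]),
                dose=str(row["dose"]),
                time=float(row["time"]),
                replicate=int(row["replicate"]),
                system=str(row["system"]),
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{metadata_path}: bad metadata row {dict(row)}: {exc}")
        if sm.sample_id in meta_by_id:
            raise FormatError(f"{metadata_path}: duplicate sample id {sm.sample_id!r}")
        meta_by_id[sm.sample_id] = sm
    sample_ids = [str(c) for c in mat.columns[1:]]
    absent = [s for s in sample_ids if s not in meta_by_id]
    if absent:
        raise FormatError(f"samples in matrix but not metadata: {absent}")
    extra = [s for s in meta_by_id if s not in set(sample_ids)]
    if extra:
        raise FormatError(f"samples in metadata but not matrix: {extra}")
    values = mat.iloc[:, 1:].to_numpy(dtype=float)
    return ExpressionPanel(
        gene_ids=genes,
        samples=[meta_by_id[s] for s in sample_ids],
        values=values,
    )


def write_expression_panel(panel: ExpressionPanel, matrix_path, metadata_path) -> None:
    mat = pd.DataFrame(panel.values, columns=[s.sample_id for s in panel.samples])
    mat.insert(0, "gene_id", panel.gene_ids)
    mat.to_csv(matrix_path, sep="\t", index=False, float_format=FLOAT_FMT)
    meta = pd.DataFrame(
        [
            (s.sample_id, s.compound, s.dose, s.time, s.replicate, s.system)
            for s in panel.samples
        ],
        columns=list(META_COLUMNS),
    )
    meta.to_csv(metadata_path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# gene -> abstract annotations (gene2pubmed dialect)


def read_gene_abstract_map(path, taxon_filter: int | None = None) -> GeneAbstractMap:
    """Read a gene2pubmed-style TSV (taxon_id, GeneID, PubMed_ID).

    Lines for other taxa are skipped when ``taxon_filter`` is given.
    Duplicate (gene, abstract) pairs collapse. Ids must be integers.
    """
    by_gene: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                taxon, gene, pmid = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer id in {parts[:3]}")
            if taxon_filter is not None and taxon != taxon_filter:
                continue
            by_gene.setdefault(str(gene), set()).add(pmid)
    return GeneAbstractMap({g: frozenset(a) for g, a in by_gene.items()})


def write_gene_abstract_map(gmap: GeneAbstractMap, path, taxon_id: int = 9606) -> None:
    with open(path, "w") as fh:
        fh.write("#tax_id\tGeneID\tPubMed_ID\n")
        for gene in sorted(gmap.by_gene, key=lambda g: (len(g), g)):
            for pmid in sorted(gmap.by_gene[gene]):
                fh.write(f"{taxon_id}\t{gene}\t{pmid}\n")


# ---------------------------------------------------------------------------
# homolog tables (HomoloGene dialect)


def read_homolog_table(path) -> HomologTable:
    """Read a HomoloGene-style TSV: HID, taxon id, gene id (extras ignored)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(parts)}"
                )
            try:
                rows.append((int(parts[0]), int(parts[1]), str(int(parts[2]))))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer field in {parts[:3]}")
    df = pd.DataFrame(rows, columns=["group_id", "taxon_id", "gene_id"])
    return HomologTable(df)


def write_homolog_table(table: HomologTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# topic abstract sets


def read_topic_set(path) -> frozenset[int]:
    ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                ids.add(int(line))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer abstract id {line!r}")
    return frozenset(ids)


def write_topic_set(abstract_ids: Iterable[int], path) -> None:
    with open(path, "w") as fh:
        for a in sorted(abstract_ids):
            fh.write(f"{a}\n")


# ---------------------------------------------------------------------------
# probeset -> gene maps (2-column TSV; repeated rows for multi-gene probesets)


def read_probeset_map(path) -> dict[str, frozenset[str]]:
    by_probeset: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            probeset, gene = parts
            if not probeset or not gene:
                raise FormatError(f"{path}:{lineno}: empty field")
            by_probeset.setdefault(probeset, set()).add(gene)
    return {p: frozenset(g) for p, g in by_probeset.items()}


# ---------------------------------------------------------------------------
# rankings


def write_ranking(path, result) -> None:
    """Write an aggregation/ranking result as TSV (gene_id, score, rank).

    Sorted by rank, then gene id for determinism. ``result`` needs
    ``gene_ids``, ``scores`` and ``ranks`` attributes (AggregationResult,
    CombinedRanking, ...).
    """
    df = pd.DataFrame(
        {
            "gene_id": list(result.gene_ids),
            "score": np.asarray(result.scores, dtype=float),
            "rank": np.asarray(result.ranks, dtype=float),
        }
    )
    df = df.sort_values(["rank", "gene_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ranking(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    expected = ["gene_id", "score", "rank"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: ranking file must have columns {expected}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene id in ranking")
    return df
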