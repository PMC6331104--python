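"""Protocol orchestration: stage functions and a file-based pipeline.

Each stage reads the TSV artifacts of the previous stage and writes its
own, so every step is runnable standalone (no hidden in-memory coupling);
:func:`run_all` chains them. Directory layout under the output directory:

    panels/<compound>.matrix.tsv / .meta.tsv   simulated expression panels
    truth/planted.txt, truth/responsive.tsv    planted ground truth
    literature/gene2pubmed.tsv, topic.txt,
               universe.txt, homologene.tsv    literature inputs
    de/<compound>.tsv                          per-compound screen results
    ranks/<compound>.tsv                       extended partial rankings
    agg/<METHOD>.tsv, agg/combined.tsv         aggregated rankings
    literature/candidates.tsv                  literature positive set
    eval/roc_<METHOD>.tsv, eval/auc.tsv        ROC evaluation
    combined/all_sum.tsv                       sum of method rankings

A single global seed is fanned out to deterministic per-stage sub-seeds so
re-running with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .aggregate import (
    AGGREGATION_METHODS,
    AggregationResult,
    BirraParams,
    aggregate_all,
)
from .de import DEParams, de_analysis, frame_to_results, results_to_frame
from .evaluate import combine_sum, roc_auc
from .literature import gene_topic_association, select_candidates
from .orthology import one_to_one_orthologs
from .ranking import RankedList, rank_compound, read_ranked_list, write_ranked_list
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_homolog_table,
    simulate_literature,
    simulate_panel,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "stage_simulate", "stage_de", "stage_rank",
           "stage_aggregate", "stage_literature", "stage_evaluate", "stage_combine"]

TAXON_A, TAXON_B = 9606, 10116  # human, rat — synthetic ids reuse the roles


@dataclass
class PipelineConfig:
    """Configuration for the full protocol run."""

    outdir: Path = Path("toxrank_out")
    seed: int = 0
    system: str = "SYN"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    de: DEParams = field(default_factory=DEParams)
    birra: BirraParams = field(default_factory=BirraParams)
    methods: tuple[str, ...] = AGGREGATION_METHODS
    bottom: str = "midrank"
    fdr_cut: float = 0.05
    min_support: int = 3
    top_k: int = 400
    overlap_fraction: float = 0.8
    universe_size: int = 20000

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Read a flat key=value config file; keyword overrides win."""
        values: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, val = line.partition("=")
                values[key.strip()] = val.strip()
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_mapping(values)

    @classmethod
    def from_mapping(cls, values: dict) -> "PipelineConfig":
        sim_fields = {f.name: f for f in dataclasses.fields(SimulationConfig)}
        de_fields = {f.name: f for f in dataclasses.fields(DEParams)}
        birra_fields = {f.name: f for f in dataclasses.fields(BirraParams)}
        top: dict = {}
        sim: dict = {}
        de: dict = {}
        birra: dict = {}

        def coerce(raw, like):
            if isinstance(raw, str):
                if isinstance(like, bool):
                    return raw.lower() in ("1", "true", "yes")
                if isinstance(like, int):
                    return int(raw)
                if isinstance(like, float):
                    return float(raw)
                if isinstance(like, tuple):
                    parts = [p for p in raw.replace(",", " ").split() if p]
                    elem = like[0] if like else 1.0
                    return tuple(type(elem)(p) for p in parts)
                if isinstance(like, Path):
                    return Path(raw)
            return raw

        defaults = cls()
        sim_defaults = SimulationConfig()
        de_defaults = DEParams()
        birra_defaults = BirraParams()
        for key, raw in values.items():
            if key.startswith("sim."):
                name = key[4:]
                if name not in sim_fields:
                    raise ValueError(f"unknown simulation key {key!r}")
                sim[name] = coerce(raw, getattr(sim_defaults, name))
            elif key.startswith("de."):
                name = key[3:]
                if name not in de_fields:
                    raise ValueError(f"unknown DE key {key!r}")
                de[name] = coerce(raw, getattr(de_defaults, name))
            elif key.startswith("birra."):
                name = key[6:]
                if name not in birra_fields:
                    raise ValueError(f"unknown BIRRA key {key!r}")
                birra[name] = coerce(raw, getattr(birra_defaults, name))
            elif key == "methods":
                top["methods"] = tuple(
                    m.strip().upper() for m in str(raw).replace(",", " ").split() if m.strip()
                ) if isinstance(raw, str) else tuple(raw)
            elif hasattr(defaults, key):
                top[key] = coerce(raw, getattr(defaults, key))
            else:
                raise ValueError(f"unknown config key {key!r}")
        if "seed" in top and "seed" not in sim:
            sim["seed"] = top["seed"]
        if "system" in top and "system" not in sim:
            sim["system"] = top["system"]
        return cls(
            sim=SimulationConfig(**sim),
            de=DEParams(**de),
            birra=BirraParams(**birra),
            **top,
        )

    def __post_init__(self) -> None:
        # the panel stream inherits the global seed; auxiliary streams are
        # offset so every stage is deterministic but independent
        self.outdir = Path(self.outdir)
        self.sim = dataclasses.replace(self.sim, seed=int(self.seed), system=self.system)

    def subseed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the global seed."""
        offsets = {"panel": 0, "literature": 101_393, "homologs": 202_787}
        return (int(self.seed) + offsets.get(stage, 500_009)) % (2**31 - 1)


def _dirs(cfg: PipelineConfig) -> dict[str, Path]:
    out = Path(cfg.outdir)
    return {
        name: out / name
        for name in ("panels", "truth", "literature", "de", "ranks", "agg", "eval", "combined")
    }


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> None:
    d = _dirs(cfg)
    for p in d.values():
        p.mkdir(parents=True, exist_ok=True)
    panels, truth = simulate_panel(cfg.sim)
    for compound, panel in panels.items():
        tio.write_expression_panel(
            panel,
            d["panels"] / f"{compound}.matrix.tsv",
            d["panels"] / f"{compound}.meta.tsv",
        )
    (d["truth"] / "planted.txt").write_text("".join(g + "\n" for g in truth.planted))
    rows = []
    for compound in sorted(truth.responsive):
        for gene in sorted(truth.responsive[compound]):
            rows.append((compound, gene, "toxicity"))
        for gene in sorted(truth.off_target.get(compound, ())):
            rows.append((compound, gene, "off_target"))
    pd.DataFrame(rows, columns=["compound", "gene", "kind"]).to_csv(
        d["truth"] / "responsive.tsv", sep="\t", index=False
    )
    (d["truth"] / "toxic_compounds.txt").write_text(
        "".join(c + "\n" for c in truth.toxic_compounds)
    )
    gmap, topic, universe = simulate_literature(
        truth,
        overlap_fraction=cfg.overlap_fraction,
        universe_size=cfg.universe_size,
        seed=cfg.subseed("literature"),
    )
    tio.write_gene_abstract_map(gmap, d["literature"] / "gene2pubmed.tsv", taxon_id=TAXON_A)
    tio.write_topic_set(topic, d["literature"] / "topic.txt")
    (d["literature"] / "universe.txt").write_text(f"{universe}\n")
    homologs = simulate_homolog_table(
        next(iter(panels.values())).gene_ids,
        taxon_a=TAXON_A,
        taxon_b=TAXON_B,
        seed=cfg.subseed("homologs"),
    )
    tio.write_homolog_table(homologs, d["literature"] / "homologene.tsv")
    logger.info("simulate: %d compounds, %d genes, %d planted",
                len(panels), cfg.sim.n_genes, cfg.sim.n_planted)


def _list_compounds(cfg: PipelineConfig) -> list[str]:
    d = _dirs(cfg)
    return sorted(p.name[: -len(".matrix.tsv")] for p in d["panels"].glob("*.matrix.tsv"))


def stage_de(cfg: PipelineConfig) -> None:
    d = _dirs(cfg)
    d["de"].mkdir(parents=True, exist_ok=True)
    compounds = _list_compounds(cfg)
    if not compounds:
        raise FileNotFoundError("no expression panels found; run simulate first")
    for compound in compounds:
        panel = tio.read_expression_panel(
            d["panels"] / f"{compound}.matrix.tsv",
            d["panels"] / f"{compound}.meta.tsv",
        )
        results = de_analysis(panel, compound, cfg.de)
        results_to_frame(results).to_csv(
            d["de"] / f"{compound}.tsv", sep="\t", index=False, float_format="%.12g"
        )
        n_sel = sum(r.selected for r in results)
        logger.info("de: %s selected %d/%d genes", compound, n_sel, len(results))


def stage_rank(cfg: PipelineConfig) -> None:
    d = _dirs(cfg)
    d["ranks"].mkdir(parents=True, exist_ok=True)
    de_files = sorted(d["de"].glob("*.tsv"))
    if not de_files:
        raise FileNotFoundError("no screen results found; run the de stage first")
    for path in de_files:
        results = frame_to_results(pd.read_csv(path, sep="\t", dtype={"gene": str}))
        ranked = rank_compound(results, bottom=cfg.bottom)
        write_ranked_list(d["ranks"] / path.name, ranked)
        logger.info("rank: %s modulated=%d", path.stem, len(ranked.modulated))


def _load_ranked_lists(cfg: PipelineConfig) -> dict[str, RankedList]:
    d = _dirs(cfg)
    lists = {p.stem: read_ranked_list(p) for p in sorted(d["ranks"].glob("*.tsv"))}
    if not lists:
        raise FileNotFoundError("no ranked lists found; run the rank stage first")
    return lists


def stage_aggregate(cfg: PipelineConfig) -> dict[str, AggregationResult]:
    d = _dirs(cfg)
    d["agg"].mkdir(parents=True, exist_ok=True)
    lists = _load_ranked_lists(cfg)
    results = aggregate_all(lists, cfg.methods, cfg.birra)
    for method, res in results.items():
        tio.write_ranking(d["agg"] / f"{method}.tsv", res)
    # wide table: gene, then score_/rank_ per method
    universe = results[list(results)[0]].gene_ids
    wide = pd.DataFrame({"gene_id": universe})
    for method, res in results.items():
        wide[f"score_{method}"] = res.scores
        wide[f"rank_{method}"] = res.ranks
    wide.to_csv(d["agg"] / "combined.tsv", sep="\t", index=False, float_format="%.12g")
    logger.info("aggregate: %s over %d lists", ",".join(results), len(lists))
    return results


def stage_literature(cfg: PipelineConfig):
    d = _dirs(cfg)
    gmap = tio.read_gene_abstract_map(d["literature"] / "gene2pubmed.tsv")
    topic = tio.read_topic_set(d["literature"] / "topic.txt")
    universe = int((d["literature"] / "universe.txt").read_text().strip())
    homologs = tio.read_homolog_table(d["literature"] / "homologene.tsv")
    pairs = one_to_one_orthologs(homologs, TAXON_A, TAXON_B)
    assoc = gene_topic_association(gmap, topic, universe, topic_label="synthetic-topic")
    cand = select_candidates(
        assoc, fdr_cut=cfg.fdr_cut, min_support=cfg.min_support, pairs=pairs
    )
    cand.write(d["literature"] / "candidates.tsv")
    logger.info(
        "literature: %d tested, %d pre-ortholog, %d selected",
        len(cand.table),
        len(cand.selected_pre_ortholog or ()),
        len(cand.selected),
    )
    return cand


def _load_positives(cfg: PipelineConfig) -> frozenset[str]:
    d = _dirs(cfg)
    df = pd.read_csv(d["literature"] / "candidates.tsv", sep="\t", dtype={"gene": str})
    return frozenset(df.loc[df["selected"] == 1, "gene"])


def stage_evaluate(cfg: PipelineConfig) -> pd.DataFrame:
    d = _dirs(cfg)
    d["eval"].mkdir(parents=True, exist_ok=True)
    positives = _load_positives(cfg)
    if not positives:
        raise ValueError("no literature positives selected; cannot evaluate")
    rows = []
    for method in cfg.methods:
        df = tio.read_ranking(d["agg"] / f"{method}.tsv")
        res = AggregationResult(
            method=method,
            gene_ids=df["gene_id"].tolist(),
            scores=df["score"].to_numpy(),
            ranks=df["rank"].to_numpy(),
        )
        pos = positives & set(res.gene_ids)
        roc = roc_auc(res, pos)
        roc.points.to_csv(
            d["eval"] / f"roc_{method}.tsv", sep="\t", index=False, float_format="%.12g"
        )
        rows.append((method, roc.auc, len(pos)))
        logger.info("evaluate: %s AUC=%.4f (%d positives)", method, roc.auc, len(pos))
    auc = pd.DataFrame(rows, columns=["method", "auc", "n_positives"])
    auc.to_csv(d["eval"] / "auc.tsv", sep="\t", index=False, float_format="%.12g")
    return auc


def stage_combine(cfg: PipelineConfig) -> None:
    """Sum the requested method rankings into one consensus table."""
    d = _dirs(cfg)
    d["combined"].mkdir(parents=True, exist_ok=True)
    results = []
    for method in cfg.methods:
        df = tio.read_ranking(d["agg"] / f"{method}.tsv")
        results.append(
            AggregationResult(
                method=method,
                gene_ids=df["gene_id"].tolist(),
                scores=df["score"].to_numpy(),
                ranks=df["rank"].to_numpy(),
            )
        )
    combined = combine_sum(results)
    tio.write_ranking(d["combined"] / "all_sum.tsv", combined)
    logger.info("combine: wrote rank-sum over %d methods", len(results))


def run_all(cfg: PipelineConfig, simulate: bool = True) -> pd.DataFrame:
    """Run the whole protocol; returns the evaluation AUC table."""
    if simulate:
        stage_simulate(cfg)
    stage_de(cfg)
    stage_rank(cfg)
    stage_aggregate(cfg)
    stage_literature(cfg)
    auc = stage_evaluate(cfg)
    stage_combine(cfg)
    return auc
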