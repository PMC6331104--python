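"""Synthetic multi-compound toxicogenomics panels with planted structure.

The generator emulates a single-dose toxicogenomics screen: per compound, a
gene x sample log2 expression panel over four dose groups (vehicle control,
low, middle, high), several post-administration timepoints and biological
replicates. A fixed set of "planted" toxicity-responsive genes carries a
dose- and time-dependent expression shift in toxic compounds, with
per-gene sensitivities drawn around the configured mean responsiveness.
Every compound — toxic or not — additionally modulates a compound-specific
set of off-target responder genes drawn from the non-planted pool: each
compound perturbs hundreds of genes (stress and pharmacological responses)
of which only some are organ-toxicity related. This makes the sizes of the
per-compound differentially-expressed sets heterogeneous, and it makes the
non-toxic compounds contribute non-empty but toxicity-uninformative
(outlier) rankings, the situation robust rank aggregation is designed to
tolerate. Setting ``off_target_range=(0, 0)`` turns the off-target arm off,
leaving non-toxic compounds entirely signal-free.

The signal model for a responsive gene g in compound c is

    log2 x = baseline_g + sign * magnitude * w(dose) * g(time) + noise

with dose weights w(control, low, middle, high) = (0, 1/3, 2/3, 1), a
monotone saturating time profile g(t) = (1 - exp(-t/tau)) / (1 -
exp(-t_max/tau)) scaled to [0, 1], and iid Gaussian noise. Toxicity-planted
genes respond with magnitude = effect_size exactly, so the realized
high-dose/late-time shift of planted responders averages to effect_size.

A companion generator plants literature structure: genes receive abstract
annotations, and a configurable fraction of planted genes is enriched for
topic-linked abstracts so the literature-mining arm has a recoverable
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import DOSE_LEVELS, ExpressionPanel, GeneAbstractMap, HomologTable, SampleMeta

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_panel",
    "simulate_literature",
    "simulate_homolog_table",
    "DOSE_WEIGHTS",
]

DOSE_WEIGHTS = {"control": 0.0, "low": 1.0 / 3.0, "middle": 2.0 / 3.0, "high": 1.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Defaults describe a 20-compound panel of 2,000 genes with 100 planted
    toxicity genes, each responding in a given toxic compound with
    probability 0.6, at a maximal shift of 2.0 log2 units against residual
    noise of SD 0.5 — with four timepoints and three replicates as in an
    in-vivo single-dose design.
    """

    n_genes: int = 2000
    n_compounds: int = 20
    n_toxic_compounds: int = 16
    n_planted: int = 100
    responsiveness: float = 0.6
    effect_size: float = 2.0
    noise_sd: float = 0.5
    timepoints: tuple[float, ...] = (3.0, 9.0, 12.0, 24.0)
    replicates: int = 3
    seed: int = 0
    # shape/realism knobs
    time_scale: float = 1.0  # hours to ~63% of the saturating response
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    off_target_range: tuple[int, int] = (30, 300)
    responsiveness_concentration: float = 5.0
    system: str = "SYN"

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted exceeds n_genes")
        if self.n_toxic_compounds > self.n_compounds:
            raise ValueError("n_toxic_compounds exceeds n_compounds")
        if not 0.0 <= self.responsiveness <= 1.0:
            raise ValueError("responsiveness must be in [0, 1]")
        if len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    planted: list[str]
    toxic_compounds: list[str]
    responsive: dict[str, set[str]]  # compound -> toxicity-responsive genes
    off_target: dict[str, set[str]]  # compound -> off-target responder genes
    effects: dict[str, float]  # planted gene -> signed maximal log2 shift
    config: SimulationConfig

    def validate(self) -> None:
        planted = set(self.planted)
        for compound, genes in self.responsive.items():
            if compound in self.toxic_compounds:
                if not genes <= planted:
                    raise ValueError("responsive subset not within planted set")
            elif genes:
                raise ValueError("non-toxic compound has responsive genes")
        for genes in self.off_target.values():
            if genes & planted:
                raise ValueError("off-target responders overlap planted set")


def _time_profile(times: np.ndarray, tau: float) -> np.ndarray:
    """Monotone saturating profile scaled so the latest timepoint maps to 1."""
    t_max = float(np.max(times))
    return (1.0 - np.exp(-times / tau)) / (1.0 - np.exp(-t_max / tau))


def simulate_panel(
    cfg: SimulationConfig,
) -> tuple[dict[str, ExpressionPanel], GroundTruth]:
    """Generate one ExpressionPanel per compound plus the ground truth.

    Identical configs (same seed) give bit-identical panels.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    compounds = [f"cpd{i:02d}" for i in range(1, cfg.n_compounds + 1)]
    toxic = compounds[: cfg.n_toxic_compounds]

    planted_idx = rng.choice(cfg.n_genes, size=cfg.n_planted, replace=False)
    planted_idx.sort()
    planted = [genes[i] for i in planted_idx]
    planted_set = set(planted)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_planted)
    effects = {g: float(s * cfg.effect_size) for g, s in zip(planted, signs)}
    # per-gene sensitivity: Beta-distributed response probability with mean
    # `responsiveness` (genes differ in how broadly compounds modulate them)
    conc = cfg.responsiveness_concentration
    if cfg.responsiveness in (0.0, 1.0) or not np.isfinite(conc):
        gene_resp = np.full(cfg.n_planted, cfg.responsiveness)
    else:
        gene_resp = rng.beta(cfg.responsiveness * conc, (1 - cfg.responsiveness) * conc,
                             size=cfg.n_planted)

    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    times = np.array(cfg.timepoints, dtype=float)
    gt = _time_profile(times, cfg.time_scale)
    non_planted_idx = np.array(
        [i for i in range(cfg.n_genes) if genes[i] not in planted_set]
    )

    responsive: dict[str, set[str]] = {c: set() for c in compounds}
    off_target: dict[str, set[str]] = {c: set() for c in compounds}
    panels: dict[str, ExpressionPanel] = {}
    lo, hi = cfg.off_target_range
    for compound in compounds:
        is_toxic = compound in toxic
        samples: list[SampleMeta] = []
        cells: list[tuple[float, float]] = []  # (dose weight, time profile)
        for dose in DOSE_LEVELS:
            for ti, t in enumerate(times):
                for rep in range(1, cfg.replicates + 1):
                    samples.append(
                        SampleMeta(
                            sample_id=f"{compound}_{dose}_t{t:g}_r{rep}",
                            compound=compound,
                            dose=dose,
                            time=float(t),
                            replicate=rep,
                            system=cfg.system,
                        )
                    )
                    cells.append((DOSE_WEIGHTS[dose], gt[ti]))
        dose_w = np.array([c[0] for c in cells])
        time_w = np.array([c[1] for c in cells])
        signal = np.zeros((cfg.n_genes, len(cells)))
        if is_toxic and cfg.n_planted:
            hit = rng.random(cfg.n_planted) < gene_resp
            resp_genes = [g for g, h in zip(planted, hit) if h]
            responsive[compound] = set(resp_genes)
            for g, h, gi in zip(planted, hit, planted_idx):
                if h:
                    signal[gi, :] = effects[g] * dose_w * time_w
        # compound-specific off-target responders among non-planted genes:
        # every compound (toxic or not) perturbs its own unrelated gene set,
        # so non-toxic compounds contribute toxicity-uninformative rankings
        if non_planted_idx.size and hi > 0:
            n_off = int(
                round(math.exp(rng.uniform(math.log(max(lo, 1)), math.log(hi))))
            )
            n_off = min(n_off, non_planted_idx.size)
            off_idx = rng.choice(non_planted_idx, size=n_off, replace=False)
            off_idx.sort()
            off_target[compound] = {genes[i] for i in off_idx}
            off_sign = rng.choice([-1.0, 1.0], size=n_off)
            off_mag = cfg.effect_size * rng.uniform(0.5, 1.5, size=n_off)
            for i, s, m in zip(off_idx, off_sign, off_mag):
                signal[i, :] = s * m * dose_w * time_w
        noise = rng.normal(0.0, cfg.noise_sd, size=signal.shape)
        values = baselines[:, None] + signal + noise
        panels[compound] = ExpressionPanel(
            gene_ids=list(genes), samples=samples, values=values
        )

    truth = GroundTruth(
        planted=planted,
        toxic_compounds=list(toxic),
        responsive=responsive,
        off_target=off_target,
        effects=effects,
        config=cfg,
    )
    truth.validate()
    return panels, truth


def _gene_ids(n_genes: int) -> list[str]:
    # Entrez-style numeric ids; fixed width so lexicographic == numeric order
    return [str(10000 + i) for i in range(1, n_genes + 1)]


def simulate_literature(
    truth: GroundTruth,
    overlap_fraction: float = 0.8,
    universe_size: int = 20000,
    seed: int = 0,
    topic_size: int = 300,
    abstracts_per_gene: float = 4.0,
    topic_abstracts_per_hit: tuple[int, int] = (3, 6),
    background_topic_rate: float | None = None,
) -> tuple[GeneAbstractMap, frozenset[int], int]:
    """Plant literature annotations enriched for a topic in planted genes.

    A fraction ``overlap_fraction`` of the planted genes receives at least
    three topic-linked abstracts (count uniform in
    ``topic_abstracts_per_hit``) on top of its background annotations.
    Every gene additionally receives 1 + Poisson(``abstracts_per_gene``)
    background abstracts, each of which is a topic abstract with probability
    ``background_topic_rate`` (default: the natural rate ``topic_size /
    universe_size``; 0.0 makes background annotations strictly off-topic).
    With ``overlap_fraction=0`` the planted and literature-supported gene
    sets are independent. Abstract ids within a gene are distinct, drawn
    without replacement from the universe.

    Returns (gene->abstract map, topic abstract set, universe size).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    lo_hit, hi_hit = topic_abstracts_per_hit
    if lo_hit < 3:
        raise ValueError("topic-linked abstracts per enriched gene must be >= 3")
    if universe_size < 2 * topic_size or universe_size < 10 * hi_hit:
        raise ValueError("universe too small to honor the requested counts")
    if background_topic_rate is None:
        background_topic_rate = topic_size / universe_size
    if not 0.0 <= background_topic_rate <= 1.0:
        raise ValueError("background_topic_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cfg = truth.config
    universe = universe_size
    topic_arr = np.sort(rng.choice(universe, size=topic_size, replace=False)) + 1
    topic = frozenset(int(a) for a in topic_arr)
    non_topic_arr = np.setdiff1d(np.arange(1, universe + 1), topic_arr)

    all_genes = _gene_ids(cfg.n_genes)
    n_hit = int(round(overlap_fraction * len(truth.planted)))
    hit_genes = (
        set(rng.choice(np.array(sorted(truth.planted)), size=n_hit, replace=False).tolist())
        if n_hit
        else set()
    )

    by_gene: dict[str, frozenset[int]] = {}
    for gene in all_genes:
        n_bg = 1 + int(rng.poisson(abstracts_per_gene))
        n_bg_topic = int(rng.binomial(n_bg, background_topic_rate))
        n_topic = n_bg_topic
        if gene in hit_genes:
            n_topic += int(rng.integers(lo_hit, hi_hit + 1))
        n_topic = min(n_topic, topic_arr.size)
        n_off = min(n_bg - n_bg_topic, non_topic_arr.size)
        picks_topic = rng.choice(topic_arr, size=n_topic, replace=False)
        picks_off = rng.choice(non_topic_arr, size=n_off, replace=False)
        by_gene[gene] = frozenset(int(a) for a in picks_topic) | frozenset(
            int(a) for a in picks_off
        )
    gmap = GeneAbstractMap(by_gene)
    gmap.validate_universe(universe)
    return gmap, topic, universe


def simulate_homolog_table(
    genes,
    taxon_a: int = 9606,
    taxon_b: int = 10116,
    paired_fraction: float = 0.9,
    seed: int = 0,
) -> HomologTable:
    """Synthetic homolog-group table over ``genes`` (taxon-A ids).

    A fraction ``paired_fraction`` of genes gets a clean one-to-one partner
    in taxon B (partner id = ``9<gene>``); the rest are placed in groups that
    are not one-to-one (either A-only, or with two B members) so the
    one-to-one restriction downstream is exercised. Deterministic per seed.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    genes = list(genes)
    rows = []
    paired = rng.random(len(genes)) < paired_fraction
    for i, (gene, ok) in enumerate(zip(genes, paired), start=1):
        partner = f"9{gene.lstrip('g').lstrip('0') or '0'}" if gene.startswith("g") else f"9{gene}"
        rows.append((i, taxon_a, str(gene)))
        if ok:
            rows.append((i, taxon_b, partner))
        elif rng.random() < 0.5:
            rows.append((i, taxon_b, partner))
            rows.append((i, taxon_b, partner + "1"))
        # else: A-only group
    df = pd.DataFrame(rows, columns=["group_id", "taxon_id", "gene_id"])
    return HomologTable(df)
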