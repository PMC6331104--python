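"""Compare and combine consensus rankings from two model systems.

Simulates one screen with a shared set of planted toxicity genes, splits
the compound panel into two halves — think of two model systems profiled
with different compound subsets — computes each half's AR consensus, and
compares/combines the two rankings.
"""

from toxrank import (
    SimulationConfig,
    aggregate_all,
    combine_diff,
    combine_sum,
    de_analysis,
    rank_compound,
    simulate_panel,
    spearman,
    top_k,
)

cfg = SimulationConfig(
    n_genes=400, n_compounds=12, n_toxic_compounds=10, n_planted=40,
    seed=21, off_target_range=(10, 50),
)
panels, truth = simulate_panel(cfg)
lists = {c: rank_compound(de_analysis(p, c)) for c, p in panels.items()}

compounds = sorted(lists)
systems = {"HH": compounds[0::2], "RH": compounds[1::2]}
ar = {
    name: aggregate_all({c: lists[c] for c in subset})["AR"]
    for name, subset in systems.items()
}

rho, p = spearman(ar["HH"], ar["RH"])
print(f"Spearman rho between the two AR rankings: {rho:.2f} (p = {p:.2e})")

combined = combine_sum([ar["HH"], ar["RH"]])
genes, size = top_k(combined, 10)
planted = set(truth.planted)
hits = sum(g in planted for g in genes)
print(f"top {size} genes by rank sum ({hits} of them planted toxicity genes):")
print(" ", " ".join(genes))

diff = combine_diff(ar["HH"], ar["RH"])
hh_specific, _ = top_k(diff, 5)
print("most HH-specific genes (low HH rank, high RH rank):")
print(" ", " ".join(hh_specific))
# A positive rho means the systems respond similarly; the rank-sum head
# collects genes perturbed everywhere, the rank-difference tails collect
# system-specific responders.
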