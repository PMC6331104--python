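"""Derive a literature positive gene set by abstract co-occurrence testing.

Simulates gene->abstract annotations in which most planted genes carry at
least three topic-linked abstracts, tests every annotated gene with the
one-tailed Fisher exact test against the abstract universe, and applies
the FDR, support and one-to-one-ortholog filters.
"""

from toxrank import (
    SimulationConfig,
    gene_topic_association,
    one_to_one_orthologs,
    select_candidates,
    simulate_homolog_table,
    simulate_literature,
    simulate_panel,
)

_, truth = simulate_panel(SimulationConfig(n_compounds=2, n_toxic_compounds=1, seed=5))
gmap, topic, universe = simulate_literature(
    truth, overlap_fraction=0.8, universe_size=20000, seed=5
)
print(f"{len(gmap)} genes annotated, {gmap.n_pairs()} gene-abstract pairs, "
      f"topic has {len(topic)} of {universe} abstracts")

assoc = gene_topic_association(gmap, topic, universe, topic_label="hepatotoxicity")
table = simulate_homolog_table(sorted(gmap.by_gene), seed=5)
pairs = one_to_one_orthologs(table, taxon_a=9606, taxon_b=10116)
candidates = select_candidates(assoc, fdr_cut=0.05, min_support=3, pairs=pairs)

pre = candidates.selected_pre_ortholog
print(f"{len(pre)} genes pass FDR<=0.05 with >=3 supporting abstracts")
print(f"{len(candidates.selected)} remain after the one-to-one ortholog filter")
planted = set(truth.planted)
print(f"of these, {len(candidates.selected & planted)} are planted toxicity genes")
top = candidates.table.nsmallest(5, "q")[["gene", "p", "q", "support"]]
print(top.to_string(index=False))
# Selected genes are the literature-derived positives later used to score
# the expression-based rankings by ROC analysis.
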