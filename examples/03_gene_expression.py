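"""Link super-enhancers to adjacent genes and classify expression change.

Each called super-enhancer is assigned the gene whose TSS is nearest its
midpoint; genes are then clustered by tumor/normal FPKM fold change
(threshold 1.5, pseudocount 2^-5).  The generator boosts tumor expression
4x for genes adjacent to planted supers, so most links should come out
"increased".
"""

from enhancerscope import (
    SimConfig,
    assign_adjacent_genes,
    call_super_enhancers,
    classify_expression_change,
    simulate_expression,
    simulate_genome,
    simulate_peaks_and_tracks,
    summarize_expression_by_class,
)

cfg = SimConfig(seed=20190312, n_super_clusters=10)
genome = simulate_genome(cfg)
sim = simulate_peaks_and_tracks(cfg, genome)
expr = simulate_expression(cfg, genome, sim.truth)

table = call_super_enhancers(sim.peaks["H3K27ac"], genome.genes, sim.tracks["H3K27ac"])
links = assign_adjacent_genes(table.super_regions(), genome.genes, mode="nearest")
links = classify_expression_change(links, expr, fc_threshold=1.5)

print(f"{len(links)} super-enhancer-adjacent genes:")
for link in links:
    print(f"  {link.gene_id}: fold change {link.fold_change:.2f} -> {link.cluster}")

typical_links = assign_adjacent_genes(table.typical_regions(), genome.genes)
summary = summarize_expression_by_class(
    expr,
    {
        "super-adjacent": [l.gene_id for l in links],
        "typical-adjacent": [l.gene_id for l in typical_links],
    },
)
print("\nmean-FPKM quartiles per class and condition:")
print(summary.round(2).to_string(index=False))
# Super-adjacent genes show a higher tumor median than typical-adjacent
# ones, mirroring how enhancer load and transcription go together.
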