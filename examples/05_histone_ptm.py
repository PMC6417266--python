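"""Histone peptidoform arithmetic: relative abundance, single marks, volcano.

Simulates a 3-vs-3 DIA peak-area table with planted tumor effects
(acetylations up, H3K36me3 down), converts areas to percent relative
abundance within each peptide, sums single-mark abundances across
peptidoforms and tests each mark with a homoscedastic t-test.
"""

from enhancerscope import (
    SimConfig,
    compare_all_marks,
    peptidoform_relative_abundance,
    simulate_peptidoform_areas,
    volcano_table,
)
from enhancerscope.ptm import all_single_marks

cfg = SimConfig(seed=20190312)
areas = simulate_peptidoform_areas(cfg)
print(f"{len(areas)} peptidoforms over {areas['peptide_id'].nunique()} peptides")

percents = peptidoform_relative_abundance(areas)
marks = all_single_marks(percents)
print(f"{len(marks)} single marks quantified")

groups = (["normal_1", "normal_2", "normal_3"], ["tumor_1", "tumor_2", "tumor_3"])
results = compare_all_marks(marks, *groups, alpha=0.05)
vt = volcano_table(results)

print("\nsignificant marks (p < 0.05):")
sig = vt[vt["significant"]].sort_values("neg_log10_p", ascending=False)
print(sig.round(3).to_string(index=False))
# Fold change > 0 on the log2 axis means higher relative abundance in
# tumor; the planted effects (H3K27ac, H4K8ac, H3K4me3 up, H3K36me3 down)
# should dominate this list.
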