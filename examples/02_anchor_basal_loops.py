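"""Anchor/basal classification and loop categorization.

A peak that overlaps any loop anchor of its mark is an *anchor* peak;
genes inherit the status through their 1 kb-upstream-through-TTS window.
Loops are categorized by what their anchors touch: promoter-promoter (PP),
promoter-intergenic (PI), or intergenic-intergenic (II).
"""

from collections import Counter

from chiahub import (
    SimConfig,
    categorize_loops,
    classify_anchor_basal_genes,
    classify_anchor_basal_peaks,
    generate_dataset,
    group_rank_test,
)

ds = generate_dataset(SimConfig(n_genes=800, n_tissues=12, n_hubs=15, seed=7))
mark = "H3K4me3"
peaks, loops = ds.peaks[mark], ds.loops[mark]

peak_status = classify_anchor_basal_peaks(peaks, loops)
gene_status = classify_anchor_basal_genes(ds.genes, peaks, peak_status)
n_anchor = sum(s.status == "anchor" for s in peak_status)
print(f"{mark}: {n_anchor}/{len(peaks)} peaks are loop anchors")

cats = Counter(c.category for c in categorize_loops(loops, ds.genes))
print(f"loop categories: {dict(cats)}")  # active marks are overwhelmingly PP

anchor_fpkm = [ds.expression.fpkm(s.subject_id, "seedling")
               for s in gene_status if s.status == "anchor"]
basal_fpkm = [ds.expression.fpkm(s.subject_id, "seedling")
              for s in gene_status if s.status == "basal"]
_, p = group_rank_test(anchor_fpkm, basal_fpkm, alternative="greater")
print(f"anchor > basal gene expression: one-sided rank-sum p = {p:.2e}")
# The planted 2x anchor boost makes loop-involved genes measurably more
# expressed than genes whose peaks stay outside interactions.
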