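"""Generate a synthetic multi-omic dataset with planted structure.

Builds a toy two-chromosome genome with a centromeric block, places genes
on the arms, and plants mark-specific peaks and loops, chromatin hubs, TF
targets, accessible regions, SNPs and an expression matrix. All planted
features are written as truth tables alongside the standard-format files.
"""

from chiahub import SimConfig, generate_dataset, write_dataset

cfg = SimConfig(n_genes=800, n_tissues=12, n_hubs=15, n_cres=200, n_snps=100, seed=7)
ds = generate_dataset(cfg)
files = write_dataset(ds, "scratch/example_dataset")

print(f"genes: {len(ds.genes)} on {len(ds.chrom_sizes)} chromosomes")
for mark, loops in sorted(ds.loops.items()):
    if mark != "ATAC":
        print(f"loops[{mark}]: {len(loops)}")
print(f"planted hubs: {len(ds.truth.hubs)}, accessible regions: {len(ds.truth.cres)}")
print(f"wrote {len(files)} files to scratch/example_dataset")
# Every loop, hub, CRE state and SNP placement above is recorded in
# truth_*.tsv, so downstream modules can be validated against exact truth.
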