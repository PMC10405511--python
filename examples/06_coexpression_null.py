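"""Co-expression of interacting gene pairs vs a distance-matched null.

Interacting anchor-gene pairs are compared, across tissues, with random
gene pairs drawn at the same genomic distance (log2 distance bins), so the
test asks whether looping adds co-expression beyond what mere linear
proximity explains. The empirical p uses the add-one convention: its
minimum over n_sim simulations is 1/(n_sim + 1).
"""

from chiahub import SimConfig, distance_matched_null, generate_dataset, mean_pair_pcc

ds = generate_dataset(SimConfig(seed=7))  # defaults: 43 tissues, pair PCC 0.5
pairs = list(ds.truth.pairs[["gene_a", "gene_b"]].itertuples(index=False, name=None))

observed, n_used, _ = mean_pair_pcc(pairs, ds.expression)
print(f"{n_used} interacting pairs, observed mean PCC = {observed:.3f}")

res = distance_matched_null(
    pairs, [g.gene_id for g in ds.genes], ds.genes, ds.expression,
    n_sim=1000, mode="A", seed=7,
)
print(f"distance-matched null mean PCC = {res.null_means.mean():.4f}")
print(f"empirical p = {res.p_value:.6f} (minimum attainable 1/1001 = 0.000999)")
# The planted pair correlation (0.5) towers over the distance-matched
# null (~0), so the p-value bottoms out at its add-one minimum.
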