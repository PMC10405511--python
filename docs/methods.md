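# Methods

This note documents the models and procedures chiahub implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinates and records

All coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted at I/O only. A gene's promoter is 1 kb upstream to 0.5 kb
downstream of the TSS, strand-aware and clipped (never dropped) at
chromosome edges. The *gene association window* — used both for
anchor-gene assignment and for carving promoter/genic/intergenic space —
runs from 1 kb upstream of the TSS through the TTS; the gene body starts
0.5 kb downstream of the TSS. Loops store two sorted, non-overlapping
anchors with mark, PET count and FDR; input loops with FDR ≥ 0.05
(configurable) are dropped at parse time and duplicates on
(anchor_a, anchor_b, mark) collapse to the maximal PET count. BEDPE has no
single standard, so the writer/reader pair fixes one dialect (columns 7–11:
name, pet_count, strand1, strand2, fdr) with configurable indices.

## Anchor/basal annotation

A peak is an anchor iff it overlaps any loop anchor of its own mark by at
least 1 bp (threshold configurable; 1 bp is the weakest consistent reading
of "involved in an interaction"). A gene is an anchor gene if any anchor
peak overlaps its association window; an anchor peak dominates any basal
peak on the same gene; genes touched by no peak are excluded rather than
called basal, so the basal class means "bound but not looping". Loop
categories label each anchor promoter / intergenic / genic, with promoter
taking precedence when an anchor touches several spaces — active-mark
loops are expected to be overwhelmingly promoter–promoter, which this
precedence makes well-defined. Loop span is measured midpoint-to-midpoint;
the 1 Mb and 10 Mb span-class boundaries are inclusive on the middle
class. SNP membership in a loop means membership in an anchor interval,
not the intervening span, and the three mark groups (active =
H3K4me3 ∪ RNAPII ∪ H3K4me1; repressive = H3K27me3; inactive = H3K9me2)
may overlap, so a SNP can count in several groups.

## Chromatin hubs

Overlapping loop anchors merge into node candidates; a candidate's degree
is the number of loops touching it and hubs require degree ≥ 5 (the
configurable detection threshold). Node and connecting genes come from the
anchor-gene rule below. Enrichment of TF targets per hub is a one-sided
(greater) Fisher exact test on the 2×2 (in hub × is target) table over a
gene universe, screened at raw p < 0.05 as the enriched flag;
Benjamini–Hochberg-adjusted p-values are reported alongside for
transparency but do not drive the flag. The random control redraws
size-matched gene sets from the anchor-gene pool without replacement,
applies the same screen, and counts targets inside passing random hubs.

Differential classification matches hubs across conditions by node gene
(hubs absent in one condition contribute Nc = 0 or Nm = 0) and evaluates,
with Ns = Nc − Nm:

- EDH iff Ns/Nc ≥ 0.7 and Ns ≥ 3;
- else PDH iff 0.3 ≤ Ns/Nc < 0.7 and Ns ≥ 3;
- else FH iff (−Ns)/Nm ≥ 0.3 and Nc − Nm ≤ −3;
- else stable.

Each rule's conditions are conjunctions; the order EDH → PDH → FH → stable
resolves the one residual ambiguity (a ratio whose denominator vanishes is
skipped; the complementary branch still fires). The full (Nc, Nm) grid is
checked against an independently coded brute-force evaluation in the test
suite. For EDH/PDH hubs the condition-1 connecting genes are partitioned
into aggregated (still connected) and separated (lost) sets.

## Anchor-gene assignment and networks

An anchor is assigned to a gene when ≥ 50 % *of the anchor's length* lies
inside the gene's association window — anchor-fraction rather than
gene-fraction, so short anchors remain assignable (configurable). For
active marks, a multi-gene anchor resolves to the highest-FPKM candidate
(tie → longer overlap → lexicographically first id), using the first
tissue column (seedling by convention) of the expression table; H3K27me3
anchors keep all candidates, so repressive edges can fan out. Networks
expand from seed genes: hop 1 keeps loops with an anchor gene among the
seeds, hop 2 additionally keeps loops touching any gene reached at hop 1;
hop-2 loops are not required to repeat hop-1 marks. A node is active /
repressive / mixed according to the marks of its incident edges.

## Cis-regulatory elements

Genomic classification tests, per accessible region, the fraction of the
region's length inside promoter space (PRE), intergenic space (DRE:
complement of the association windows), and gene-body space (intragenic);
classes reaching 50 % resolve by the priority PRE > DRE > intragenic. A
region reaching 50 % nowhere falls back to the maximal-overlap class (tie
→ priority) and is flagged — an extension of the 50 % rule, which is
otherwise silent on that case.

States and statuses follow a fixed decision tree. DRE branch: the
nearest peaks within 500 bp (edge-to-edge, 0 when overlapping; only the
minimal-distance peak set counts) decide — if they are H3K27me3-only the
DRE is poised, anchor or basal according to the peak's status; otherwise
the DRE is active, anchor iff its nearest protein-coding gene (minimal
|CRE midpoint − TSS|, tie → lexicographic) is an anchor gene. PRE branch:
overlap with an H3K27me3 anchor peak alone → poised anchor; with an
H3K27me3 anchor peak and an active-mark anchor peak simultaneously →
poiAct (bivalent) anchor; else a PRE whose promoter-linked gene is basal
is a basal PRE with its state read from the overlapping peak marks; the
remainder are active anchors. Intragenic regions are carried through
unannotated. Note one asymmetry built into these rules: an
active anchor DRE is defined by its nearest gene's status, so it can in
principle carry no long-range connecting genes; the synthetic data places
active anchor DREs inside loop anchors, where connecting genes always
exist. Gene status for this tree is computed over peaks of *all* marks, so
a gene whose only peak is basal H3K27me3 reads as basal, not unclassified.

## Co-expression statistics

Expression breadth counts tissues with FPKM ≥ 1 (threshold configurable
and reported). Pair co-expression is the mean Pearson correlation (sample
n−1 normalization) over interacting gene pairs; zero-variance profiles are
excluded pairwise and counted. The distance-matched null draws, for each
observed pair, a same-chromosome candidate pair whose TSS distance falls
in the same log2 bin of width 0.25 (exact distance matching is infeasible
on finite gene sets; binning preserves the null's intent); an empty bin
widens once by one bin either side, then falls back to the nearest
non-empty bin. Mode A draws from all genes, mode B from a supplied
anchor-gene set. The empirical p-value uses the add-one convention,
p = (1 + #{null means ≥ observed}) / (1 + n_sim), so p > 0 always and the
minimum at n_sim = 1000 is 1/1001. Group comparisons are Mann–Whitney
rank-sum tests (scipy), with an exact-permutation option at small n.

## Contact-map architecture

Binning adds each intrachromosomal loop's PET count at the anchor-midpoint
bin pair (interchromosomal contacts are out of scope). ICE balancing
divides rows/columns of retained bins by their marginals, renormalized to
mean 1 each round, until the coefficient of variation of retained
marginals < tol (default 1e-4, max 100 iterations); biases are returned so
raw = biasᵢ·biasⱼ·balanced, recoverable under either marginal-target
convention. Loop-derived matrices are much sparser than sequencing-depth
contact maps and may stop short of full equalization; non-convergence
returns the result with a warning rather than failing. O/E divides each
cell by the mean contact at its exact bin distance (no smoothing — toy
matrices are small; per-stratum means equal 1 by construction).
Compartments are the leading eigenvector of the Pearson correlation matrix
of O/E rows, with fewer than 10 retained bins refused as unstable; because
an eigenvector's sign is arbitrary, labels are oriented so positive bins
have the higher mean orientation track — per-bin gene density by default,
pluggable — and positive bins are A. The aggregate chromosome map
block-averages each chromosome onto a common grid and sums; the weighted
cell mean equals the matrix mean, and the operation is linear and
order-invariant.

Interacting-domain segmentation is this package's operationalization of a
connectivity-based domain concept, made fully explicit here: per mark group, 10 kb bins carrying ≥ 1 loop anchor are
covered, runs merge across ≤ 1 uncovered bin (both parameters
configurable and recorded), then bins covered by exactly one group become
AID/RID/HID, by two or more MID, by none gap. Segments tile each
chromosome exactly. The resulting coverage percentages are a property of
the input loop set, not a claim about any particular genome.

## Synthetic data

The generator emulates the target experimental design at desk scale. Defaults: 2
chromosomes × 20 Mb with a centromeric block at fractions 0.40–0.60 of
each chromosome; 2,000 non-overlapping genes on the arms (one per layout
slot, which also reserves a clean intergenic zone per slot for distal
anchors and elements); 43 tissues; background loop counts
H3K4me3/RNAPII/H3K4me1/H3K27me3/H3K9me2 = 250/125/125/200/200 with
category mixes 96/3/1 (active, P-P/P-I/I-I), 40/30/30 (H3K27me3), and
100 % I-I for H3K9me2 (whose anchors all lie in the pericentromere); 50
hubs of degree 8–12 on top of the background (hub loops and the support
loops that realize bivalent genes and DRE targets are tagged by origin in
the truth tables, so mix-recovery checks run on the background subset).
Span laws are log-normal — a modeling choice; only target ranges and
medians are fixed — with medians 30 kb (active), 50 kb (H3K27me3) and 105 kb
(H3K9me2, log-sd 0.45 so the central ~95 % covers ≈ 39–341 kb). H3K9me2
spans are placed exactly; arm spans are realized through gene spacing and
are approximate.

Expression is log-normal: ln FPKM = b_g + σ·z with gene-level
b_g ~ N(1, 1) and tissue log-sd σ = 1. Active anchor genes are multiplied
by the planted boost (default 2×), and genes connected to active DREs by a
further 1.5×. Planted co-expression uses a shared latent factor on the log
scale for a disjoint set of interacting pairs (default 200), with loading
√r solved analytically from the log-normal correlation identity
ρ = (e^{rσ²} − 1)/(e^{σ²} − 1), so the expected *linear-scale* Pearson
correlation equals the configured value (default 0.5). Accessible regions
(default 600) are planted with class fractions 61/29/10 (PRE/DRE/
intragenic) and state fractions 80/13/7 (active/poised/poiAct), with a
70 % anchor share; SNPs (default 200) are planted inside loop anchors
*exclusive* to one mark group at fractions 23/11/11 % (active/repressive/
inactive) so the group fractions are recovered exactly despite groups
being allowed to overlap in general.

The second condition relabels a shuffled 10 %/20 %/5 % of hubs as
EDH/PDH/FH: EDH hubs lose all member loops; PDH hubs lose
max(3, ⌈0.3·Nc⌉) connecting genes — which requires Nm ≥ 5 so the hub
remains detectable, hence the default degree range 8–12; FH hubs gain
max(3, ⌈3Nc/7⌉) fresh basal genes. Condition FPKM vectors carry
multiplicative log-normal noise (log-sd 0.1), with separated genes further
multiplied by 0.4. One global seed fans out to per-component sub-seeds by
fixed offsets; identical configs give byte-identical output files.

What the generator does not emulate: read-level data, sequence content,
realistic peak-width and intensity distributions, distance-decay
background contacts (matrices contain loop signal only, hence the sparse-
matrix caveats above), interchromosomal loops, DNA methylation, and
biological coupling between marks beyond the planted structures. Passing
tests therefore demonstrate correctness of the analysis layer on inputs
with known truth, not performance on sequencing noise.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the scales
above or smaller (the differential-hub recovery uses a dedicated 200-hub,
2,800-gene configuration; null calibration uses 50 expression replicates
at 200 simulations each; power uses 1,000 simulations). All randomness
flows through numpy Generators seeded from explicit arguments; the
pipeline writes SHA-256 checksums of every output so reruns are verifiable
hash-for-hash.

## Known limitations

Anchor merging uses simple interval overlap (1 bp); heavily overlapping
anchor sets from many marks can chain into large nodes. Hub identity
across conditions relies on node genes; node anchors with no assignable
gene are dropped from the comparison rather than matched by reciprocal
overlap. The compartment caller is intended for coarse bins on dense
matrices; on loop-only matrices the eigenvector reflects loop geometry
more than checkerboard compartmentalization unless bins are coarse. The
CRE tree applies its rules uniformly even where they leave anchor-status
asymmetries (see above), and intragenic elements receive no state by
design.
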