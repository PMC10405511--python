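"""Anchor/basal classification of peaks and genes, loop categorization,
and SNP-in-loop overlap.

An *anchor* peak participates in at least one chromatin interaction of its
mark; a *basal* peak does not. Genes inherit anchor/basal status from the
peaks overlapping their association window. Loops are categorized by what
their two anchors overlap (promoter / intergenic / genic space) and by span.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .intervals import (
    MARK_GROUPS,
    Gene,
    GenomicInterval,
    Loop,
    Peak,
    gene_region,
    overlap_bp,
    promoter_of,
)

__all__ = [
    "AnchorStatus",
    "LoopCategory",
    "classify_anchor_basal_peaks",
    "classify_anchor_basal_genes",
    "categorize_loop",
    "categorize_loops",
    "snps_in_loops",
    "build_tree",
]

SPAN_CLASS_BOUNDARIES = (1_000_000, 10_000_000)


@dataclass(frozen=True)
class AnchorStatus:
    """Anchor/basal call for a peak or gene, with its supporting loops."""

    subject_id: str
    status: str  # "anchor" | "basal"
    supporting_loops: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.status == "anchor") != bool(self.supporting_loops):
            raise ValueError(
                "anchor status requires supporting loops (and basal forbids them)"
            )


@dataclass(frozen=True)
class LoopCategory:
    loop_id: str
    category: str  # PP | PI | II | other
    span_bp: Optional[int]
    span_class: str  # lt1Mb | 1to10Mb | gt10Mb | inter


def build_tree(intervals: Iterable[tuple[GenomicInterval, object]]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees mapping intervals to payloads."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv, payload in intervals:
        trees[iv.chrom].addi(iv.start, iv.end, payload)
    return dict(trees)


def _loop_ids(loops: Sequence[Loop]) -> list[str]:
    return [lp.loop_id or f"loop_{i}" for i, lp in enumerate(loops)]


def classify_anchor_basal_peaks(
    peaks: Sequence[Peak],
    loops: Sequence[Loop],
    same_mark_only: bool = True,
    min_overlap_bp: int = 1,
) -> list[AnchorStatus]:
    """Partition peaks into anchor and basal.

    A peak is an anchor iff it overlaps (>= ``min_overlap_bp``) any loop
    anchor, restricted to loops of the same mark when ``same_mark_only``.
    The partition is exhaustive and disjoint.
    """
    if same_mark_only and peaks and loops:
        if not ({p.mark for p in peaks} & {lp.mark for lp in loops}):
            raise ValueError("no shared marks between peaks and loops")
    ids = _loop_ids(loops)
    trees: dict[tuple, IntervalTree] = defaultdict(IntervalTree)
    for lid, lp in zip(ids, loops):
        for anchor in (lp.anchor_a, lp.anchor_b):
            key = (lp.mark if same_mark_only else None, anchor.chrom)
            trees[key].addi(anchor.start, anchor.end, lid)
    out = []
    for i, p in enumerate(peaks):
        key = (p.mark if same_mark_only else None, p.chrom)
        hits = sorted(
            {
                h.data
                for h in trees.get(key, IntervalTree()).overlap(p.interval.start, p.interval.end)
                if min(h.end, p.interval.end) - max(h.begin, p.interval.start) >= min_overlap_bp
            }
        )
        out.append(
            AnchorStatus(
                subject_id=p.name or f"peak_{i}",
                status="anchor" if hits else "basal",
                supporting_loops=tuple(hits),
            )
        )
    return out


def classify_anchor_basal_genes(
    genes: Sequence[Gene],
    peaks: Sequence[Peak],
    peak_statuses: Sequence[AnchorStatus],
    upstream: int = 1000,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[AnchorStatus]:
    """Anchor/basal status for genes from overlapping classified peaks.

    The association window is 1 kb upstream of the TSS through the TTS. A
    gene overlapped by any anchor peak is an anchor gene (anchor dominates);
    a gene overlapped only by basal peaks is basal; genes touched by no peak
    are excluded from the output.
    """
    peak_trees = build_tree(
        (p.interval, st) for p, st in zip(peaks, peak_statuses)
    )
    out = []
    for g in genes:
        window = gene_region(g, upstream=upstream, chrom_sizes=chrom_sizes)
        tree = peak_trees.get(g.chrom)
        if tree is None:
            continue
        hits = [h.data for h in tree.overlap(window.start, window.end)]
        if not hits:
            continue
        loops = sorted({lid for st in hits for lid in st.supporting_loops})
        status = "anchor" if any(st.status == "anchor" for st in hits) else "basal"
        out.append(
            AnchorStatus(
                subject_id=g.gene_id,
                status=status,
                supporting_loops=tuple(loops) if status == "anchor" else (),
            )
        )
    return out


class _AnchorLabeller:
    """Labels a loop anchor as promoter / intergenic / genic.

    Promoter space: 1 kb upstream to 0.5 kb downstream of each TSS.
    Intergenic space: complement of (1 kb upstream of TSS through TTS).
    Remaining overlap (gene body beyond the promoter) is genic. Promoter
    takes precedence when an anchor touches several spaces.
    """

    def __init__(
        self,
        genes: Sequence[Gene],
        upstream: int = 1000,
        downstream: int = 500,
        chrom_sizes: Optional[Mapping[str, int]] = None,
    ) -> None:
        self.promoters = build_tree(
            (promoter_of(g, upstream, downstream, chrom_sizes), g.gene_id) for g in genes
        )
        self.gene_regions = build_tree(
            (gene_region(g, upstream, chrom_sizes), g.gene_id) for g in genes
        )

    def label(self, anchor: GenomicInterval) -> str:
        ptree = self.promoters.get(anchor.chrom)
        if ptree is not None and ptree.overlap(anchor.start, anchor.end):
            return "promoter"
        gtree = self.gene_regions.get(anchor.chrom)
        hits = gtree.overlap(anchor.start, anchor.end) if gtree is not None else set()
        if not hits:
            return "intergenic"
        # merged coverage of gene regions over the anchor
        spans = sorted((max(h.begin, anchor.start), min(h.end, anchor.end)) for h in hits)
        merged_end = spans[0][0]
        total = 0
        for s, e in spans:
            s = max(s, merged_end)
            if e > s:
                total += e - s
                merged_end = e
        if total < anchor.length:
            return "intergenic"
        return "genic"


def categorize_loop(
    loop: Loop,
    labeller: _AnchorLabeller,
    loop_id: str = "loop",
) -> LoopCategory:
    """Categorize one loop by anchor labels and span.

    PP / PI / II from the promoter/intergenic labels of the two anchors;
    pairs involving a purely genic anchor map to "other". Span classes:
    < 1 Mb, 1-10 Mb (boundaries inclusive), > 10 Mb, or "inter".
    """
    if not loop.intrachromosomal:
        span, span_class = None, "inter"
    else:
        span = loop.span_bp
        if span < SPAN_CLASS_BOUNDARIES[0]:
            span_class = "lt1Mb"
        elif span <= SPAN_CLASS_BOUNDARIES[1]:
            span_class = "1to10Mb"
        else:
            span_class = "gt10Mb"
    la = labeller.label(loop.anchor_a)
    lb = labeller.label(loop.anchor_b)
    pair = frozenset((la, lb)) if la != lb else frozenset((la,))
    if "genic" in pair:
        category = "other"
    elif pair == {"promoter"}:
        category = "PP"
    elif pair == {"intergenic"}:
        category = "II"
    else:
        category = "PI"
    return LoopCategory(loop_id=loop_id, category=category, span_bp=span, span_class=span_class)


def categorize_loops(
    loops: Sequence[Loop],
    genes: Sequence[Gene],
    upstream: int = 1000,
    downstream: int = 500,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[LoopCategory]:
    labeller = _AnchorLabeller(genes, upstream, downstream, chrom_sizes)
    ids = _loop_ids(loops)
    return [categorize_loop(lp, labeller, lid) for lp, lid in zip(loops, ids)]


def snps_in_loops(
    snps: Sequence[GenomicInterval],
    loops_by_mark: Mapping[str, Sequence[Loop]],
    groups: Mapping[str, Sequence[str]] = MARK_GROUPS,
) -> dict[str, float]:
    """Fraction of SNPs lying inside any loop anchor, per mark group.

    Groups may overlap (a SNP can count in several); SNPs outside all
    anchors contribute to ``not_involved``. Membership means overlap with
    an anchor interval, not the intervening span.
    """
    if not snps:
        return {g: 0.0 for g in groups} | {"not_involved": 0.0}
    group_trees: dict[str, dict[str, IntervalTree]] = {}
    for group, marks in groups.items():
        anchors = [
            (anchor, None)
            for mark in marks
            for lp in loops_by_mark.get(mark, [])
            for anchor in (lp.anchor_a, lp.anchor_b)
        ]
        group_trees[group] = build_tree(anchors)
    counts = {g: 0 for g in groups}
    not_involved = 0
    for snp in snps:
        hit_any = False
        for group, trees in group_trees.items():
            tree = trees.get(snp.chrom)
            if tree is not None and tree.overlap(snp.start, snp.end):
                counts[group] += 1
                hit_any = True
        if not hit_any:
            not_involved += 1
    n = len(snps)
    result = {g: counts[g] / n for g in groups}
    result["not_involved"] = not_involved / n
    return result
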