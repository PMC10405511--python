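"""Classification of accessible regions (CREs) into proximal/distal
regulatory elements with chromatin states and target-gene links.

Genomic classes: a CRE is a PRE when >= 50% of its length lies in promoter
space (1 kb upstream to 0.5 kb downstream of a TSS), a DRE when >= 50% lies
in intergenic space (the complement of the 1 kb-upstream-of-TSS-through-TTS
windows), and intragenic when >= 50% lies in gene-body space; qualifying
classes resolve by the priority PRE > DRE > intragenic, and a CRE reaching
50% nowhere falls back to the maximal-overlap class (flagged).

Chromatin states: *poised* CREs sit with H3K27me3 and no active mark,
*poiAct* (bivalent) PREs with H3K27me3 and an active mark simultaneously,
everything else is *active*. Interaction status (anchor / basal) follows
the anchor/basal status of the relevant peak or linked gene.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .annotate import AnchorStatus
from .intervals import (
    ACTIVE_MARKS,
    ExpressionTable,
    Gene,
    GenomicInterval,
    Loop,
    Peak,
    gene_body,
    gene_region,
    overlap_bp,
    promoter_of,
)
from .network import GeneAssigner

__all__ = [
    "CREAnnotation",
    "GenomeSpaces",
    "classify_genomic",
    "classify_state_and_status",
    "link_targets",
    "annotate_cres",
    "build_expression_categories",
]


@dataclass
class CREAnnotation:
    cre_id: str
    interval: GenomicInterval
    genomic_class: str  # PRE | DRE | intragenic
    state: Optional[str] = None  # active | poised | poiAct (None for intragenic)
    interaction_status: Optional[str] = None  # anchor | basal
    nearest_gene: Optional[str] = None
    nearest_gene_distance: Optional[int] = None
    nearest_gene_status: Optional[str] = None
    connecting_genes: tuple[str, ...] = ()
    n_loops: int = 0
    class_below_threshold: bool = False  # 50% reached in no class (fallback used)


class _MergedSpace:
    """Merged, sorted interval union per chromosome with overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        raw: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for iv in intervals:
            raw[iv.chrom].append((iv.start, iv.end))
        self.merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in raw.items():
            ivs.sort()
            out: list[tuple[int, int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], e))
                else:
                    out.append((s, e))
            self.merged[chrom] = out

    def overlap_bp(self, iv: GenomicInterval) -> int:
        total = 0
        for s, e in self.merged.get(iv.chrom, []):
            if s >= iv.end:
                break
            if e > iv.start:
                total += min(e, iv.end) - max(s, iv.start)
        return total


class GenomeSpaces:
    """Promoter / gene-body / intergenic partition of the genome."""

    def __init__(
        self,
        genes: Sequence[Gene],
        upstream: int = 1000,
        downstream: int = 500,
        chrom_sizes: Optional[Mapping[str, int]] = None,
    ) -> None:
        self.promoters = _MergedSpace(
            promoter_of(g, upstream, downstream, chrom_sizes) for g in genes
        )
        bodies = [gene_body(g, downstream) for g in genes]
        self.bodies = _MergedSpace(b for b in bodies if b is not None)
        # intergenic = complement of the 1 kb upstream-of-TSS..TTS windows
        self.gene_windows = _MergedSpace(
            gene_region(g, upstream, chrom_sizes) for g in genes
        )

    def overlaps(self, iv: GenomicInterval) -> dict[str, int]:
        return {
            "PRE": self.promoters.overlap_bp(iv),
            "DRE": iv.length - self.gene_windows.overlap_bp(iv),
            "intragenic": self.bodies.overlap_bp(iv),
        }


_PRIORITY = ("PRE", "DRE", "intragenic")


def classify_genomic(
    cre: GenomicInterval,
    spaces: GenomeSpaces,
    min_fraction: float = 0.5,
) -> tuple[str, bool]:
    """Genomic class of one CRE; returns (class, below_threshold_flag)."""
    ov = spaces.overlaps(cre)
    need = min_fraction * cre.length
    qualifying = [c for c in _PRIORITY if ov[c] >= need]
    if qualifying:
        return qualifying[0], False
    best = max(ov.values())
    for c in _PRIORITY:  # tie on maximal overlap resolves by priority
        if ov[c] == best:
            return c, True
    raise AssertionError("unreachable")


def _edge_distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    if a.chrom != b.chrom:
        return None
    if overlap_bp(a, b) > 0:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def classify_state_and_status(
    cre: GenomicInterval,
    genomic_class: str,
    peaks: Sequence[Peak],
    peak_statuses: Sequence[AnchorStatus],
    gene_statuses: Mapping[str, str],
    nearest_gene: Optional[str],
    linked_genes: Sequence[str],
    near_bp: int = 500,
    active_marks: Sequence[str] = ACTIVE_MARKS,
) -> Optional[tuple[str, str]]:
    """Chromatin state and interaction status for a PRE or DRE.

    DRE branch: the nearest peaks within ``near_bp`` (edge-to-edge) decide.
    If they are H3K27me3-only, the DRE is poised, with the peak's
    anchor/basal status; otherwise the DRE is active, anchor iff its
    nearest protein-coding gene is an anchor gene.

    PRE branch: overlap with an H3K27me3 anchor peak only -> poised anchor;
    with an H3K27me3 anchor peak and an active-mark anchor peak
    simultaneously -> poiAct anchor; else if the linked (promoter-overlap)
    gene is basal -> basal, state from the overlapping peak marks; the
    remainder are active anchors.

    Intragenic CREs are carried through unannotated (returns None).
    """
    if genomic_class == "intragenic":
        return None
    active_set = set(active_marks)

    if genomic_class == "DRE":
        # peaks within near_bp, keeping only those at the minimal distance
        near: list[tuple[int, Peak, AnchorStatus]] = []
        for p, st in zip(peaks, peak_statuses):
            d = _edge_distance(cre, p.interval)
            if d is not None and d < near_bp:
                near.append((d, p, st))
        if near:
            dmin = min(d for d, _, _ in near)
            nearest_peaks = [(p, st) for d, p, st in near if d == dmin]
            marks = {p.mark for p, _ in nearest_peaks}
            if marks == {"H3K27me3"}:
                status = (
                    "anchor"
                    if any(st.status == "anchor" for _, st in nearest_peaks)
                    else "basal"
                )
                return ("poised", status)
        status = gene_statuses.get(nearest_gene, "basal") if nearest_gene else "basal"
        return ("active", status)

    # PRE branch
    overlapping = [
        (p, st) for p, st in zip(peaks, peak_statuses) if overlap_bp(cre, p.interval) > 0
    ]
    anchor_marks = {p.mark for p, st in overlapping if st.status == "anchor"}
    if "H3K27me3" in anchor_marks:
        if anchor_marks & active_set:
            return ("poiAct", "anchor")
        return ("poised", "anchor")
    linked_status = [gene_statuses.get(g) for g in linked_genes]
    if linked_status and all(s == "basal" for s in linked_status if s is not None) and any(
        s == "basal" for s in linked_status
    ):
        all_marks = {p.mark for p, _ in overlapping}
        if "H3K27me3" in all_marks:
            state = "poiAct" if all_marks & active_set else "poised"
        else:
            state = "active"
        return (state, "basal")
    return ("active", "anchor")


def link_targets(
    cre: GenomicInterval,
    loops: Sequence[Loop],
    genes: Sequence[Gene],
    assigner: GeneAssigner,
    mark_category: str = "active",
) -> tuple[Optional[str], Optional[int], tuple[str, ...], int]:
    """Nearest gene and long-range connecting genes of a CRE.

    The nearest gene minimizes |CRE midpoint - TSS| (ties break to the
    lexicographically first gene id). Connecting genes are the anchor genes
    at the far anchors of every loop whose near anchor overlaps the CRE
    (>= 1 bp), excluding the nearest gene. Returns
    (nearest_gene, distance, connecting_genes, n_loops).
    """
    mid = cre.midpoint
    best: Optional[tuple[float, str]] = None
    for g in genes:
        if g.chrom != cre.chrom:
            continue
        d = abs(mid - g.tss)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    nearest, distance = (best[1], int(best[0])) if best else (None, None)
    connecting: set[str] = set()
    n_loops = 0
    for lp in loops:
        hit_a = overlap_bp(cre, lp.anchor_a) > 0
        hit_b = overlap_bp(cre, lp.anchor_b) > 0
        if not (hit_a or hit_b):
            continue
        n_loops += 1
        far_anchors = []
        if hit_a:
            far_anchors.append(lp.anchor_b)
        if hit_b:
            far_anchors.append(lp.anchor_a)
        for far in far_anchors:
            connecting.update(assigner.assign(far, mark_category))
    connecting.discard(nearest)
    return nearest, distance, tuple(sorted(connecting)), n_loops


def annotate_cres(
    cres: Sequence[Peak],
    genes: Sequence[Gene],
    peaks: Sequence[Peak],
    peak_statuses: Sequence[AnchorStatus],
    gene_statuses: Mapping[str, str],
    loops: Sequence[Loop],
    expression: Optional[ExpressionTable] = None,
    near_bp: int = 500,
    overlap_frac: float = 0.5,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[CREAnnotation]:
    """Full annotation of accessible regions.

    ``peaks``/``peak_statuses`` are the mark peaks with their anchor/basal
    calls; ``gene_statuses`` maps gene_id -> "anchor"/"basal" for genes
    touched by classified peaks.
    """
    spaces = GenomeSpaces(genes, chrom_sizes=chrom_sizes)
    assigner = GeneAssigner(genes, expression, chrom_sizes=chrom_sizes)
    # promoter-overlap (linked) genes per chromosome for the PRE branch
    promoters = [
        (promoter_of(g, chrom_sizes=chrom_sizes), g.gene_id) for g in genes
    ]
    prom_by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = defaultdict(list)
    for iv, gid in promoters:
        prom_by_chrom[iv.chrom].append((iv, gid))
    peaks_by_chrom: dict[str, list[tuple[Peak, AnchorStatus]]] = defaultdict(list)
    for p, st in zip(peaks, peak_statuses):
        peaks_by_chrom[p.chrom].append((p, st))

    out = []
    for i, cre_peak in enumerate(cres):
        cre = cre_peak.interval
        cre_id = cre_peak.name or f"cre_{i}"
        genomic_class, below = classify_genomic(cre, spaces, overlap_frac)
        nearest, distance, connecting, n_loops = link_targets(
            cre, loops, genes, assigner
        )
        linked = [
            gid
            for iv, gid in prom_by_chrom.get(cre.chrom, [])
            if overlap_bp(cre, iv) > 0
        ]
        chrom_peaks = peaks_by_chrom.get(cre.chrom, [])
        result = classify_state_and_status(
            cre,
            genomic_class,
            [p for p, _ in chrom_peaks],
            [st for _, st in chrom_peaks],
            gene_statuses,
            nearest,
            linked,
            near_bp=near_bp,
        )
        state, status = result if result is not None else (None, None)
        out.append(
            CREAnnotation(
                cre_id=cre_id,
                interval=cre,
                genomic_class=genomic_class,
                state=state,
                interaction_status=status,
                nearest_gene=nearest,
                nearest_gene_distance=distance,
                nearest_gene_status=gene_statuses.get(nearest) if nearest else None,
                connecting_genes=connecting if status == "anchor" else (),
                n_loops=n_loops,
                class_below_threshold=below,
            )
        )
    return out


def build_expression_categories(
    annotations: Sequence[CREAnnotation],
    genes: Sequence[Gene],
) -> dict[str, list[str]]:
    """The comparison gene groups for CRE-effect analysis.

    Per genomic class and state: nearest genes of basal CREs, nearest genes
    of anchor CREs, long-range connecting genes (single- and multi-loop
    strata), plus no-CRE controls and PRE/DRE additivity strata. Groups are
    not exclusive; a gene may appear in several.
    """
    groups: dict[str, set[str]] = defaultdict(set)
    genes_with_cre: set[str] = set()
    nearest_by_class: dict[str, set[str]] = defaultdict(set)
    for ann in annotations:
        if ann.genomic_class == "intragenic" or ann.state is None:
            # intragenic CREs carry no state but still disqualify their
            # nearest gene from the no-CRE control
            if ann.nearest_gene:
                genes_with_cre.add(ann.nearest_gene)
            continue
        key = f"{ann.state}_{ann.genomic_class}"
        if ann.nearest_gene:
            genes_with_cre.add(ann.nearest_gene)
            nearest_by_class[ann.genomic_class].add(ann.nearest_gene)
            if ann.interaction_status == "basal":
                groups[f"{key}_nearest_basal"].add(ann.nearest_gene)
            else:
                groups[f"{key}_nearest_anchor"].add(ann.nearest_gene)
        for g in ann.connecting_genes:
            genes_with_cre.add(g)
            groups[f"{key}_connecting"].add(g)
            stratum = "single" if ann.n_loops == 1 else "multi"
            groups[f"{key}_connecting_{stratum}"].add(g)
    all_ids = {g.gene_id for g in genes}
    groups["no_cre_control"] = all_ids - genes_with_cre
    both = nearest_by_class["PRE"] & nearest_by_class["DRE"]
    groups["nearest_PRE_and_DRE"] = both
    groups["nearest_PRE_only"] = nearest_by_class["PRE"] - nearest_by_class["DRE"]
    groups["nearest_DRE_only"] = nearest_by_class["DRE"] - nearest_by_class["PRE"]
    return {k: sorted(v) for k, v in groups.items()}
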