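"""Core genomic record types and interval arithmetic.

All coordinates are 0-based half-open internally. Conversion from 1-based
closed conventions (GFF3) happens only inside the I/O layer
(:mod:`chiahub.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "Gene",
    "Peak",
    "Loop",
    "ExpressionTable",
    "promoter_of",
    "gene_region",
    "overlap_bp",
    "overlap_fraction",
    "ACTIVE_MARKS",
    "REPRESSIVE_MARK",
    "INACTIVE_MARK",
    "MARK_GROUPS",
]

#: Histone marks / factors treated as transcriptionally active.
ACTIVE_MARKS = ("H3K4me3", "RNAPII", "H3K4me1")
#: Polycomb-repressive mark.
REPRESSIVE_MARK = "H3K27me3"
#: Heterochromatic (inactive) mark.
INACTIVE_MARK = "H3K9me2"

#: Named mark groups used for SNP overlap and domain segmentation.
MARK_GROUPS = {
    "active": ACTIVE_MARKS,
    "repressive": (REPRESSIVE_MARK,),
    "inactive": (INACTIVE_MARK,),
}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_bp(self, other) > 0

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(a: GenomicInterval, b: GenomicInterval, of: str = "a") -> float:
    """Overlap as a fraction of the length of interval ``a`` (or ``b``)."""
    denom = a if of == "a" else b
    return overlap_bp(a, b) / denom.length


@dataclass(frozen=True)
class Gene:
    """A gene-level record (TSS-to-TTS extent, strand-aware)."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == "protein_coding"


def _clip(start: int, end: int, chrom_length: Optional[int]) -> GenomicInterval:
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return (start, end)


def promoter_of(
    gene: Gene,
    upstream: int = 1000,
    downstream: int = 500,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS.

    Default window is 1 kb upstream to 0.5 kb downstream of the TSS, the
    region used to define promoters throughout this package. The window is
    clipped at chromosome bounds, never dropped.
    """
    length = chrom_sizes.get(gene.chrom) if chrom_sizes else None
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss + 1 - downstream, gene.tss + 1 + upstream
    start, end = _clip(start, end, length)
    return GenomicInterval(gene.chrom, start, end)


def gene_region(
    gene: Gene,
    upstream: int = 1000,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> GenomicInterval:
    """The window from ``upstream`` bp of the TSS through the TTS.

    This is the association window used both for anchor-gene assignment and
    for carving the genome into promoter / genic / intergenic space (the
    intergenic space is the complement of this window over all genes).
    """
    length = chrom_sizes.get(gene.chrom) if chrom_sizes else None
    if gene.strand == "+":
        start, end = gene.interval.start - upstream, gene.interval.end
    else:
        start, end = gene.interval.start, gene.interval.end + upstream
    start, end = _clip(start, end, length)
    return GenomicInterval(gene.chrom, start, end)


def gene_body(gene: Gene, downstream_of_tss: int = 500) -> Optional[GenomicInterval]:
    """Gene body: 0.5 kb downstream of the TSS through the TTS.

    Returns ``None`` for genes shorter than ``downstream_of_tss``.
    """
    if gene.interval.length <= downstream_of_tss:
        return None
    if gene.strand == "+":
        return GenomicInterval(
            gene.chrom, gene.interval.start + downstream_of_tss, gene.interval.end
        )
    return GenomicInterval(
        gene.chrom, gene.interval.start, gene.interval.end - downstream_of_tss
    )


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq / ATAC-seq peak with a mark label.

    ``summit`` is an offset from ``interval.start`` (narrowPeak convention);
    anchor/basal status is computed downstream, never stored here.
    """

    interval: GenomicInterval
    mark: str
    intensity: float = 0.0
    summit: Optional[int] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"negative peak intensity: {self}")
        if self.summit is not None and not (0 <= self.summit < self.interval.length):
            raise ValueError(f"summit outside peak interval: {self}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class Loop:
    """A chromatin interaction: two anchor intervals with mark, PET count, FDR.

    Anchors are stored sorted (by chromosome name, then start) and must not
    overlap each other.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    mark: str
    pet_count: int = 1
    fdr: float = 0.0
    loop_id: Optional[str] = None

    def __post_init__(self) -> None:
        a, b = self.anchor_a, self.anchor_b
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            object.__setattr__(self, "anchor_a", b)
            object.__setattr__(self, "anchor_b", a)
        if self.pet_count < 1:
            raise ValueError(f"non-positive PET count: {self}")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR outside [0, 1]: {self}")
        if overlap_bp(self.anchor_a, self.anchor_b) > 0:
            raise ValueError(f"loop anchors overlap: {self}")

    @property
    def intrachromosomal(self) -> bool:
        return self.anchor_a.chrom == self.anchor_b.chrom

    @property
    def span_bp(self) -> Optional[int]:
        """Midpoint-to-midpoint distance; ``None`` for interchromosomal loops."""
        if not self.intrachromosomal:
            return None
        return int(round(abs(self.anchor_b.midpoint - self.anchor_a.midpoint)))


def dedupe_loops(loops: Iterable[Loop]) -> list[Loop]:
    """Deduplicate on (anchor_a, anchor_b, mark), keeping the max PET count."""
    best: dict[tuple, Loop] = {}
    for lp in loops:
        key = (lp.anchor_a, lp.anchor_b, lp.mark)
        prev = best.get(key)
        if prev is None or lp.pet_count > prev.pet_count:
            best[key] = lp
    return list(best.values())


class ExpressionTable:
    """Gene x tissue matrix of FPKM values.

    Thin wrapper over a :class:`pandas.DataFrame` (genes as index, tissues as
    columns) enforcing non-negative finite values and unique labels.
    """

    def __init__(self, frame) -> None:
        import numpy as np
        import pandas as pd

        frame = pd.DataFrame(frame)
        if frame.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression table")
        if frame.columns.has_duplicates:
            raise ValueError("duplicate tissue labels in expression table")
        values = frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("expression table contains non-finite values")
        if (values < 0).any():
            raise ValueError("expression table contains negative values")
        self.frame = frame.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.frame.columns)

    def fpkm(self, gene_id: str, tissue=None):
        """FPKM profile of a gene (or a single value when ``tissue`` given).

        Genes absent from the table report 0 (unexpressed).
        """
        if gene_id not in self.frame.index:
            return 0.0 if tissue is not None else None
        row = self.frame.loc[gene_id]
        return float(row[tissue]) if tissue is not None else row.to_numpy()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.frame.index

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionTable) and self.frame.equals(other.frame)
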