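"""Parsers and writers for the standard formats touched by the pipeline.

Formats: GFF3 (genes), BED3/BED6/narrowPeak (peaks, SNPs), BEDPE (loops),
TSV expression matrices, and two-column chromosome-size tables. GFF3 is
1-based closed on disk and converted to the internal 0-based half-open
convention here; BED-family formats are natively half-open.

Writers emit exactly the dialect the matching reader consumes, so
write -> read is the identity on all fields.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .intervals import (
    ExpressionTable,
    Gene,
    GenomicInterval,
    Loop,
    Peak,
    dedupe_loops,
)

__all__ = [
    "ParseError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_snps",
    "read_bedpe",
    "write_bedpe",
    "read_expression",
    "write_expression",
]


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


def _check_chrom(chrom: str, chrom_sizes: Optional[Mapping[str, int]], where: str) -> None:
    if chrom_sizes is not None and chrom not in chrom_sizes:
        raise ParseError(f"{where}: unknown chromosome {chrom!r}")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{i}: expected 2 columns, got {len(fields)}")
        name, length = fields
        sizes[name] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    Path(path).write_text("".join(f"{c}\t{l}\n" for c, l in sizes.items()))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(
    path,
    protein_coding_only: bool = True,
    feature_type: str = "gene",
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[Gene]:
    """Read gene features from a GFF3 file.

    1-based closed GFF3 coordinates are converted to 0-based half-open.
    Biotype is taken from a ``biotype`` attribute when present, defaulting
    to ``protein_coding``. Duplicate gene IDs are an error.
    """
    genes: list[Gene] = []
    seen: set[str] = set()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ParseError(f"{path}:{i}: expected 9 tab-separated columns")
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise ParseError(f"{path}:{i}: {exc}") from exc
        if feat.featuretype != feature_type:
            continue
        ids = feat.attributes.get("ID")
        if not ids:
            raise ParseError(f"{path}:{i}: {feature_type} feature without ID attribute")
        gene_id = ids[0]
        if gene_id in seen:
            raise ParseError(f"{path}:{i}: duplicate gene ID {gene_id!r}")
        seen.add(gene_id)
        biotype = feat.attributes.get("biotype", ["protein_coding"])[0]
        if protein_coding_only and biotype != "protein_coding":
            continue
        _check_chrom(feat.seqid, chrom_sizes, f"{path}:{i}")
        genes.append(
            Gene(
                gene_id=gene_id,
                interval=GenomicInterval(feat.seqid, feat.start - 1, feat.end),
                strand=feat.strand,
                biotype=biotype,
            )
        )
    return genes


def write_gff3(genes: Iterable[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.interval.start + 1}\t{g.interval.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def read_bed(
    path,
    mark: str,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[Peak]:
    """Read peaks from BED3/BED6 or 10-column narrowPeak.

    narrowPeak: column 7 (signalValue) becomes ``intensity`` and column 10
    the summit offset (-1 meaning absent). BED6: the score column becomes
    ``intensity``.
    """
    peaks: list[Peak] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}:{i}: expected >= 3 columns")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        if start < 0:
            raise ParseError(f"{path}:{i}: negative coordinate")
        if start >= end:
            raise ParseError(f"{path}:{i}: start >= end")
        _check_chrom(chrom, chrom_sizes, f"{path}:{i}")
        name = f[3] if len(f) > 3 and f[3] != "." else None
        intensity = 0.0
        summit = None
        if len(f) >= 10:  # narrowPeak
            intensity = float(f[6])
            summit = int(f[9]) if int(f[9]) >= 0 else None
        elif len(f) >= 5:
            intensity = float(f[4])
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end),
                mark=mark,
                intensity=intensity,
                summit=summit,
                name=name,
            )
        )
    return peaks


def write_bed(peaks: Iterable[Peak], path, dialect: str = "narrowPeak") -> None:
    """Write peaks as narrowPeak (default), BED6 or BED3."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i}"
            iv = p.interval
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{p.intensity:g}\t.\n")
            elif dialect == "narrowPeak":
                summit = p.summit if p.summit is not None else -1
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\t"
                    f"{p.intensity:g}\t-1\t-1\t{summit}\n"
                )
            else:
                raise ValueError(f"unknown BED dialect {dialect!r}")


def read_snps(path, chrom_sizes: Optional[Mapping[str, int]] = None) -> list[GenomicInterval]:
    """Read SNP positions from BED; returns 1 bp (or wider) intervals."""
    return [p.interval for p in read_bed(path, mark="SNP", chrom_sizes=chrom_sizes)]


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def read_bedpe(
    path,
    mark: str,
    fdr_max: Optional[float] = 0.05,
    pet_count_col: int = 7,
    fdr_col: int = 10,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    dedupe: bool = True,
) -> list[Loop]:
    """Read loops from BEDPE.

    Columns 1-6 are the two anchors; by default column 8 (0-based index 7)
    carries the PET count and column 11 (index 10) the FDR, matching this
    package's writer. Loops with ``fdr >= fdr_max`` are excluded when
    ``fdr_max`` is not None. Anchors are normalized to sorted order and
    duplicates on (anchor_a, anchor_b, mark) collapse to the max PET count.
    """
    loops: list[Loop] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ParseError(f"{path}:{i}: expected >= 6 columns")
        try:
            c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
        if min(s1, s2) < 0:
            raise ParseError(f"{path}:{i}: negative coordinate")
        if s1 >= e1 or s2 >= e2:
            raise ParseError(f"{path}:{i}: start >= end")
        _check_chrom(c1, chrom_sizes, f"{path}:{i}")
        _check_chrom(c2, chrom_sizes, f"{path}:{i}")
        name = f[6] if len(f) > 6 and f[6] != "." else None
        pet = int(f[pet_count_col]) if len(f) > pet_count_col else 1
        fdr = float(f[fdr_col]) if len(f) > fdr_col else 0.0
        if fdr_max is not None and fdr >= fdr_max:
            continue
        loops.append(
            Loop(
                anchor_a=GenomicInterval(c1, s1, e1),
                anchor_b=GenomicInterval(c2, s2, e2),
                mark=mark,
                pet_count=pet,
                fdr=fdr,
                loop_id=name,
            )
        )
    return dedupe_loops(loops) if dedupe else loops


def write_bedpe(loops: Iterable[Loop], path) -> None:
    """Write loops as BEDPE with name, pet_count, strands and fdr columns."""
    with open(path, "w") as fh:
        for i, lp in enumerate(loops):
            a, b = lp.anchor_a, lp.anchor_b
            name = lp.loop_id or f"loop_{i}"
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{name}\t{lp.pet_count}\t.\t.\t{lp.fdr!r}\n"
            )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionTable:
    """Read a TSV expression matrix with header ``gene_id<TAB>tissue...``."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ExpressionTable(frame)


def write_expression(table: ExpressionTable, path) -> None:
    frame = table.frame.copy()
    frame.index.name = "gene_id"
    # no float_format: pandas emits shortest-repr floats, so values round-trip
    frame.to_csv(path, sep="\t")
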