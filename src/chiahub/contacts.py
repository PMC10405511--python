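"""Contact-map architecture: binning, iterative-correction balancing,
A/B compartments, aggregate chromosome analysis, and interacting-domain
segmentation.

The matrices here are coarse, per-chromosome, symmetric bin x bin count
matrices built from loop anchor midpoints weighted by PET counts. Balancing
follows the iterative-correction scheme (divide rows and columns by their
marginals until the marginals equalize); compartments come from the sign of
the leading eigenvector of the Pearson correlation matrix of the
observed/expected map, oriented by a per-bin track (gene density by
default) so that the A side is the active/gene-rich side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .intervals import ACTIVE_MARKS, Gene, GenomicInterval, Loop

__all__ = [
    "ContactMatrix",
    "CompartmentCall",
    "DomainSegment",
    "bin_contacts",
    "ice_balance",
    "observed_expected",
    "call_compartments",
    "gene_density_track",
    "aggregate_chromosome_analysis",
    "segment_domains",
    "DOMAIN_GROUPS",
]

DOMAIN_GROUPS = {
    "AID": ACTIVE_MARKS,
    "RID": ("H3K27me3",),
    "HID": ("H3K9me2",),
}


@dataclass
class ContactMatrix:
    """A per-chromosome binned symmetric contact matrix."""

    chrom: str
    resolution: int
    matrix: np.ndarray
    bin_mask: np.ndarray  # True = retained

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.bin_mask = np.asarray(self.bin_mask, dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def retained(self) -> np.ndarray:
        return np.flatnonzero(self.bin_mask)

    def to_tsv(self, path) -> None:
        """Dense TSV plus a JSON sidecar (chrom, resolution, mask)."""
        np.savetxt(path, self.matrix, delimiter="\t", fmt="%.10g")
        sidecar = Path(str(path) + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "chrom": self.chrom,
                    "resolution": self.resolution,
                    "bin_mask": self.bin_mask.astype(int).tolist(),
                }
            )
        )

    @classmethod
    def from_tsv(cls, path) -> "ContactMatrix":
        meta = json.loads(Path(str(path) + ".json").read_text())
        matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
        return cls(
            chrom=meta["chrom"],
            resolution=meta["resolution"],
            matrix=matrix,
            bin_mask=np.array(meta["bin_mask"], dtype=bool),
        )


@dataclass
class CompartmentCall:
    chrom: str
    resolution: int
    eigenvector: np.ndarray  # NaN for masked bins
    labels: np.ndarray  # "A" | "B" | "masked"


@dataclass(frozen=True)
class DomainSegment:
    interval: GenomicInterval
    label: str  # AID | RID | HID | MID | gap


def bin_contacts(
    loops: Sequence[Loop],
    chrom_sizes: Mapping[str, int],
    resolution: int,
) -> dict[str, ContactMatrix]:
    """Bin intrachromosomal loops into per-chromosome contact matrices.

    Each loop adds its PET count to the symmetric cell pair indexed by its
    anchor-midpoint bins (once to the diagonal when both anchors fall in
    the same bin). Bins with zero marginal are masked.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    mats = {
        chrom: np.zeros((max(1, -(-length // resolution)),) * 2)
        for chrom, length in chrom_sizes.items()
    }
    for lp in loops:
        if not lp.intrachromosomal:
            continue
        m = mats[lp.anchor_a.chrom]
        i = min(int(lp.anchor_a.midpoint // resolution), m.shape[0] - 1)
        j = min(int(lp.anchor_b.midpoint // resolution), m.shape[0] - 1)
        m[i, j] += lp.pet_count
        if i != j:
            m[j, i] += lp.pet_count
    out = {}
    for chrom, m in mats.items():
        mask = m.sum(axis=1) > 0
        out[chrom] = ContactMatrix(chrom=chrom, resolution=resolution, matrix=m, bin_mask=mask)
    return out


def ice_balance(
    cm: ContactMatrix,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[ContactMatrix, np.ndarray, bool]:
    """Iterative-correction balancing.

    Rows/columns of retained bins are repeatedly divided by their marginals
    (renormalized to mean 1 each round) until the coefficient of variation
    of the retained-bin marginals drops below ``tol``. Returns the balanced
    matrix, the bias vector (``raw = bias_i * bias_j * balanced``; NaN for
    masked bins) and a convergence flag.
    """
    mask = cm.bin_mask.copy()
    if not mask.any():
        raise ValueError("all bins are masked; nothing to balance")
    w = cm.matrix.copy()
    w[~mask, :] = 0.0
    w[:, ~mask] = 0.0
    bias = np.ones(cm.n_bins)
    converged = False
    for _ in range(max_iter):
        marg = w.sum(axis=1)
        retained = marg[mask]
        cv = retained.std() / retained.mean()
        if cv < tol:
            converged = True
            break
        s = np.ones_like(marg)
        s[mask] = marg[mask] / retained.mean()
        w = w / np.outer(s, s)
        bias *= s
    if not converged:
        marg = w.sum(axis=1)[mask]
        if marg.std() / marg.mean() >= tol:
            warnings.warn("ICE balancing did not converge", RuntimeWarning)
        else:
            converged = True
    bias_out = np.where(mask, bias, np.nan)
    balanced = ContactMatrix(cm.chrom, cm.resolution, w, mask)
    return balanced, bias_out, converged


def observed_expected(cm: ContactMatrix) -> np.ndarray:
    """Observed/expected transform over retained bins.

    The expected value at distance d is the mean contact over all retained
    bin pairs at that exact bin distance (no smoothing).
    """
    idx = cm.retained()
    sub = cm.matrix[np.ix_(idx, idx)]
    n = len(idx)
    dist = np.abs(idx[:, None] - idx[None, :])
    oe = np.zeros_like(sub)
    for d in np.unique(dist):
        sel = dist == d
        mean = sub[sel].mean()
        oe[sel] = sub[sel] / mean if mean > 0 else 0.0
    return oe


def gene_density_track(
    genes: Sequence[Gene], chrom: str, n_bins: int, resolution: int
) -> np.ndarray:
    """Per-bin count of gene midpoints; the default compartment-orientation
    track (the A side is the gene-rich side)."""
    track = np.zeros(n_bins)
    for g in genes:
        if g.chrom == chrom:
            b = min(int(g.interval.midpoint // resolution), n_bins - 1)
            track[b] += 1
    return track


def call_compartments(
    cm: ContactMatrix,
    orientation_track: np.ndarray,
    min_bins: int = 10,
) -> CompartmentCall:
    """A/B compartments from the first eigenvector of the correlation matrix.

    Pipeline: observed/expected over retained bins -> Pearson correlation
    of O/E rows -> leading eigenvector. The eigenvector sign is arbitrary,
    so it is oriented such that positive-value bins have the higher mean
    ``orientation_track``; positive -> A, negative -> B.
    """
    idx = cm.retained()
    if len(idx) < min_bins:
        raise ValueError(
            f"only {len(idx)} retained bins; need >= {min_bins} for a stable eigenvector"
        )
    orientation_track = np.asarray(orientation_track, dtype=float)
    if orientation_track.shape[0] != cm.n_bins:
        raise ValueError("orientation track length must equal the number of bins")
    oe = observed_expected(cm)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr)
    eigvals, eigvecs = np.linalg.eigh(corr)
    ev = eigvecs[:, -1]  # leading eigenvector
    pos, neg = ev > 0, ev < 0
    track_sub = orientation_track[idx]
    mean_pos = track_sub[pos].mean() if pos.any() else -np.inf
    mean_neg = track_sub[neg].mean() if neg.any() else -np.inf
    if mean_neg > mean_pos:
        ev = -ev
    full_ev = np.full(cm.n_bins, np.nan)
    full_ev[idx] = ev
    labels = np.full(cm.n_bins, "masked", dtype=object)
    labels[idx] = np.where(ev >= 0, "A", "B")
    return CompartmentCall(cm.chrom, cm.resolution, full_ev, labels)


def aggregate_chromosome_analysis(
    matrices: Iterable[ContactMatrix], grid: int = 100
) -> np.ndarray:
    """Rescale each chromosome's matrix onto a ``grid x grid`` lattice by
    block-averaging, then sum across chromosomes."""
    if grid < 2:
        raise ValueError("grid must be >= 2")
    matrices = list(matrices)
    if not matrices:
        raise ValueError("at least one matrix required")
    out = np.zeros((grid, grid))
    for cm in matrices:
        n = cm.n_bins
        assign = (np.arange(n) * grid) // n  # partition of bins onto grid rows
        rescaled = np.zeros((grid, grid))
        counts = np.zeros((grid, grid))
        np.add.at(rescaled, (assign[:, None], assign[None, :]), cm.matrix)
        np.add.at(counts, (assign[:, None], assign[None, :]), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rescaled = np.where(counts > 0, rescaled / counts, 0.0)
        out += rescaled
    return out


def _group_coverage(
    loops: Sequence[Loop],
    chrom: str,
    n_bins: int,
    bin_size: int,
    gap_tolerance_bins: int,
) -> np.ndarray:
    covered = np.zeros(n_bins, dtype=bool)
    for lp in loops:
        for anchor in (lp.anchor_a, lp.anchor_b):
            if anchor.chrom != chrom:
                continue
            b0 = anchor.start // bin_size
            b1 = min((anchor.end - 1) // bin_size, n_bins - 1)
            covered[b0 : b1 + 1] = True
    if gap_tolerance_bins > 0 and covered.any():
        idx = np.flatnonzero(covered)
        for a, b in zip(idx[:-1], idx[1:]):
            if 1 < b - a <= gap_tolerance_bins + 1:
                covered[a:b] = True
    return covered


def segment_domains(
    loops_by_mark: Mapping[str, Sequence[Loop]],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 10_000,
    gap_tolerance_bins: int = 1,
    groups: Mapping[str, Sequence[str]] = DOMAIN_GROUPS,
) -> tuple[list[DomainSegment], "pd.DataFrame"]:
    """Segment the genome into interacting domains.

    Per domain group (AID: active marks; RID: H3K27me3; HID: H3K9me2), bins
    carrying at least one loop anchor are marked covered; runs of covered
    bins separated by <= ``gap_tolerance_bins`` empty bins merge. Bins
    covered by exactly one group take its label, bins covered by two or
    more become MID, uncovered bins are gap. Segments tile each chromosome.
    Returns the segment list and a per-label coverage summary (bp and %).
    """
    import pandas as pd

    segments: list[DomainSegment] = []
    coverage: dict[str, int] = {label: 0 for label in list(groups) + ["MID", "gap"]}
    total_bp = 0
    for chrom, length in chrom_sizes.items():
        n_bins = max(1, -(-length // bin_size))
        total_bp += length
        per_group = {}
        for label, marks in groups.items():
            group_loops = [lp for m in marks for lp in loops_by_mark.get(m, [])]
            per_group[label] = _group_coverage(
                group_loops, chrom, n_bins, bin_size, gap_tolerance_bins
            )
        stack = np.stack([per_group[label] for label in groups])
        n_groups = stack.sum(axis=0)
        labels = np.full(n_bins, "gap", dtype=object)
        for gi, label in enumerate(groups):
            labels[(n_groups == 1) & stack[gi]] = label
        labels[n_groups >= 2] = "MID"
        # run-length encode into segments
        start_bin = 0
        for b in range(1, n_bins + 1):
            if b == n_bins or labels[b] != labels[start_bin]:
                seg_start = start_bin * bin_size
                seg_end = min(b * bin_size, length)
                segments.append(
                    DomainSegment(
                        GenomicInterval(chrom, seg_start, seg_end), str(labels[start_bin])
                    )
                )
                coverage[str(labels[start_bin])] += seg_end - seg_start
                start_bin = b
    summary = pd.DataFrame(
        {
            "label": list(coverage),
            "bp": [coverage[k] for k in coverage],
            "percent": [100.0 * coverage[k] / total_bp for k in coverage],
        }
    )
    return segments, summary
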