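"""Synthetic datasets with planted structure for every downstream stage.

The generator emulates the kind of dataset this package analyzes: a small
multi-chromosome genome with a central heterochromatic (centromeric) block;
active-mark peaks and loops on the chromosome arms, overwhelmingly
promoter-promoter; H3K27me3 loops mixing promoter and intergenic anchors;
H3K9me2 loops confined to the pericentromere with a log-normal span law
(median 105 kb by default); elevated expression and co-expression of
anchor-gene pairs; TF targets clustered into chromatin hubs; accessible
regions planted with known PRE/DRE class, chromatin state and interaction
status; trait SNPs planted inside mark-group-exclusive loop anchors; and a
second condition in which planted fractions of hubs disassemble (EDH/PDH)
or grow (FH), with separated genes down-regulated.

Everything is deterministic under ``SimConfig.seed``: one global seed fans
out to per-component seeds by fixed offsets, so identical configs produce
byte-identical output files. Truth tables are first-class outputs so tests
never re-derive ground truth from the generator's internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    ACTIVE_MARKS,
    ExpressionTable,
    Gene,
    GenomicInterval,
    Loop,
    Peak,
    promoter_of,
)
from . import io as chio

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "ConditionPair",
    "generate_genome",
    "generate_peaks_and_loops",
    "generate_expression",
    "generate_condition_pair",
    "generate_dataset",
    "write_dataset",
]

# fixed sub-seed offsets (component reproducibility when configs change)
_SEED_GENOME = 1
_SEED_LOOPS = 2
_SEED_EXPR = 3
_SEED_COND = 4


def _default_loop_counts() -> dict[str, int]:
    return {"H3K4me3": 250, "RNAPII": 125, "H3K4me1": 125, "H3K27me3": 200, "H3K9me2": 200}


def _default_category_mix() -> dict[str, dict[str, float]]:
    active = {"PP": 0.96, "PI": 0.03, "II": 0.01}
    return {
        "H3K4me3": dict(active),
        "RNAPII": dict(active),
        "H3K4me1": dict(active),
        "H3K27me3": {"PP": 0.40, "PI": 0.30, "II": 0.30},
        "H3K9me2": {"II": 1.0},
    }


def _default_span_laws() -> dict[str, tuple[str, float, float]]:
    # (law, median bp, log-sd); spans on the arms ~tens of kb, pericentromeric
    # heterochromatin spans with median 105 kb
    return {
        "H3K4me3": ("lognormal", 30_000.0, 1.0),
        "RNAPII": ("lognormal", 30_000.0, 1.0),
        "H3K4me1": ("lognormal", 30_000.0, 1.0),
        "H3K27me3": ("lognormal", 50_000.0, 1.0),
        "H3K9me2": ("lognormal", 105_000.0, 0.45),
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator (see module docstring)."""

    n_chroms: int = 2
    chrom_length: int = 20_000_000
    centromere_span: tuple[float, float] = (0.4, 0.6)
    n_genes: int = 2000
    n_tissues: int = 43
    gene_length: tuple[int, int] = (1000, 5000)
    loop_counts: dict[str, int] = field(default_factory=_default_loop_counts)
    category_mix: dict[str, dict[str, float]] = field(default_factory=_default_category_mix)
    span_distributions: dict[str, tuple[str, float, float]] = field(
        default_factory=_default_span_laws
    )
    anchor_expression_boost: float = 2.0
    planted_pair_pcc: float = 0.5
    n_coexpr_pairs: int = 200
    expr_log_mean: float = 1.0
    expr_gene_log_sd: float = 1.0
    expr_tissue_log_sd: float = 1.0
    cre_connected_boost: float = 1.5
    tf_configs: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("MYC2", 300, 0.7)]
    )
    n_hubs: int = 50
    hub_degree_range: tuple[int, int] = (8, 12)
    hub_disassembly_fractions: tuple[float, float, float] = (0.10, 0.20, 0.05)
    separated_downregulation: float = 0.4
    condition_noise_log_sd: float = 0.1
    n_cres: int = 600
    cre_class_fractions: dict[str, float] = field(
        default_factory=lambda: {"PRE": 0.61, "DRE": 0.29, "intragenic": 0.10}
    )
    cre_state_fractions: dict[str, float] = field(
        default_factory=lambda: {"active": 0.80, "poised": 0.13, "poiAct": 0.07}
    )
    cre_anchor_fraction: float = 0.7
    n_snps: int = 200
    snp_fractions: dict[str, float] = field(
        default_factory=lambda: {"active": 0.23, "repressive": 0.11, "inactive": 0.11}
    )
    detection_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "n_tissues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        c0, c1 = self.centromere_span
        if not (0.0 < c0 < c1 < 1.0):
            raise ValueError("centromere_span must be a fractional interval in (0, 1)")
        f = self.hub_disassembly_fractions
        if any(not (0.0 <= x <= 1.0) for x in f) or sum(f) > 1.0:
            raise ValueError("hub disassembly fractions must lie in [0,1] and sum <= 1")
        for mark, mix in self.category_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"category mix for {mark} does not sum to 1")
        if sum(self.snp_fractions.values()) > 1.0:
            raise ValueError("SNP group fractions sum > 1")

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, offset])


@dataclass
class SimTruth:
    """Planted ground truth, one table per aspect.

    gene_roles: gene_id, role, active_anchor, h3k27me3_anchor, boosted,
    cre_boosted. loops: loop_id, mark, category, span_bp, origin.
    pairs: co-expression-planted gene pairs. hubs: hub_id, node_gene,
    connecting_genes (comma-joined). tf_targets / cres / snps likewise.
    """

    gene_roles: pd.DataFrame
    loops: pd.DataFrame
    pairs: pd.DataFrame
    hubs: pd.DataFrame
    tf_targets: pd.DataFrame
    cres: pd.DataFrame
    snps: pd.DataFrame

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        for name in ("gene_roles", "loops", "pairs", "hubs", "tf_targets", "cres", "snps"):
            getattr(self, name).to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, indir) -> "SimTruth":
        indir = Path(indir)
        frames = {
            name: pd.read_csv(indir / f"truth_{name}.tsv", sep="\t")
            for name in ("gene_roles", "loops", "pairs", "hubs", "tf_targets", "cres", "snps")
        }
        return cls(**frames)

    def hub_connecting(self, hub_id: str) -> list[str]:
        row = self.hubs.loc[self.hubs.hub_id == hub_id].iloc[0]
        return row.connecting_genes.split(",")


@dataclass
class ConditionPair:
    loops_cond1: list[Loop]
    loops_cond2: list[Loop]
    hub_truth: pd.DataFrame  # hub_id, node_gene, label, n_c, n_m, separated, aggregated
    expression_conditions: pd.DataFrame  # gene x {cond1, cond2} FPKM


@dataclass
class SimDataset:
    config: SimConfig
    chrom_sizes: dict[str, int]
    genes: list[Gene]
    peaks: dict[str, list[Peak]]
    loops: dict[str, list[Loop]]
    truth: SimTruth
    expression: ExpressionTable
    condition_pair: ConditionPair


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

_GENE_ZONE_FRAC = 0.6  # leading fraction of each slot that may hold the gene
_GENE_MARGIN = 1500  # clearance from slot start (room for the promoter)
_ZONE_CLEARANCE = 2000  # gap between gene zone / slot end and intergenic zone
_ANCHOR_WIDTH = 800  # width of intergenic loop anchors
_CRE_WIDTH = 400


def _layout(cfg: SimConfig) -> dict:
    """Deterministic slot geometry shared by all generator stages."""
    c0 = int(cfg.chrom_length * cfg.centromere_span[0])
    c1 = int(cfg.chrom_length * cfg.centromere_span[1])
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    arms = [(0, c0), (c1, cfg.chrom_length)]
    slots: dict[str, list[tuple[int, int]]] = {}
    for chrom, n in zip(chroms, per_chrom):
        arm_lens = [a1 - a0 for a0, a1 in arms]
        n_left = round(n * arm_lens[0] / sum(arm_lens))
        counts = [n_left, n - n_left]
        chrom_slots = []
        for (a0, a1), k in zip(arms, counts):
            if k == 0:
                continue
            size = (a1 - a0) // k
            min_size = int(
                (_GENE_MARGIN + cfg.gene_length[1]) / _GENE_ZONE_FRAC
            )
            if size < min_size:
                raise ValueError(
                    f"{n} genes cannot fit on the arms of {chrom} "
                    f"(slot {size} bp < minimum {min_size} bp)"
                )
            chrom_slots.extend((a0 + i * size, a0 + (i + 1) * size) for i in range(k))
        slots[chrom] = chrom_slots
    return {
        "chroms": chroms,
        "centromere": (c0, c1),
        "slots": slots,
        "chrom_sizes": {c: cfg.chrom_length for c in chroms},
    }


def _zone_of_slot(slot: tuple[int, int]) -> Optional[tuple[int, int]]:
    s0, s1 = slot
    z0 = s0 + int(_GENE_ZONE_FRAC * (s1 - s0)) + _ZONE_CLEARANCE
    z1 = s1 - _ZONE_CLEARANCE
    if z1 - z0 < _ANCHOR_WIDTH + _CRE_WIDTH + 400:
        return None
    return (z0, z1)


def generate_genome(cfg: SimConfig) -> tuple[dict[str, int], list[Gene]]:
    """Place non-overlapping genes on the chromosome arms.

    One gene per slot, offset randomly inside the slot's gene zone; no gene
    intersects the centromeric block. Infeasible densities raise.
    """
    lay = _layout(cfg)
    rng = cfg.rng(_SEED_GENOME)
    genes: list[Gene] = []
    idx = 0
    for chrom in lay["chroms"]:
        for s0, s1 in lay["slots"][chrom]:
            glen = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
            zone_end = s0 + int(_GENE_ZONE_FRAC * (s1 - s0))
            start = int(rng.integers(s0 + _GENE_MARGIN, zone_end - glen + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(
                    gene_id=f"g{idx:05d}",
                    interval=GenomicInterval(chrom, start, start + glen),
                    strand=strand,
                )
            )
            idx += 1
    return lay["chrom_sizes"], genes


# ---------------------------------------------------------------------------
# peaks, loops, CREs, SNPs
# ---------------------------------------------------------------------------


def _sample_span(rng: np.random.Generator, law: tuple[str, float, float]) -> int:
    kind, median, sigma = law
    if kind != "lognormal":
        raise ValueError(f"unsupported span law {kind!r}")
    return max(3000, int(rng.lognormal(math.log(median), sigma)))


class _RoleBook:
    """Tracks gene roles and per-gene loop usage during generation."""

    def __init__(self, genes: Sequence[Gene]) -> None:
        self.genes = {g.gene_id: g for g in genes}
        self.role: dict[str, str] = {}
        self.usage: dict[str, int] = {}
        self.by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in self.by_chrom:
            self.by_chrom[chrom].sort(key=lambda g: g.interval.start)

    def assign(self, gene_id: str, role: str) -> None:
        self.role[gene_id] = role

    def of_role(self, role: str, chrom: Optional[str] = None) -> list[Gene]:
        out = [
            g
            for gid, g in self.genes.items()
            if self.role.get(gid) == role and (chrom is None or g.chrom == chrom)
        ]
        return sorted(out, key=lambda g: (g.chrom, g.interval.start))


def generate_peaks_and_loops(
    cfg: SimConfig,
    chrom_sizes: Mapping[str, int],
    genes: Sequence[Gene],
) -> tuple[dict[str, list[Peak]], dict[str, list[Loop]], SimTruth]:
    """Plant peaks, loops, hubs, TF targets, CREs and SNPs.

    Loops come in three origins: ``hub`` (node-gene centred, H3K4me3),
    ``background`` (honouring the per-mark category mix exactly, by largest
    remainder), and ``support`` (extra loops that realize planted bivalent
    genes and DRE targets). Truth tables record every planted feature.
    """
    lay = _layout(cfg)
    rng = cfg.rng(_SEED_LOOPS)
    book = _RoleBook(genes)
    cen0, cen1 = lay["centromere"]

    # ---- gene role allocation -------------------------------------------
    n_pre = round(cfg.n_cres * cfg.cre_class_fractions.get("PRE", 0.0))
    n_poiact = round(n_pre * cfg.cre_state_fractions.get("poiAct", 0.0))
    n_poised_pre = round(n_pre * cfg.cre_state_fractions.get("poised", 0.0))
    n_poised_pre_basal = round(n_poised_pre * (1 - cfg.cre_anchor_fraction))
    n_pp_k27 = round(
        cfg.loop_counts.get("H3K27me3", 0)
        * cfg.category_mix.get("H3K27me3", {}).get("PP", 0.0)
    )
    quota = {
        "bivalent": n_poiact,
        "polycomb": max(2 * n_pp_k27, n_poised_pre - n_poised_pre_basal),
        "polycomb_basal": n_poised_pre_basal + 6,
    }

    hub_degrees = rng.integers(
        cfg.hub_degree_range[0], cfg.hub_degree_range[1] + 1, size=cfg.n_hubs
    )
    cursors = {c: 0 for c in lay["chroms"]}
    hub_rows = []
    for h in range(cfg.n_hubs):
        chrom = lay["chroms"][h % len(lay["chroms"])]
        pool = book.by_chrom[chrom]
        need = int(hub_degrees[h]) + 1
        if cursors[chrom] + need > len(pool):
            raise ValueError("not enough genes to host the requested hubs")
        block = pool[cursors[chrom] : cursors[chrom] + need]
        cursors[chrom] += need
        node, conns = block[0], block[1:]
        book.assign(node.gene_id, "hub_node")
        for g in conns:
            book.assign(g.gene_id, "hub_conn")
        hub_rows.append(
            {
                "hub_id": f"truehub_{h}",
                "node_gene": node.gene_id,
                "connecting_genes": ",".join(g.gene_id for g in conns),
                "chrom": chrom,
            }
        )

    unassigned = [
        g for g in genes if g.gene_id not in book.role
    ]
    perm = rng.permutation(len(unassigned))
    shuffled = [unassigned[i] for i in perm]
    pos = 0
    for role, count in quota.items():
        for g in shuffled[pos : pos + count]:
            book.assign(g.gene_id, role)
        pos += count
    remaining = shuffled[pos:]
    n_active_pool = int(0.45 * len(remaining))
    for g in remaining[:n_active_pool]:
        book.assign(g.gene_id, "active_pool")
    for g in remaining[n_active_pool:]:
        book.assign(g.gene_id, "basal")

    # ---- intergenic zones ------------------------------------------------
    zones: dict[str, list[tuple[int, int]]] = {}
    zone_used: dict[str, list[bool]] = {}
    for chrom in lay["chroms"]:
        zs = [z for s in lay["slots"][chrom] if (z := _zone_of_slot(s)) is not None]
        zones[chrom] = zs
        zone_used[chrom] = [False] * len(zs)

    def take_zone(chrom: str, near: Optional[int] = None) -> Optional[tuple[int, int]]:
        free = [i for i, used in enumerate(zone_used[chrom]) if not used]
        if not free:
            return None
        if near is None:
            i = free[int(rng.integers(len(free)))]
        else:
            i = min(free, key=lambda k: abs((zones[chrom][k][0] + zones[chrom][k][1]) / 2 - near))
        zone_used[chrom][i] = True
        return zones[chrom][i]

    # ---- loops -----------------------------------------------------------
    loops: dict[str, list[Loop]] = {m: [] for m in cfg.loop_counts}
    loop_rows = []
    loop_counter = [0]
    seen_loop_keys: set[tuple] = set()

    def add_loop(mark: str, a: GenomicInterval, b: GenomicInterval, category: str, origin: str):
        key = (min(a, b), max(a, b), mark)
        if key in seen_loop_keys:
            return None  # duplicates would collapse in the deduping reader
        seen_loop_keys.add(key)
        lid = f"{mark}_{loop_counter[0]}"
        loop_counter[0] += 1
        lp = Loop(
            anchor_a=a,
            anchor_b=b,
            mark=mark,
            pet_count=int(rng.integers(2, 21)),
            fdr=float(rng.uniform(0.0, 0.049)),
            loop_id=lid,
        )
        loops.setdefault(mark, []).append(lp)
        loop_rows.append(
            {
                "loop_id": lid,
                "mark": mark,
                "category": category,
                "span_bp": lp.span_bp,
                "origin": origin,
            }
        )
        return lp

    prom = {g.gene_id: promoter_of(g, chrom_sizes=chrom_sizes) for g in genes}

    # hub loops (H3K4me3)
    for row in hub_rows:
        for conn in row["connecting_genes"].split(","):
            add_loop("H3K4me3", prom[row["node_gene"]], prom[conn], "PP", "hub")

    # bivalent support: each bivalent gene gets one active and one H3K27me3 loop
    active_pool = book.of_role("active_pool")
    pool_cursor: dict[str, int] = {c: 0 for c in lay["chroms"]}

    def next_pool_gene(chrom: str, max_usage: int = 4) -> Optional[Gene]:
        pool = [g for g in active_pool if g.chrom == chrom]
        if not pool:
            return None
        start = pool_cursor[chrom]
        for k in range(len(pool)):
            g = pool[(start + k) % len(pool)]
            if book.usage.get(g.gene_id, 0) < max_usage:
                pool_cursor[chrom] = (start + k + 1) % len(pool)
                book.usage[g.gene_id] = book.usage.get(g.gene_id, 0) + 1
                return g
        return None

    polycomb = book.of_role("polycomb")
    poly_cursor = [0]

    def next_poly_gene(chrom: str) -> Optional[Gene]:
        pool = [g for g in polycomb if g.chrom == chrom]
        if not pool:
            return None
        g = pool[poly_cursor[0] % len(pool)]
        poly_cursor[0] += 1
        return g

    for g in book.of_role("bivalent"):
        partner = next_pool_gene(g.chrom)
        if partner is not None:
            add_loop("H3K4me3", prom[g.gene_id], prom[partner.gene_id], "PP", "support")
        poly_partner = next_poly_gene(g.chrom)
        if poly_partner is not None:
            add_loop("H3K27me3", prom[g.gene_id], prom[poly_partner.gene_id], "PP", "support")

    def category_counts(mark: str) -> dict[str, int]:
        """Largest-remainder rounding of the mix onto the loop budget."""
        total = cfg.loop_counts.get(mark, 0)
        mix = cfg.category_mix.get(mark, {})
        raw = {c: total * f for c, f in mix.items()}
        counts = {c: int(math.floor(v)) for c, v in raw.items()}
        short = total - sum(counts.values())
        for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
            counts[c] += 1
        return counts

    def intergenic_anchor(chrom: str, near: Optional[int] = None) -> Optional[GenomicInterval]:
        zone = take_zone(chrom, near)
        if zone is None:
            return None
        z0, z1 = zone
        start = int(rng.integers(z0, z1 - _ANCHOR_WIDTH - _CRE_WIDTH - 200))
        return GenomicInterval(chrom, start, start + _ANCHOR_WIDTH)

    def pp_partner(pool: list[Gene], gi: int, span: int) -> Optional[Gene]:
        """Partner at roughly the sampled span (index-offset heuristic)."""
        if len(pool) < 2:
            return None
        g = pool[gi]
        spacing = max(1, (pool[-1].tss - pool[0].tss) // max(1, len(pool) - 1))
        offset = max(1, round(span / spacing))
        j = gi + offset if gi + offset < len(pool) else gi - offset
        if j < 0 or j == gi:
            j = (gi + 1) % len(pool)
        return pool[j]

    for mark in ACTIVE_MARKS:
        counts = category_counts(mark)
        law = cfg.span_distributions[mark]
        for category, count in counts.items():
            made = 0
            attempts = 0
            while made < count and attempts < count * 20:
                attempts += 1
                chrom = lay["chroms"][int(rng.integers(len(lay["chroms"])))]
                span = _sample_span(rng, law)
                if category == "PP":
                    pool = [g for g in active_pool if g.chrom == chrom]
                    if len(pool) < 2:
                        continue
                    gi = int(rng.integers(len(pool)))
                    g1 = pool[gi]
                    g2 = pp_partner(pool, gi, span)
                    if (
                        g2 is None
                        or g1.gene_id == g2.gene_id
                        or book.usage.get(g1.gene_id, 0) >= 4
                        or book.usage.get(g2.gene_id, 0) >= 4
                    ):
                        continue
                    if add_loop(
                        mark, prom[g1.gene_id], prom[g2.gene_id], "PP", "background"
                    ) is None:
                        continue
                    book.usage[g1.gene_id] = book.usage.get(g1.gene_id, 0) + 1
                    book.usage[g2.gene_id] = book.usage.get(g2.gene_id, 0) + 1
                elif category == "PI":
                    g = next_pool_gene(chrom)
                    if g is None:
                        continue
                    anchor = intergenic_anchor(chrom, near=g.tss + span)
                    if anchor is None or anchor.overlaps(prom[g.gene_id]):
                        continue
                    add_loop(mark, prom[g.gene_id], anchor, "PI", "background")
                else:  # II
                    a = intergenic_anchor(chrom)
                    if a is None:
                        continue
                    b = intergenic_anchor(chrom, near=a.start + span)
                    if b is None or a.overlaps(b):
                        continue
                    add_loop(mark, a, b, "II", "background")
                made += 1

    # H3K27me3 background loops
    counts = category_counts("H3K27me3")
    law = cfg.span_distributions.get("H3K27me3", ("lognormal", 50_000.0, 1.0))
    poly_pairs_made = 0
    for category, count in counts.items():
        made = 0
        attempts = 0
        while made < count and attempts < count * 20:
            attempts += 1
            chrom = lay["chroms"][int(rng.integers(len(lay["chroms"])))]
            span = _sample_span(rng, law)
            if category == "PP":
                pool = [g for g in polycomb if g.chrom == chrom]
                if len(pool) < 2:
                    continue
                gi = 2 * poly_pairs_made
                if gi + 1 >= len(pool):
                    # reuse the pool pairwise once exhausted
                    gi = int(rng.integers(len(pool) - 1))
                g1, g2 = pool[gi], pool[gi + 1]
                poly_pairs_made += 1
                if add_loop(
                    "H3K27me3", prom[g1.gene_id], prom[g2.gene_id], "PP", "background"
                ) is None:
                    continue
            elif category == "PI":
                pool = [g for g in polycomb if g.chrom == chrom]
                if not pool:
                    continue
                g = pool[int(rng.integers(len(pool)))]
                anchor = intergenic_anchor(chrom, near=g.tss + span)
                if anchor is None or anchor.overlaps(prom[g.gene_id]):
                    continue
                add_loop("H3K27me3", prom[g.gene_id], anchor, "PI", "background")
            else:
                a = intergenic_anchor(chrom)
                if a is None:
                    continue
                b = intergenic_anchor(chrom, near=a.start + span)
                if b is None or a.overlaps(b):
                    continue
                add_loop("H3K27me3", a, b, "II", "background")
            made += 1

    # H3K9me2: pericentromeric intergenic-intergenic, spans drawn exactly
    law = cfg.span_distributions.get("H3K9me2", ("lognormal", 105_000.0, 0.45))
    pad = 10_000
    target = cfg.loop_counts.get("H3K9me2", 0)
    made = 0
    attempts = 0
    while made < target and attempts < target * 20:
        attempts += 1
        chrom = lay["chroms"][int(rng.integers(len(lay["chroms"])))]
        span = _sample_span(rng, law)
        span = min(span, cen1 - cen0 - 2 * pad - 2 * _ANCHOR_WIDTH)
        left = int(rng.integers(cen0 + pad, cen1 - pad - span - _ANCHOR_WIDTH))
        a = GenomicInterval(chrom, left, left + _ANCHOR_WIDTH)
        b = GenomicInterval(chrom, left + span, left + span + _ANCHOR_WIDTH)
        if a.overlaps(b) or add_loop("H3K9me2", a, b, "II", "background") is None:
            continue
        made += 1

    # ---- peaks -----------------------------------------------------------
    peaks: dict[str, list[Peak]] = {}
    anchor_peak_truth = []

    def anchor_intensity() -> float:
        return float(rng.lognormal(math.log(20.0), 0.5))

    def basal_intensity() -> float:
        return float(rng.lognormal(math.log(10.0), 0.5))

    for mark in cfg.loop_counts:
        seen: dict[GenomicInterval, None] = {}
        for lp in loops.get(mark, []):
            for anchor in (lp.anchor_a, lp.anchor_b):
                seen.setdefault(anchor, None)
        mark_peaks = [
            Peak(
                interval=iv,
                mark=mark,
                intensity=anchor_intensity(),
                name=f"{mark}_anchor_{i}",
            )
            for i, iv in enumerate(seen)
        ]
        for p in mark_peaks:
            anchor_peak_truth.append({"mark": mark, "peak": p.name, "status": "anchor"})
        peaks[mark] = mark_peaks

    # basal peaks: active marks on all loop-free non-polycomb genes
    active_anchor_genes = {
        gid
        for gid, role in book.role.items()
        if role in ("hub_node", "hub_conn", "bivalent")
        or (role == "active_pool" and book.usage.get(gid, 0) > 0)
    }
    for mark in ACTIVE_MARKS:
        basal_hosts = [
            g
            for g in genes
            if g.gene_id not in active_anchor_genes
            and book.role[g.gene_id] in ("active_pool", "basal")
        ]
        if mark != "H3K4me3":  # secondary marks cover a random half
            keep = rng.random(len(basal_hosts)) < 0.5
            basal_hosts = [g for g, k in zip(basal_hosts, keep) if k]
        for i, g in enumerate(basal_hosts):
            p = Peak(
                interval=prom[g.gene_id],
                mark=mark,
                intensity=basal_intensity(),
                name=f"{mark}_basal_{i}",
            )
            peaks[mark].append(p)
            anchor_peak_truth.append({"mark": mark, "peak": p.name, "status": "basal"})

    # basal H3K27me3 peaks at polycomb_basal promoters
    for i, g in enumerate(book.of_role("polycomb_basal")):
        p = Peak(
            interval=prom[g.gene_id],
            mark="H3K27me3",
            intensity=basal_intensity(),
            name=f"H3K27me3_basal_{i}",
        )
        peaks["H3K27me3"].append(p)
        anchor_peak_truth.append({"mark": "H3K27me3", "peak": p.name, "status": "basal"})

    # ---- CREs ------------------------------------------------------------
    cre_rows, cres = _plant_cres(
        cfg, lay, rng, book, genes, prom, loops, peaks, zones, zone_used,
        active_anchor_genes, add_loop, chrom_sizes,
    )

    # ---- TF targets ------------------------------------------------------
    tf_rows = []
    hub_genes_ordered = [
        gid
        for row in hub_rows
        for gid in [row["node_gene"]] + row["connecting_genes"].split(",")
    ]
    outside_pool = sorted(
        gid
        for gid, role in book.role.items()
        if role in ("active_pool", "basal") and gid not in active_anchor_genes
    )
    for name, n_targets, concentration in cfg.tf_configs:
        n_in = min(round(n_targets * concentration), len(hub_genes_ordered))
        inside = hub_genes_ordered[:n_in]
        n_out = n_targets - len(inside)
        picks = rng.choice(len(outside_pool), size=min(n_out, len(outside_pool)), replace=False)
        outside = [outside_pool[i] for i in sorted(picks)]
        for gid in inside:
            tf_rows.append({"tf": name, "gene_id": gid, "in_hub": True})
        for gid in outside:
            tf_rows.append({"tf": name, "gene_id": gid, "in_hub": False})

    # ---- SNPs ------------------------------------------------------------
    snp_rows = _plant_snps(cfg, rng, loops, zones, zone_used)

    # ---- truth assembly --------------------------------------------------
    k27_anchor_genes = {
        lp_gene
        for lp in loops.get("H3K27me3", [])
        for lp_gene, piv in prom.items()
        if piv == lp.anchor_a or piv == lp.anchor_b
    }
    cre_boosted = {
        row["connected_gene"] for row in cre_rows if isinstance(row.get("connected_gene"), str)
    }
    gene_rows = [
        {
            "gene_id": g.gene_id,
            "role": book.role[g.gene_id],
            "active_anchor": g.gene_id in active_anchor_genes,
            "h3k27me3_anchor": g.gene_id in k27_anchor_genes,
            "boosted": g.gene_id in active_anchor_genes,
            "cre_boosted": g.gene_id in cre_boosted,
        }
        for g in genes
    ]

    # co-expression pairs: disjoint PP pairs from active background loops
    pair_rows = []
    used_genes: set[str] = set()
    gene_of_prom = {iv: gid for gid, iv in prom.items()}
    for mark in ACTIVE_MARKS:
        for lp in loops.get(mark, []):
            if len(pair_rows) >= cfg.n_coexpr_pairs:
                break
            ga = gene_of_prom.get(lp.anchor_a)
            gb = gene_of_prom.get(lp.anchor_b)
            if ga is None or gb is None or ga in used_genes or gb in used_genes:
                continue
            used_genes.update((ga, gb))
            pair_rows.append({"gene_a": ga, "gene_b": gb, "mark": mark})

    truth = SimTruth(
        gene_roles=pd.DataFrame(gene_rows),
        loops=pd.DataFrame(loop_rows),
        pairs=pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "mark"]),
        hubs=pd.DataFrame(hub_rows),
        tf_targets=pd.DataFrame(tf_rows, columns=["tf", "gene_id", "in_hub"]),
        cres=pd.DataFrame(cre_rows),
        snps=pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "group"]),
    )
    peaks["ATAC"] = cres
    return peaks, loops, truth


def _plant_cres(
    cfg, lay, rng, book, genes, prom, loops, peaks, zones, zone_used,
    active_anchor_genes, add_loop, chrom_sizes,
):
    """Plant accessible regions with known class / state / status."""
    if cfg.n_cres == 0:
        return [], []
    n = {c: round(cfg.n_cres * f) for c, f in cfg.cre_class_fractions.items()}
    n_pre, n_dre, n_intra = n.get("PRE", 0), n.get("DRE", 0), n.get("intragenic", 0)
    sf = cfg.cre_state_fractions
    af = cfg.cre_anchor_fraction
    pre_quota = {
        ("poiAct", "anchor"): round(n_pre * sf.get("poiAct", 0.0)),
        ("poised", "anchor"): round(n_pre * sf.get("poised", 0.0) * af),
        ("poised", "basal"): round(n_pre * sf.get("poised", 0.0) * (1 - af)),
        ("active", "basal"): round(n_pre * sf.get("active", 0.0) * (1 - af)),
    }
    pre_quota[("active", "anchor")] = n_pre - sum(pre_quota.values())
    dre_quota = {
        ("poised", "anchor"): round(n_dre * sf.get("poised", 0.0) * af),
        ("poised", "basal"): round(n_dre * sf.get("poised", 0.0) * (1 - af)),
        ("active", "basal"): round(n_dre * sf.get("active", 0.0) * (1 - af)),
    }
    dre_quota[("active", "anchor")] = n_dre - sum(dre_quota.values())

    rows = []
    cres: list[Peak] = []

    def emit(iv, genomic_class, state, status, nearest=None, connected=None):
        name = f"cre_{len(cres)}"
        cres.append(
            Peak(interval=iv, mark="ATAC", intensity=float(rng.lognormal(2.0, 0.4)), name=name)
        )
        rows.append(
            {
                "cre_id": name,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "genomic_class": genomic_class,
                "state": state,
                "status": status,
                "nearest_gene": nearest,
                "connected_gene": connected,
            }
        )

    def pre_interval(g: Gene) -> GenomicInterval:
        if g.strand == "+":
            return GenomicInterval(g.chrom, g.tss - 600, g.tss + 200)
        return GenomicInterval(g.chrom, g.tss - 199, g.tss + 601)

    hosts = {
        # bivalent promoters would classify poiAct, so exclude them here
        ("active", "anchor"): sorted(
            gid for gid in active_anchor_genes if book.role.get(gid) != "bivalent"
        ),
        ("active", "basal"): [g.gene_id for g in book.of_role("basal")],
        ("poised", "anchor"): [
            gid
            for gid, role in book.role.items()
            if role == "polycomb"
            and any(
                prom[gid] in (lp.anchor_a, lp.anchor_b)
                for lp in loops.get("H3K27me3", [])
            )
        ],
        ("poised", "basal"): [g.gene_id for g in book.of_role("polycomb_basal")],
        ("poiAct", "anchor"): [g.gene_id for g in book.of_role("bivalent")],
    }
    for key in hosts:
        hosts[key] = sorted(hosts[key])

    used_hosts: set[str] = set()
    for key, count in pre_quota.items():
        pool = [h for h in hosts.get(key, []) if h not in used_hosts]
        take = pool[:count]
        used_hosts.update(take)
        for gid in take:
            g = book.genes[gid]
            emit(pre_interval(g), "PRE", key[0], key[1], nearest=gid)

    # DREs in intergenic zones
    gene_list = sorted(genes, key=lambda g: (g.chrom, g.tss))

    def nearest_gene(iv: GenomicInterval) -> Optional[str]:
        mid = iv.midpoint
        best = None
        for g in gene_list:
            if g.chrom != iv.chrom:
                continue
            d = abs(mid - g.tss)
            if best is None or (d, g.gene_id) < best:
                best = (d, g.gene_id)
        return best[1] if best else None

    def free_zone_indices(chrom: str) -> list[int]:
        return [i for i, u in enumerate(zone_used[chrom]) if not u]

    # poised DREs: next to an H3K27me3 intergenic anchor (anchor status) or
    # a freshly planted basal H3K27me3 intergenic peak (basal status)
    k27_intergenic_anchors = [
        anchor
        for lp in loops.get("H3K27me3", [])
        for anchor in (lp.anchor_a, lp.anchor_b)
        if anchor not in {prom[g.gene_id] for g in genes if g.chrom == anchor.chrom}
    ]
    ki = 0
    for status in ("anchor", "basal"):
        count = dre_quota[("poised", status)]
        made = 0
        while made < count:
            if status == "anchor":
                if ki >= len(k27_intergenic_anchors):
                    break
                host = k27_intergenic_anchors[ki]
                ki += 1
            else:
                chrom = lay["chroms"][made % len(lay["chroms"])]
                free = free_zone_indices(chrom)
                if not free:
                    break
                zi = free[0]
                zone_used[chrom][zi] = True
                z0, z1 = zones[chrom][zi]
                host = GenomicInterval(chrom, z0, z0 + _ANCHOR_WIDTH)
                p = Peak(
                    interval=host,
                    mark="H3K27me3",
                    intensity=float(rng.lognormal(math.log(10.0), 0.5)),
                    name=f"H3K27me3_ibasal_{made}",
                )
                peaks["H3K27me3"].append(p)
            gap = int(rng.integers(100, 300))
            cre = GenomicInterval(host.chrom, host.end + gap, host.end + gap + _CRE_WIDTH)
            emit(cre, "DRE", "poised", status, nearest=nearest_gene(cre))
            made += 1

    # active anchor DREs: a fresh PI loop (H3K4me1) from an intergenic
    # anchor placed in the slot zone of an active anchor gene; the far
    # anchor is another active-pool gene's promoter (the connected gene)
    count = dre_quota[("active", "anchor")]
    made = 0
    slot_gene = {}
    for g in genes:
        slots = lay["slots"][g.chrom]
        # gene sits inside exactly one slot (layout construction)
        for si, (s0, s1) in enumerate(slots):
            if s0 <= g.interval.start < s1:
                slot_gene[(g.chrom, si)] = g
                break
    zone_slot_index: dict[str, dict[int, int]] = {}
    for chrom in lay["chroms"]:
        zone_slot_index[chrom] = {}
        zi = 0
        for si, slot in enumerate(lay["slots"][chrom]):
            if _zone_of_slot(slot) is not None:
                zone_slot_index[chrom][zi] = si
                zi += 1
    anchor_host_candidates = [
        (chrom, zi)
        for chrom in lay["chroms"]
        for zi in free_zone_indices(chrom)
        if (g := slot_gene.get((chrom, zone_slot_index[chrom].get(zi, -1)))) is not None
        and g.gene_id in active_anchor_genes
    ]
    conn_pool = [g for g in book.of_role("active_pool") if book.usage.get(g.gene_id, 0) < 4]
    ci = 0
    for chrom, zi in anchor_host_candidates:
        if made >= count or ci >= len(conn_pool):
            break
        z0, z1 = zones[chrom][zi]
        anchor = GenomicInterval(chrom, z0, z0 + _ANCHOR_WIDTH)
        cre = GenomicInterval(chrom, z0 + 100, z0 + 100 + _CRE_WIDTH)  # inside anchor
        near = nearest_gene(cre)
        if near is None or near not in active_anchor_genes:
            continue
        partner = None
        while ci < len(conn_pool):
            cand = conn_pool[ci]
            ci += 1
            if cand.chrom == chrom:
                partner = cand
                break
        if partner is None:
            continue
        zone_used[chrom][zi] = True
        add_loop("H3K4me1", anchor, prom[partner.gene_id], "PI", "support")
        # every loop anchor carries a peak of its mark
        existing = {p.interval for p in peaks["H3K4me1"]}
        for iv in (anchor, prom[partner.gene_id]):
            if iv not in existing:
                peaks["H3K4me1"].append(
                    Peak(
                        interval=iv,
                        mark="H3K4me1",
                        intensity=float(rng.lognormal(math.log(20.0), 0.5)),
                        name=f"H3K4me1_support_{made}_{iv.start}",
                    )
                )
        book.usage[partner.gene_id] = book.usage.get(partner.gene_id, 0) + 1
        active_anchor_genes.add(partner.gene_id)
        emit(cre, "DRE", "active", "anchor", nearest=near, connected=partner.gene_id)
        made += 1

    # active basal DREs: quiet zones whose nearest gene is basal
    count = dre_quota[("active", "basal")]
    made = 0
    basal_ids = {g.gene_id for g in book.of_role("basal")}
    for chrom in lay["chroms"]:
        for zi in list(free_zone_indices(chrom)):
            if made >= count:
                break
            z0, z1 = zones[chrom][zi]
            cre = GenomicInterval(chrom, z0 + 600, z0 + 600 + _CRE_WIDTH)
            near = nearest_gene(cre)
            if near is None or near not in basal_ids:
                continue
            zone_used[chrom][zi] = True
            emit(cre, "DRE", "active", "basal", nearest=near)
            made += 1

    # intragenic CREs: inside long gene bodies, clear of the promoter
    made = 0
    for g in gene_list:
        if made >= n_intra:
            break
        if g.interval.length < 2500 or g.gene_id in used_hosts:
            continue
        if g.strand == "+":
            iv = GenomicInterval(g.chrom, g.tss + 700, g.tss + 700 + _CRE_WIDTH)
        else:
            iv = GenomicInterval(g.chrom, g.tss - 700 - _CRE_WIDTH + 1, g.tss - 699)
        used_hosts.add(g.gene_id)
        emit(iv, "intragenic", None, None, nearest=g.gene_id)
        made += 1

    return rows, cres


def _plant_snps(cfg, rng, loops, zones, zone_used):
    """SNPs planted inside group-exclusive loop anchors plus background."""
    if cfg.n_snps == 0:
        return []
    from .annotate import build_tree

    group_marks = {
        "active": ACTIVE_MARKS,
        "repressive": ("H3K27me3",),
        "inactive": ("H3K9me2",),
    }
    anchors_by_group = {
        grp: [
            anchor
            for mark in marks
            for lp in loops.get(mark, [])
            for anchor in (lp.anchor_a, lp.anchor_b)
        ]
        for grp, marks in group_marks.items()
    }
    trees = {
        grp: build_tree((a, None) for a in anchors)
        for grp, anchors in anchors_by_group.items()
    }

    def exclusive(anchor: GenomicInterval, group: str) -> bool:
        for other, tree in trees.items():
            if other == group:
                continue
            t = tree.get(anchor.chrom)
            if t is not None and t.overlap(anchor.start, anchor.end):
                return False
        return True

    rows = []
    counts = {g: round(cfg.n_snps * f) for g, f in cfg.snp_fractions.items()}
    for group, count in counts.items():
        hosts = [a for a in anchors_by_group[group] if exclusive(a, group)]
        if len(hosts) < count:
            raise ValueError(f"not enough exclusive {group} anchors to host SNPs")
        picks = rng.choice(len(hosts), size=count, replace=False)
        for k, pi in enumerate(sorted(picks)):
            a = hosts[pi]
            pos = int(rng.integers(a.start, a.end))
            rows.append(
                {"snp_id": f"snp_{group}_{k}", "chrom": a.chrom, "pos": pos, "group": group}
            )
    # background SNPs in loop-free intergenic zones
    n_bg = cfg.n_snps - sum(counts.values())
    made = 0
    for chrom in sorted(zones):
        for zi, (z0, z1) in enumerate(zones[chrom]):
            if made >= n_bg:
                break
            if zone_used[chrom][zi]:
                continue
            pos = int(rng.integers(z0, z1))
            rows.append(
                {"snp_id": f"snp_none_{made}", "chrom": chrom, "pos": pos, "group": "none"}
            )
            made += 1
    return rows


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    cfg: SimConfig,
    genes: Sequence[Gene],
    truth: SimTruth,
) -> ExpressionTable:
    """FPKM table with planted anchor boost and pairwise co-expression.

    Log-FPKM of gene g in tissue t is ``b_g + sigma * z_gt`` with iid
    standard-normal z; each planted pair shares a common latent factor with
    loading sqrt(r) where r is chosen analytically so the *linear-scale*
    expected Pearson correlation of the log-normal profiles equals
    ``planted_pair_pcc``:  rho = (exp(r s^2) - 1) / (exp(s^2) - 1).
    Anchor genes are multiplied by ``anchor_expression_boost`` (a constant
    factor, leaving correlations untouched).
    """
    rng = cfg.rng(_SEED_EXPR)
    rho = cfg.planted_pair_pcc
    s2 = cfg.expr_tissue_log_sd**2
    denom = math.expm1(s2)
    arg = 1.0 + rho * denom
    if not (-1.0 < rho < 1.0) or arg <= 0:
        raise ValueError(f"planted_pair_pcc {rho} not representable")
    r = math.log(arg) / s2
    if abs(r) > 1:
        raise ValueError(f"planted_pair_pcc {rho} needs |r| > 1 latent loading")

    n_g, n_t = len(genes), cfg.n_tissues
    gene_ids = [g.gene_id for g in genes]
    base = rng.normal(cfg.expr_log_mean, cfg.expr_gene_log_sd, size=n_g)
    z = rng.standard_normal((n_g, n_t))
    index = {gid: i for i, gid in enumerate(gene_ids)}
    for _, row in truth.pairs.iterrows():
        ia, ib = index.get(row.gene_a), index.get(row.gene_b)
        if ia is None or ib is None:
            continue
        common = rng.standard_normal(n_t)
        la = math.sqrt(abs(r))
        lb = math.copysign(la, r)
        resid = math.sqrt(1 - abs(r))
        z[ia] = la * common + resid * rng.standard_normal(n_t)
        z[ib] = lb * common + resid * rng.standard_normal(n_t)

    log_fpkm = base[:, None] + cfg.expr_tissue_log_sd * z
    roles = truth.gene_roles.set_index("gene_id")
    boosted = roles.reindex(gene_ids)["boosted"].fillna(False).to_numpy(dtype=bool)
    cre_boosted = roles.reindex(gene_ids)["cre_boosted"].fillna(False).to_numpy(dtype=bool)
    log_fpkm[boosted] += math.log(cfg.anchor_expression_boost)
    log_fpkm[cre_boosted] += math.log(cfg.cre_connected_boost)
    tissues = ["seedling"] + [f"tissue_{i:02d}" for i in range(2, n_t + 1)]
    frame = pd.DataFrame(np.exp(log_fpkm), index=gene_ids, columns=tissues)
    return ExpressionTable(frame)


# ---------------------------------------------------------------------------
# two-condition hub disassembly
# ---------------------------------------------------------------------------

def _pdh_removals(n_c: int) -> int:
    """Removals planting a partially-disassembled hub: ratio in [0.3, 0.7),
    at least 3 lost, at least 5 left (so the hub is still detected)."""
    k = max(3, math.ceil(0.3 * n_c))
    if not (0.3 <= k / n_c < 0.7 and n_c - k >= 5):
        raise ValueError(f"cannot plant a PDH on a hub of degree {n_c}")
    return k


def _fh_additions(n_c: int) -> int:
    """Gains planting a formed/grown hub: g/(Nc+g) >= 0.3 and g >= 3."""
    g = max(3, math.ceil(3 * n_c / 7))
    assert g / (n_c + g) >= 0.3 - 1e-12
    return g


def generate_condition_pair(
    cfg: SimConfig,
    loops: Mapping[str, Sequence[Loop]],
    truth: SimTruth,
    expression: ExpressionTable,
    genes: Sequence[Gene],
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> ConditionPair:
    """Create a second condition with planted hub disassembly.

    Condition 1 is the base H3K4me3 loop set. In condition 2, a fraction
    f_EDH of planted hubs loses all member loops, f_PDH loses enough
    connecting genes to satisfy the PDH inequalities exactly (while staying
    above the hub-detection degree), f_FH gains fresh connecting genes, and
    the remainder is untouched. Per-condition FPKM vectors carry
    multiplicative log-normal noise, with separated genes additionally
    down-regulated by ``separated_downregulation``.
    """
    rng = cfg.rng(_SEED_COND)
    hubs = truth.hubs
    n_hubs = len(hubs)
    f_edh, f_pdh, f_fh = cfg.hub_disassembly_fractions
    n_edh, n_pdh, n_fh = (round(n_hubs * f) for f in (f_edh, f_pdh, f_fh))
    if n_edh + n_pdh + n_fh > n_hubs:
        raise ValueError("disassembly fractions exceed the number of planted hubs")
    order = rng.permutation(n_hubs)
    labels = {}
    for k, hi in enumerate(order):
        if k < n_edh:
            labels[hi] = "EDH"
        elif k < n_edh + n_pdh:
            labels[hi] = "PDH"
        elif k < n_edh + n_pdh + n_fh:
            labels[hi] = "FH"
        else:
            labels[hi] = "stable"

    base = list(loops.get("H3K4me3", []))
    roles = truth.gene_roles.set_index("gene_id")
    fresh_pool = [
        gid
        for gid in roles.index
        if roles.loc[gid, "role"] == "basal" and not roles.loc[gid, "active_anchor"]
    ]
    fresh_cursor = 0
    prom = {g.gene_id: promoter_of(g, chrom_sizes=chrom_sizes) for g in genes}
    by_chrom_fresh: dict[str, list[str]] = {}
    gene_chrom = {g.gene_id: g.chrom for g in genes}
    for gid in fresh_pool:
        by_chrom_fresh.setdefault(gene_chrom[gid], []).append(gid)

    hub_truth_rows = []
    for hi in range(n_hubs):
        row = hubs.iloc[hi]
        label = labels[hi]
        conns = row.connecting_genes.split(",")
        n_c = len(conns)
        separated: list[str] = []
        gained: list[str] = []
        if label == "EDH":
            separated = conns
        elif label == "PDH":
            k = _pdh_removals(n_c)
            picks = rng.choice(n_c, size=k, replace=False)
            separated = [conns[i] for i in sorted(picks)]
        elif label == "FH":
            g = _fh_additions(n_c)
            pool = by_chrom_fresh.get(row.chrom, [])
            gained = pool[:g]
            by_chrom_fresh[row.chrom] = pool[g:]
            if len(gained) < g:
                raise ValueError("fresh gene pool exhausted while planting FH hubs")
        hub_truth_rows.append(
            {
                "hub_id": row.hub_id,
                "node_gene": row.node_gene,
                "label": label,
                "n_c": n_c,
                "n_m": n_c - len(separated) + len(gained),
                "separated": ",".join(separated),
                "aggregated": ",".join(c for c in conns if c not in separated),
                "gained": ",".join(gained),
            }
        )

    # hub loops were emitted node-first in hubs-table order with sequential
    # ids, so the (node, connecting) pair of each hub loop is recoverable
    pair_of_loop: dict[str, tuple[str, str]] = {}
    k = 0
    for _, row in hubs.iterrows():
        for conn in row.connecting_genes.split(","):
            pair_of_loop[f"H3K4me3_{k}"] = (row.node_gene, conn)
            k += 1
    sep_pairs = {
        (r["node_gene"], s)
        for r in hub_truth_rows
        for s in r["separated"].split(",")
        if s
    }
    cond2 = [
        lp
        for lp in base
        if pair_of_loop.get(lp.loop_id) not in sep_pairs
    ]
    gain_specs = [
        (r["node_gene"], g)
        for r in hub_truth_rows
        for g in r["gained"].split(",")
        if g
    ]
    for i, (node, gid) in enumerate(gain_specs):
        cond2.append(
            Loop(
                anchor_a=prom[node],
                anchor_b=prom[gid],
                mark="H3K4me3",
                pet_count=int(rng.integers(2, 21)),
                fdr=float(rng.uniform(0.0, 0.049)),
                loop_id=f"H3K4me3_gain_{i}",
            )
        )

    hub_truth = pd.DataFrame(hub_truth_rows)
    expr1 = expression.frame["seedling"].copy()
    noise = np.exp(rng.normal(0.0, cfg.condition_noise_log_sd, size=len(expr1)))
    factor = pd.Series(noise, index=expr1.index)
    separated_all = {
        s for r in hub_truth_rows for s in r["separated"].split(",") if s
    }
    factor.loc[factor.index.isin(separated_all)] *= cfg.separated_downregulation
    expr2 = expr1 * factor
    frame = pd.DataFrame({"cond1": expr1, "cond2": expr2})
    return ConditionPair(
        loops_cond1=base,
        loops_cond2=cond2,
        hub_truth=hub_truth,
        expression_conditions=frame,
    )


def generate_dataset(cfg: SimConfig) -> SimDataset:
    """Run the full generator pipeline under one config."""
    chrom_sizes, genes = generate_genome(cfg)
    peaks, loops, truth = generate_peaks_and_loops(cfg, chrom_sizes, genes)
    expression = generate_expression(cfg, genes, truth)
    pair = generate_condition_pair(
        cfg, loops, truth, expression, genes=genes, chrom_sizes=chrom_sizes
    )
    return SimDataset(
        config=cfg,
        chrom_sizes=chrom_sizes,
        genes=genes,
        peaks=peaks,
        loops=loops,
        truth=truth,
        expression=expression,
        condition_pair=pair,
    )


def write_dataset(ds: SimDataset, outdir) -> list[Path]:
    """Emit the dataset in the exact formats the I/O layer reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def note(path):
        written.append(path)
        return path

    chio.write_chrom_sizes(ds.chrom_sizes, note(outdir / "genome.chrom.sizes"))
    chio.write_gff3(ds.genes, note(outdir / "genes.gff3"))
    for mark, peaks in sorted(ds.peaks.items()):
        chio.write_bed(peaks, note(outdir / f"peaks_{mark}.narrowPeak"))
    for mark, loops in sorted(ds.loops.items()):
        chio.write_bedpe(loops, note(outdir / f"loops_{mark}.bedpe"))
    chio.write_expression(ds.expression, note(outdir / "expression.tsv"))
    with open(note(outdir / "snps.bed"), "w") as fh:
        for _, row in ds.truth.snps.iterrows():
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.snp_id}\n")
    chio.write_bedpe(ds.condition_pair.loops_cond1, note(outdir / "loops_H3K4me3_cond1.bedpe"))
    chio.write_bedpe(ds.condition_pair.loops_cond2, note(outdir / "loops_H3K4me3_cond2.bedpe"))
    frame = ds.condition_pair.expression_conditions.copy()
    frame.index.name = "gene_id"
    frame.to_csv(note(outdir / "expression_conditions.tsv"), sep="\t")
    ds.truth.to_dir(outdir)
    for name in ("gene_roles", "loops", "pairs", "hubs", "tf_targets", "cres", "snps"):
        written.append(outdir / f"truth_{name}.tsv")
    return written
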