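"""Chromatin hub detection, TF-target enrichment, and two-condition
differential hub classification.

A chromatin hub is a merged loop anchor from which at least ``min_degree``
interactions emanate; the gene at that anchor is the node gene and the
genes at the far anchors are the connecting genes. Between two conditions,
hubs sharing a node gene are the same hub, and the change in connecting
genes Ns = Nc - Nm classifies the hub as stable, partially disassembled
(PDH), entirely disassembled (EDH), or newly formed / markedly grown (FH).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import ExpressionTable, Gene, GenomicInterval, Loop
from .network import assign_anchor_gene, GeneAssigner

__all__ = [
    "Hub",
    "HubDelta",
    "EnrichmentResult",
    "detect_hubs",
    "hub_enrichment",
    "random_hub_control",
    "classify_hub_change",
    "compare_conditions",
]


@dataclass
class Hub:
    hub_id: str
    node_anchor: GenomicInterval
    node_gene: Optional[str]
    degree: int
    connecting_genes: frozenset[str]
    member_loops: tuple[str, ...]


@dataclass(frozen=True)
class HubDelta:
    """Per-hub change between condition 1 (Nc connecting genes) and
    condition 2 (Nm)."""

    node_gene: str
    n_c: int
    n_m: int
    category: str
    aggregated: frozenset[str] = frozenset()
    separated: frozenset[str] = frozenset()

    @property
    def n_s(self) -> int:
        return self.n_c - self.n_m


@dataclass
class EnrichmentResult:
    hub_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    p_adjusted: Optional[float]
    enriched: bool


def _merge_anchors(anchors: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for a in anchors:
        by_chrom[a.chrom].append(a)
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_e:  # strict overlap (half-open abutting stays split)
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def detect_hubs(
    loops: Sequence[Loop],
    genes: Sequence[Gene],
    expression: Optional[ExpressionTable] = None,
    min_degree: int = 5,
    merge_anchors: bool = True,
    tissue: Optional[str] = None,
    mark_category: str = "active",
) -> list[Hub]:
    """Detect chromatin hubs from a set of loops.

    Overlapping loop anchors are merged into node candidates; a candidate's
    degree is the number of member loops touching it, and candidates with
    degree >= ``min_degree`` become hubs. Node and connecting genes are
    assigned with the anchor-gene rule (>= 50% of the anchor inside the
    gene's 1 kb-upstream-through-TTS window; highest FPKM wins ties for the
    active category).
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    loops = list(loops)
    all_anchors = [a for lp in loops for a in (lp.anchor_a, lp.anchor_b)]
    if not all_anchors:
        return []
    nodes = _merge_anchors(all_anchors) if merge_anchors else sorted(set(all_anchors))
    # locate which merged node each anchor belongs to
    node_index: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for ni, node in enumerate(nodes):
        node_index[node.chrom].append((node.start, node.end, ni))
    for chrom in node_index:
        node_index[chrom].sort()
    import bisect

    def find_node(anchor: GenomicInterval) -> Optional[int]:
        # merged nodes are disjoint and sorted, so binary search suffices
        entries = node_index.get(anchor.chrom, [])
        pos = bisect.bisect_right(entries, (anchor.start, float("inf"), -1)) - 1
        for k in (pos, pos + 1):
            if 0 <= k < len(entries):
                s, e, ni = entries[k]
                if anchor.start < e and anchor.end > s:
                    return ni
        return None

    members: dict[int, list[tuple[str, GenomicInterval]]] = defaultdict(list)
    for i, lp in enumerate(loops):
        lid = lp.loop_id or f"loop_{i}"
        na = find_node(lp.anchor_a)
        nb = find_node(lp.anchor_b)
        if na is not None:
            members[na].append((lid, lp.anchor_b))
        if nb is not None and nb != na:
            members[nb].append((lid, lp.anchor_a))

    assigner = GeneAssigner(genes, expression, tissue=tissue)
    hubs = []
    for ni, node in enumerate(nodes):
        mem = members.get(ni, [])
        if len(mem) < min_degree:
            continue
        node_genes = assigner.assign(node, mark_category)
        connecting: set[str] = set()
        for _, far in mem:
            connecting.update(assigner.assign(far, mark_category))
        hubs.append(
            Hub(
                hub_id=f"hub_{len(hubs)}",
                node_anchor=node,
                node_gene=node_genes[0] if node_genes else None,
                degree=len(mem),
                connecting_genes=frozenset(connecting),
                member_loops=tuple(sorted(lid for lid, _ in mem)),
            )
        )
    return hubs


def _hypergeom_greater(k: int, big_n: int, big_k: int, n: int) -> float:
    """One-sided (greater) Fisher p: P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def hub_enrichment(
    hub_genes: Iterable[str],
    tf_targets: Iterable[str],
    gene_universe: Iterable[str],
    alpha: float = 0.05,
    hub_id: str = "hub",
) -> EnrichmentResult:
    """Fisher's exact test (one-sided, greater) for TF-target enrichment
    in one hub against the gene universe."""
    universe = set(gene_universe)
    if not universe:
        raise ValueError("empty gene universe")
    hub_set = set(hub_genes) & universe
    targets = set(tf_targets) & universe
    a = len(hub_set & targets)
    b = len(hub_set - targets)
    c = len(targets - hub_set)
    d = len(universe - hub_set - targets)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(
        hub_id=hub_id,
        table=((a, b), (c, d)),
        p_value=float(p),
        p_adjusted=None,
        enriched=bool(p < alpha),
    )


def enrich_hubs(
    hubs: Sequence[Hub],
    tf_targets: Iterable[str],
    gene_universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Enrichment for every hub, with BH-adjusted p reported alongside
    (the ``enriched`` flag follows the raw p < alpha screen)."""
    results = [
        hub_enrichment(
            hub.connecting_genes | ({hub.node_gene} if hub.node_gene else set()),
            tf_targets,
            gene_universe,
            alpha=alpha,
            hub_id=hub.hub_id,
        )
        for hub in hubs
    ]
    if results:
        ps = np.array([r.p_value for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, ps[i] * m / (rank + 1))
            adj[i] = running
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    return results


def random_hub_control(
    hubs: Sequence[Hub],
    anchor_gene_pool: Sequence[str],
    tf_targets: Iterable[str],
    n_rounds: int,
    seed: int,
    alpha: float = 0.05,
) -> list[int]:
    """Size-matched random-hub control for TF-target enrichment.

    Per round, for every observed hub a same-size gene set is drawn without
    replacement from the anchor-gene pool and screened at raw p < alpha;
    the round's value is the total number of TF targets inside the random
    hubs that pass the screen.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    pool = list(anchor_gene_pool)
    sizes = [
        len(h.connecting_genes | ({h.node_gene} if h.node_gene else set())) for h in hubs
    ]
    if sizes and max(sizes) > len(pool):
        raise ValueError("anchor gene pool smaller than the largest hub")
    targets = set(tf_targets)
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_rounds):
        total = 0
        for size in sizes:
            sample = rng.choice(len(pool), size=size, replace=False)
            genes = {pool[i] for i in sample}
            res = hub_enrichment(genes, targets, pool, alpha=alpha)
            if res.enriched:
                total += len(genes & targets)
        counts.append(total)
    return counts


def classify_hub_change(n_c: int, n_m: int) -> str:
    """Classify a hub's change from its connecting-gene counts.

    With Ns = Nc - Nm: EDH iff Ns/Nc >= 0.7 and Ns >= 3; else PDH iff
    0.3 <= Ns/Nc < 0.7 and Ns >= 3; else FH iff (-Ns)/Nm >= 0.3 and
    Nc - Nm <= -3; else stable. Each formula's conditions are conjunctions,
    evaluated in the order EDH, PDH, FH.
    """
    if n_c < 0 or n_m < 0:
        raise ValueError("connecting-gene counts must be non-negative")
    if n_c == 0 and n_m == 0:
        raise ValueError("hub absent in both conditions")
    n_s = n_c - n_m
    if n_c > 0:
        ratio = n_s / n_c
        if ratio >= 0.7 and n_s >= 3:
            return "EDH"
        if 0.3 <= ratio < 0.7 and n_s >= 3:
            return "PDH"
    if n_m > 0 and (-n_s) / n_m >= 0.3 and n_s <= -3:
        return "FH"
    return "stable"


def compare_conditions(
    hubs_1: Sequence[Hub],
    hubs_2: Sequence[Hub],
) -> list[HubDelta]:
    """Match hubs across two conditions by node gene and classify changes.

    Hubs present in only one condition get Nm = 0 (condition 1 only) or
    Nc = 0 (condition 2 only). For disassembled hubs (EDH/PDH), the
    condition-1 connecting genes are partitioned into aggregated (still
    connected in condition 2) and separated (lost) genes.
    """

    def by_node(hubs: Sequence[Hub]) -> dict[str, frozenset[str]]:
        out: dict[str, frozenset[str]] = {}
        for h in hubs:
            if h.node_gene is None:
                continue
            if h.node_gene in out:
                warnings.warn(
                    f"duplicate node gene {h.node_gene}; merging hubs", RuntimeWarning
                )
                out[h.node_gene] = out[h.node_gene] | h.connecting_genes
            else:
                out[h.node_gene] = h.connecting_genes
        return out

    cond1 = by_node(hubs_1)
    cond2 = by_node(hubs_2)
    deltas = []
    for node in sorted(set(cond1) | set(cond2)):
        genes1 = cond1.get(node, frozenset())
        genes2 = cond2.get(node, frozenset())
        category = classify_hub_change(len(genes1), len(genes2))
        aggregated = separated = frozenset()
        if category in ("EDH", "PDH"):
            aggregated = frozenset(genes1 & genes2)
            separated = frozenset(genes1 - genes2)
        deltas.append(
            HubDelta(
                node_gene=node,
                n_c=len(genes1),
                n_m=len(genes2),
                category=category,
                aggregated=aggregated,
                separated=separated,
            )
        )
    return deltas
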