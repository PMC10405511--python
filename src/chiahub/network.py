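"""Anchor-gene assignment and seed-gene chromatin connectivity networks.

An anchor is assigned to a gene when at least half of the anchor's length
lies inside the gene's association window (1 kb upstream of the TSS through
the TTS). For active-mark anchors overlapping several genes, the gene with
the highest FPKM wins; for H3K27me3 anchors all candidate genes are kept.
Networks expand from seed genes by one or two hops of loop-mediated
gene-gene edges and label every node active / repressive / mixed from the
marks of its incident edges.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .intervals import (
    ACTIVE_MARKS,
    ExpressionTable,
    Gene,
    GenomicInterval,
    Loop,
    gene_region,
    overlap_bp,
)

__all__ = ["GeneAssigner", "assign_anchor_gene", "build_network", "network_summary"]


class GeneAssigner:
    """Assigns genes to anchors by the >= 50%-of-anchor overlap rule."""

    def __init__(
        self,
        genes: Sequence[Gene],
        expression: Optional[ExpressionTable] = None,
        upstream: int = 1000,
        min_fraction: float = 0.5,
        tissue: Optional[str] = None,
        chrom_sizes: Optional[Mapping[str, int]] = None,
    ) -> None:
        self.min_fraction = min_fraction
        self.expression = expression
        # default tie-break column: the first tissue (seedling by convention)
        if tissue is None and expression is not None:
            tissue = expression.tissues[0]
        self.tissue = tissue
        self.regions: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        for g in genes:
            region = gene_region(g, upstream=upstream, chrom_sizes=chrom_sizes)
            self.regions[g.chrom].append((region.start, region.end, g.gene_id))
        self._max_len: dict[str, int] = {}
        for chrom in self.regions:
            self.regions[chrom].sort()
            self._max_len[chrom] = max(e - s for s, e, _ in self.regions[chrom])

    def _fpkm(self, gene_id: str) -> float:
        if self.expression is None:
            return 0.0
        return self.expression.fpkm(gene_id, self.tissue)

    def candidates(self, anchor: GenomicInterval) -> list[tuple[str, int]]:
        """(gene_id, overlap_bp) for genes covering >= min_fraction of the
        anchor's length."""
        import bisect

        out = []
        need = self.min_fraction * anchor.length
        regions = self.regions.get(anchor.chrom, [])
        if not regions:
            return out
        lo = bisect.bisect_left(
            regions, (anchor.start - self._max_len[anchor.chrom], -1, "")
        )
        for s, e, gid in regions[lo:]:
            if s >= anchor.end:
                break
            ov = min(e, anchor.end) - max(s, anchor.start)
            if ov >= need and ov > 0:
                out.append((gid, ov))
        return out

    def assign(self, anchor: GenomicInterval, mark_category: str = "active") -> list[str]:
        """Anchor genes for one anchor.

        ``mark_category`` "active": the single best candidate (highest FPKM,
        ties broken by longer overlap then lexicographic gene id).
        "repressive" (H3K27me3): all candidates.
        """
        cands = self.candidates(anchor)
        if not cands:
            return []
        if mark_category == "repressive":
            return sorted(gid for gid, _ in cands)
        # highest FPKM; ties -> longer overlap -> lexicographically first id
        best = min(cands, key=lambda c: (-self._fpkm(c[0]), -c[1], c[0]))
        return [best[0]]


def assign_anchor_gene(
    anchor: GenomicInterval,
    genes: Sequence[Gene],
    expression: Optional[ExpressionTable] = None,
    mark_category: str = "active",
    **kwargs,
) -> list[str]:
    """One-shot convenience wrapper around :class:`GeneAssigner`."""
    return GeneAssigner(genes, expression, **kwargs).assign(anchor, mark_category)


def _mark_category(mark: str) -> str:
    return "active" if mark in ACTIVE_MARKS else "repressive"


def build_network(
    seed_genes: Sequence[str],
    loops_by_mark: Mapping[str, Sequence[Loop]],
    genes: Sequence[Gene],
    expression: Optional[ExpressionTable] = None,
    hops: int = 1,
) -> nx.MultiGraph:
    """Build a seed-gene connectivity network.

    Hop 1 keeps loops with at least one anchor assigned to a seed gene;
    hop 2 additionally keeps loops touching any gene reached at hop 1.
    Nodes carry ``role`` (seed / connecting) and ``category`` (active /
    repressive / mixed, from the marks of incident edges); edges carry
    ``mark`` and ``loop_id``.
    """
    if hops not in (1, 2):
        raise ValueError("hops must be 1 or 2")
    if not seed_genes:
        raise ValueError("seed gene list is empty")
    known = {g.gene_id for g in genes}
    seeds = []
    for s in seed_genes:
        if s not in known:
            warnings.warn(f"unknown seed gene {s!r}; skipped", RuntimeWarning)
        else:
            seeds.append(s)
    assigner = GeneAssigner(genes, expression)
    # pre-assign both anchors of every loop
    loop_pairs = []  # (loop_id, mark, genes_a, genes_b)
    for mark, loops in loops_by_mark.items():
        cat = _mark_category(mark)
        for i, lp in enumerate(loops):
            lid = lp.loop_id or f"{mark}_loop_{i}"
            ga = assigner.assign(lp.anchor_a, cat)
            gb = assigner.assign(lp.anchor_b, cat)
            if ga and gb:
                loop_pairs.append((lid, mark, ga, gb))

    graph = nx.MultiGraph()
    frontier = set(seeds)
    used: set[str] = set()
    for _hop in range(hops):
        reached = set()
        for lid, mark, ga, gb in loop_pairs:
            if lid in used:
                continue
            if frontier & set(ga) or frontier & set(gb):
                used.add(lid)
                for a in ga:
                    for b in gb:
                        if a != b:
                            graph.add_edge(a, b, mark=mark, loop_id=lid)
                            reached.update((a, b))
        frontier = frontier | reached
    for node in graph.nodes:
        graph.nodes[node]["role"] = "seed" if node in set(seeds) else "connecting"
        marks = {data["mark"] for _, _, data in graph.edges(node, data=True)}
        has_active = bool(marks & set(ACTIVE_MARKS))
        has_rep = bool(marks - set(ACTIVE_MARKS))
        category = "mixed" if has_active and has_rep else ("active" if has_active else "repressive")
        graph.nodes[node]["category"] = category
    graph.graph["hops"] = hops
    graph.graph["seeds"] = sorted(set(seeds))
    return graph


def network_summary(graph: nx.MultiGraph) -> dict:
    """Per-category seed counts, component sizes, and a node table."""
    seed_counts = {"active": 0, "repressive": 0, "mixed": 0}
    for node, data in graph.nodes(data=True):
        if data.get("role") == "seed":
            seed_counts[data["category"]] += 1
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=len, reverse=True
    )
    rows = [
        {
            "gene_id": node,
            "role": data["role"],
            "category": data["category"],
            "component": next(i for i, c in enumerate(components) if node in c),
        }
        for node, data in sorted(graph.nodes(data=True))
    ]
    return {
        "seed_counts": seed_counts,
        "component_sizes": [len(c) for c in components],
        "nodes": rows,
        "n_edges": graph.number_of_edges(),
    }


def write_edge_list(graph: nx.MultiGraph, path) -> None:
    """Edge-list TSV export (source, target, mark, loop_id), sorted for
    byte-identical output under identical inputs."""
    rows = sorted(
        (min(u, v), max(u, v), d["mark"], d["loop_id"])
        for u, v, d in graph.edges(data=True)
    )
    with open(path, "w") as fh:
        fh.write("source\ttarget\tmark\tloop_id\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
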