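"""Hub detection, enrichment statistics and differential classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chiahub.hubs import (
    classify_hub_change,
    compare_conditions,
    detect_hubs,
    hub_enrichment,
    random_hub_control,
    Hub,
)
from chiahub.intervals import Gene, GenomicInterval, Loop


def gi(c, s, e):
    return GenomicInterval(c, s, e)


def star_loops(center, leaves, mark="H3K4me3"):
    return [Loop(center, leaf, mark) for leaf in leaves]


def brute_force_label(n_c: int, n_m: int) -> str:
    """Literal re-coding of the three printed hub-change formulas, read as
    conjunctions and evaluated EDH -> PDH -> FH -> stable."""
    n_s = n_c - n_m
    edh = n_c > 0 and (n_s / n_c >= 0.7) and (n_s >= 3)
    pdh = n_c > 0 and (n_s / n_c >= 0.3) and (n_s / n_c < 0.7) and (n_s >= 3)
    fh = n_m > 0 and ((-n_s) / n_m >= 0.3) and (n_c - n_m <= -3)
    if edh:
        return "EDH"
    if pdh:
        return "PDH"
    if fh:
        return "FH"
    return "stable"


class TestClassifyHubChange:
    @pytest.mark.parametrize(
        "n_c,n_m,expected",
        [
            (10, 2, "EDH"),  # Ns=8, ratio 0.8
            (10, 7, "PDH"),  # ratio exactly 0.3, inclusive
            (4, 2, "stable"),  # Ns=2 < 3 despite ratio 0.5
            (5, 10, "FH"),  # Ns=-5, 0.5 >= 0.3 and -5 <= -3
            (7, 7, "stable"),
            (5, 0, "EDH"),  # hub vanished entirely
            (0, 5, "FH"),  # hub newly formed
            (0, 2, "stable"),  # too small a gain for FH
            (10, 3, "EDH"),  # ratio exactly 0.7, inclusive
        ],
    )
    def test_printed_formula_examples(self, n_c, n_m, expected):
        assert classify_hub_change(n_c, n_m) == expected

    def test_both_zero_is_error(self):
        with pytest.raises(ValueError):
            classify_hub_change(0, 0)

    @given(n_c=st.integers(0, 50), n_m=st.integers(0, 50))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_on_grid_samples(self, n_c, n_m):
        if n_c == 0 and n_m == 0:
            return
        assert classify_hub_change(n_c, n_m) == brute_force_label(n_c, n_m)


GENES = [
    Gene(f"g{i}", gi("chr1", 100_000 * (i + 1), 100_000 * (i + 1) + 5000), "+")
    for i in range(12)
]
PROMS = {g.gene_id: gi("chr1", g.tss - 1000, g.tss + 500) for g in GENES}


class TestDetectHubs:
    def test_degree_threshold_boundary(self):
        center = PROMS["g0"]
        five = star_loops(center, [PROMS[f"g{i}"] for i in range(1, 6)])
        four = five[:4]
        assert len(detect_hubs(five, GENES)) == 1
        assert detect_hubs(five, GENES)[0].degree == 5
        assert detect_hubs(four, GENES) == []

    def test_hub_node_and_connecting_genes(self):
        loops = star_loops(PROMS["g0"], [PROMS[f"g{i}"] for i in range(1, 7)])
        (hub,) = detect_hubs(loops, GENES)
        assert hub.node_gene == "g0"
        assert hub.connecting_genes == frozenset(f"g{i}" for i in range(1, 7))

    def test_overlapping_anchors_merge_then_count(self):
        # two center anchors overlapping each other, 3 loops each -> one
        # merged node of degree 6
        c1 = gi("chr1", 99_500, 100_600)
        c2 = gi("chr1", 100_400, 101_500)
        loops = star_loops(c1, [PROMS[f"g{i}"] for i in range(1, 4)]) + star_loops(
            c2, [PROMS[f"g{i}"] for i in range(4, 7)]
        )
        hubs = detect_hubs(loops, GENES, min_degree=5)
        assert len(hubs) == 1 and hubs[0].degree == 6

    def test_min_degree_validation(self):
        with pytest.raises(ValueError):
            detect_hubs([], GENES, min_degree=0)


class TestHubEnrichment:
    def test_example_matches_hypergeometric_tail(self):
        universe = [f"u{i}" for i in range(1000)]
        targets = universe[:100]
        hub = universe[:5] + universe[500:505]  # 5 of 10 are targets
        res = hub_enrichment(hub, targets, universe)
        # P(X >= 5) for X ~ Hypergeom(N=1000, K=100, n=10)
        expected = sum(
            math.comb(100, k) * math.comb(900, 10 - k) / math.comb(1000, 10)
            for k in range(5, 11)
        )
        assert res.p_value == pytest.approx(expected, abs=1e-12)
        assert res.enriched

    def test_targets_equal_universe_gives_p_one(self):
        universe = [f"u{i}" for i in range(50)]
        res = hub_enrichment(universe[:10], universe, universe)
        assert res.p_value == pytest.approx(1.0)
        assert not res.enriched

    def test_zero_targets_in_hub_gives_p_one(self):
        universe = [f"u{i}" for i in range(100)]
        res = hub_enrichment(universe[:10], universe[90:], universe)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            hub_enrichment(["a"], ["a"], [])


def make_hub(hub_id, node, genes):
    return Hub(
        hub_id=hub_id,
        node_anchor=gi("chr1", 0, 1000),
        node_gene=node,
        degree=len(genes),
        connecting_genes=frozenset(genes),
        member_loops=tuple(f"l{i}" for i in range(len(genes))),
    )


class TestRandomHubControl:
    POOL = [f"a{i}" for i in range(200)]

    def test_no_targets_all_zero(self):
        hubs = [make_hub("h0", "a0", self.POOL[1:8])]
        counts = random_hub_control(hubs, self.POOL, [], n_rounds=5, seed=0)
        assert counts == [0, 0, 0, 0, 0]

    def test_pool_equals_targets_counts_hub_sizes(self):
        hubs = [make_hub("h0", "a0", self.POOL[1:8])]
        counts = random_hub_control(hubs, self.POOL, self.POOL, n_rounds=3, seed=0)
        # every sampled gene is a target, but p = 1 so no hub screens in
        assert counts == [0, 0, 0]

    def test_n_rounds_validation(self):
        with pytest.raises(ValueError):
            random_hub_control([], self.POOL, [], n_rounds=0, seed=0)

    def test_planted_clustering_beats_control(self, small_ds):
        ds = small_ds
        hubs = detect_hubs(ds.condition_pair.loops_cond1, ds.genes, ds.expression)
        targets = set(ds.truth.tf_targets.gene_id)
        pool = sorted(
            {g for h in hubs for g in h.connecting_genes}
            | {h.node_gene for h in hubs if h.node_gene}
        )
        observed = 0
        for hub in hubs:
            genes = hub.connecting_genes | ({hub.node_gene} if hub.node_gene else set())
            res = hub_enrichment(genes, targets, pool)
            if res.enriched:
                observed += len(set(genes) & targets)
        control = random_hub_control(hubs, pool, targets, n_rounds=40, seed=1)
        assert observed > np.percentile(control, 97.5)


class TestCompareConditions:
    def test_identical_hub_sets_all_stable(self):
        hubs = [make_hub("h0", "g0", [f"g{i}" for i in range(1, 7)])]
        deltas = compare_conditions(hubs, hubs)
        assert [d.category for d in deltas] == ["stable"]
        assert deltas[0].separated == frozenset()

    def test_hub_only_in_condition_one_is_edh_all_separated(self):
        hub = make_hub("h0", "g0", [f"g{i}" for i in range(1, 6)])
        (delta,) = compare_conditions([hub], [])
        assert delta.category == "EDH" and delta.n_c == 5 and delta.n_m == 0
        assert delta.separated == hub.connecting_genes

    def test_partition_covers_condition1_genes(self):
        h1 = make_hub("h0", "g0", [f"g{i}" for i in range(1, 11)])
        h2 = make_hub("h0", "g0", [f"g{i}" for i in range(1, 5)])  # lost 6 of 10
        (delta,) = compare_conditions([h1], [h2])
        assert delta.category == "PDH"
        assert delta.aggregated | delta.separated == h1.connecting_genes
        assert delta.aggregated & delta.separated == frozenset()

    def test_duplicate_node_gene_merges_with_warning(self):
        a = make_hub("h0", "g0", ["g1", "g2", "g3"])
        b = make_hub("h1", "g0", ["g4", "g5", "g6"])
        with pytest.warns(RuntimeWarning, match="duplicate node gene"):
            deltas = compare_conditions([a, b], [a, b])
        assert len(deltas) == 1 and deltas[0].n_c == 6

    def test_planted_labels_recovered(self, small_ds):
        ds = small_ds
        h1 = detect_hubs(ds.condition_pair.loops_cond1, ds.genes, ds.expression)
        h2 = detect_hubs(ds.condition_pair.loops_cond2, ds.genes, ds.expression)
        deltas = {d.node_gene: d for d in compare_conditions(h1, h2)}
        for row in ds.condition_pair.hub_truth.itertuples():
            assert deltas[row.node_gene].category == row.label
            if row.label in ("EDH", "PDH"):
                want_sep = set(row.separated.split(",")) if row.separated else set()
                assert set(deltas[row.node_gene].separated) == want_sep
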