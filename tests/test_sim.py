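"""Synthetic-data generator: determinism, validity, planted structure."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from chiahub import io as chio
from chiahub.intervals import overlap_bp
from chiahub.sim import (
    SimConfig,
    generate_dataset,
    generate_expression,
    generate_genome,
    write_dataset,
)


class TestConfigValidation:
    def test_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            SimConfig(hub_disassembly_fractions=(0.6, 0.5, 0.2))
        with pytest.raises(ValueError):
            SimConfig(centromere_span=(0.7, 0.3))
        with pytest.raises(ValueError):
            SimConfig(category_mix={"H3K4me3": {"PP": 0.5, "PI": 0.2}})

    def test_rejects_unrepresentable_pcc(self, small_cfg):
        cfg = replace(small_cfg, planted_pair_pcc=1.5)
        sizes, genes = generate_genome(cfg)
        with pytest.raises(ValueError):
            from chiahub.sim import generate_peaks_and_loops

            _, _, truth = generate_peaks_and_loops(cfg, sizes, genes)
            generate_expression(cfg, genes, truth)


class TestGenome:
    def test_genes_non_overlapping_and_off_centromere(self, small_ds):
        cfg = small_ds.config
        cen0 = cfg.chrom_length * cfg.centromere_span[0]
        cen1 = cfg.chrom_length * cfg.centromere_span[1]
        by_chrom = {}
        for g in small_ds.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
            assert g.interval.end <= cen0 or g.interval.start >= cen1
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.interval.start)
            for a, b in zip(genes[:-1], genes[1:]):
                assert overlap_bp(a.interval, b.interval) == 0

    def test_same_seed_identical_gff3_bytes(self, tmp_path, small_cfg):
        paths = []
        for run in ("a", "b"):
            _, genes = generate_genome(small_cfg)
            p = tmp_path / f"{run}.gff3"
            chio.write_gff3(genes, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError, match="cannot fit"):
            generate_genome(SimConfig(n_genes=50_000))


class TestDeterminismAndValidity:
    def test_full_dataset_byte_identical(self, tmp_path, small_cfg):
        hashes = []
        for run in ("a", "b"):
            ds = generate_dataset(small_cfg)
            outdir = tmp_path / run
            files = write_dataset(ds, outdir)
            hashes.append({f.name: f.read_bytes() for f in files})
        assert hashes[0] == hashes[1]

    def test_emitted_files_pass_validators(self, tmp_path, small_ds):
        files = write_dataset(small_ds, tmp_path)
        sizes = chio.read_chrom_sizes(tmp_path / "genome.chrom.sizes")
        genes = chio.read_gff3(tmp_path / "genes.gff3", chrom_sizes=sizes)
        assert len(genes) == small_ds.config.n_genes
        for mark in small_ds.loops:
            if mark == "ATAC":
                continue
            loops = chio.read_bedpe(
                tmp_path / f"loops_{mark}.bedpe", mark=mark, chrom_sizes=sizes
            )
            assert len(loops) == len(small_ds.loops[mark])
        peaks = chio.read_bed(
            tmp_path / "peaks_H3K4me3.narrowPeak", mark="H3K4me3", chrom_sizes=sizes
        )
        assert len(peaks) == len(small_ds.peaks["H3K4me3"])
        expr = chio.read_expression(tmp_path / "expression.tsv")
        assert expr.genes == [g.gene_id for g in genes]


class TestPlantedStructure:
    def test_background_category_mix_exact(self, small_ds):
        truth = small_ds.truth.loops
        cfg = small_ds.config
        for mark, mix in cfg.category_mix.items():
            bg = truth[(truth["mark"] == mark) & (truth.origin == "background")]
            total = cfg.loop_counts[mark]
            if len(bg) < total:
                continue  # placement shortfalls allowed only via attempts cap
            for cat, frac in mix.items():
                want = round(total * frac) if frac * total == int(frac * total) else None
                got = (bg.category == cat).sum()
                assert abs(got - total * frac) <= 1  # largest-remainder rounding

    def test_h3k9me2_loops_pericentromeric(self, small_ds):
        cfg = small_ds.config
        cen0 = cfg.chrom_length * cfg.centromere_span[0]
        cen1 = cfg.chrom_length * cfg.centromere_span[1]
        for lp in small_ds.loops["H3K9me2"]:
            for anchor in (lp.anchor_a, lp.anchor_b):
                assert cen0 <= anchor.start and anchor.end <= cen1

    def test_h3k9me2_span_median_near_config(self, default_ds):
        law = default_ds.config.span_distributions["H3K9me2"]
        spans = default_ds.truth.loops.query("mark == 'H3K9me2'").span_bp
        assert len(spans) == default_ds.config.loop_counts["H3K9me2"]
        assert np.median(spans) == pytest.approx(law[1], rel=0.15)

    def test_null_pcc_pairs_uncorrelated(self, small_cfg):
        cfg = replace(small_cfg, planted_pair_pcc=0.0)
        ds = generate_dataset(cfg)
        from chiahub.coexpr import mean_pair_pcc

        pairs = list(ds.truth.pairs[["gene_a", "gene_b"]].itertuples(index=False, name=None))
        mean, _, _ = mean_pair_pcc(pairs, ds.expression)
        # ~60 pairs x 12 tissues: sampling error ~ 1/sqrt(60*11) ~ 0.04
        assert abs(mean) < 0.15

    def test_boost_one_means_no_shift(self, small_cfg):
        cfg = replace(small_cfg, anchor_expression_boost=1.0, seed=19)
        ds = generate_dataset(cfg)
        from chiahub.coexpr import group_rank_test

        roles = ds.truth.gene_roles
        anchors = roles[roles.boosted & ~roles.cre_boosted].gene_id.tolist()
        basal = roles[
            (~roles.boosted) & (~roles.cre_boosted)
            & roles.role.isin(["active_pool", "basal"])
        ].gene_id.tolist()
        a = [ds.expression.fpkm(g, "seedling") for g in anchors]
        b = [ds.expression.fpkm(g, "seedling") for g in basal]
        _, p = group_rank_test(a, b, "two-sided")
        assert p > 0.001  # no planted effect -> no extreme significance

    def test_planted_boost_recovered_in_median_ratio(self, default_ds):
        ds = default_ds
        roles = ds.truth.gene_roles
        anchors = roles[roles.boosted & ~roles.cre_boosted].gene_id.tolist()
        basal = roles[
            (~roles.boosted) & (~roles.cre_boosted)
            & roles.role.isin(["active_pool", "basal"])
        ].gene_id.tolist()
        med = lambda ids: np.median(
            [np.median(ds.expression.fpkm(g)) for g in ids]
        )
        ratio = med(anchors) / med(basal)
        assert ratio == pytest.approx(ds.config.anchor_expression_boost, rel=0.25)

    def test_condition_pair_zero_fractions_identical(self, small_cfg):
        cfg = replace(small_cfg, hub_disassembly_fractions=(0.0, 0.0, 0.0))
        ds = generate_dataset(cfg)
        assert ds.condition_pair.loops_cond1 == ds.condition_pair.loops_cond2
        assert (ds.condition_pair.hub_truth.label == "stable").all()

    def test_planted_hub_counts_match_fractions(self, small_ds):
        cfg = small_ds.config
        ht = small_ds.condition_pair.hub_truth
        f_edh, f_pdh, f_fh = cfg.hub_disassembly_fractions
        assert (ht.label == "EDH").sum() == round(cfg.n_hubs * f_edh)
        assert (ht.label == "PDH").sum() == round(cfg.n_hubs * f_pdh)
        assert (ht.label == "FH").sum() == round(cfg.n_hubs * f_fh)
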