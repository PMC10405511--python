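"""Contact matrices: binning, ICE balancing, compartments, ACA, domains."""

import numpy as np
import pytest

from chiahub.contacts import (
    ContactMatrix,
    aggregate_chromosome_analysis,
    bin_contacts,
    call_compartments,
    gene_density_track,
    ice_balance,
    observed_expected,
    segment_domains,
)
from chiahub.intervals import Gene, GenomicInterval, Loop


def gi(c, s, e):
    return GenomicInterval(c, s, e)


def make_loop(c, pos_a, pos_b, pet=1, mark="H3K4me3"):
    return Loop(gi(c, pos_a, pos_a + 1000), gi(c, pos_b, pos_b + 1000), mark, pet_count=pet)


SIZES = {"chr1": 1_000_000}


class TestBinContacts:
    def test_single_loop_symmetric_increment(self):
        # anchors with midpoints in bins 3 and 7 at 100 kb resolution
        loop = make_loop("chr1", 350_000, 750_000, pet=4)
        cm = bin_contacts([loop], SIZES, 100_000)["chr1"]
        assert cm.matrix[3, 7] == 4 and cm.matrix[7, 3] == 4
        assert cm.bin_mask[3] and cm.bin_mask[7] and not cm.bin_mask[0]

    def test_empty_input_all_masked(self):
        cm = bin_contacts([], SIZES, 100_000)["chr1"]
        assert cm.matrix.sum() == 0 and not cm.bin_mask.any()

    def test_total_mass_matches_hand_count(self):
        rng = np.random.default_rng(5)
        loops = []
        hand_total = 0
        for _ in range(20):
            a = int(rng.integers(0, 400_000))
            b = a + 10_000 + int(rng.integers(0, 500_000))
            pet = int(rng.integers(1, 10))
            loops.append(make_loop("chr1", a, b, pet=pet))
            same_bin = (a + 500) // 50_000 == (b + 500) // 50_000
            hand_total += pet if same_bin else 2 * pet
        cm = bin_contacts(loops, SIZES, 50_000)["chr1"]
        assert cm.matrix.sum() == hand_total

    def test_resolution_larger_than_chromosome(self):
        cm = bin_contacts([], {"chr1": 5000}, 100_000)["chr1"]
        assert cm.n_bins == 1


class TestIceBalance:
    def test_constant_matrix_unchanged_up_to_scale(self):
        m = np.full((10, 10), 3.0)
        cm = ContactMatrix("chr1", 1000, m, np.ones(10, bool))
        balanced, bias, converged = ice_balance(cm)
        assert converged
        ratio = balanced.matrix / balanced.matrix[0, 0]
        assert np.allclose(ratio, 1.0)
        assert np.allclose(bias, bias[0])

    def test_marginals_equalize(self):
        # diagonally dominant 3x3 with unequal marginals
        m = np.array([[1.0, 0.5, 0.2], [0.5, 2.0, 0.6], [0.2, 0.6, 4.0]])
        cm = ContactMatrix("chr1", 1000, m, np.ones(3, bool))
        balanced, bias, converged = ice_balance(cm, tol=1e-6, max_iter=500)
        marg = balanced.matrix.sum(axis=1)
        assert converged and marg.std() / marg.mean() < 1e-6
        assert np.allclose(np.outer(bias, bias) * balanced.matrix, m, rtol=1e-8)

    def test_zero_row_masked_remainder_balanced(self):
        m = np.array([[1.0, 0.5, 0.0], [0.5, 2.0, 0.0], [0.0, 0.0, 0.0]])
        cm = ContactMatrix("chr1", 1000, m, m.sum(1) > 0)
        balanced, bias, _ = ice_balance(cm, tol=1e-6, max_iter=500)
        assert np.isnan(bias[2])
        assert balanced.matrix[2].sum() == 0
        marg = balanced.matrix.sum(1)[:2]
        assert marg.std() / marg.mean() < 1e-6

    def test_all_masked_is_error(self):
        cm = ContactMatrix("chr1", 1000, np.zeros((4, 4)), np.zeros(4, bool))
        with pytest.raises(ValueError):
            ice_balance(cm)


class TestObservedExpected:
    def test_distance_strata_mean_one(self):
        rng = np.random.default_rng(6)
        m = rng.uniform(0.5, 2.0, (30, 30))
        m = (m + m.T) / 2
        cm = ContactMatrix("chr1", 1000, m, np.ones(30, bool))
        oe = observed_expected(cm)
        n = 30
        dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        for d in range(n):
            sel = dist == d
            assert abs(oe[sel].mean() - 1.0) < 1e-9


def checkerboard(n=200, block=20, enrich=5.0):
    labels = (np.arange(n) // block) % 2
    m = np.where(labels[:, None] == labels[None, :], enrich, 1.0)
    return m, labels


class TestCompartments:
    def test_two_block_checkerboard_recovered(self):
        m, labels = checkerboard()
        cm = ContactMatrix("chr1", 100_000, m, np.ones(len(m), bool))
        track = np.where(labels == 0, 5.0, 0.5)
        call = call_compartments(cm, track)
        want = np.where(labels == 0, "A", "B")
        assert (call.labels == want).all()

    def test_orientation_follows_track(self):
        m, labels = checkerboard()
        cm = ContactMatrix("chr1", 100_000, m, np.ones(len(m), bool))
        call_fwd = call_compartments(cm, np.where(labels == 0, 5.0, 0.5))
        call_rev = call_compartments(cm, np.where(labels == 0, 0.5, 5.0))
        # inverting the track flips every label
        flipped = np.where(call_fwd.labels == "A", "B", "A")
        assert (call_rev.labels == flipped).all()

    def test_too_few_bins_is_error(self):
        m = np.ones((5, 5))
        cm = ContactMatrix("chr1", 1000, m, np.ones(5, bool))
        with pytest.raises(ValueError, match="retained bins"):
            call_compartments(cm, np.ones(5))

    def test_gene_density_track(self):
        genes = [Gene("g1", gi("chr1", 150_000, 160_000), "+")]
        track = gene_density_track(genes, "chr1", 10, 100_000)
        assert track[1] == 1 and track.sum() == 1


class TestACA:
    def test_grid_sized_input_is_identity(self):
        m, _ = checkerboard(n=50, block=10)
        cm = ContactMatrix("chr1", 1000, m, np.ones(50, bool))
        assert np.allclose(aggregate_chromosome_analysis([cm], grid=50), m)

    def test_two_identical_chromosomes_double(self):
        m, _ = checkerboard(n=60, block=10)
        cm = ContactMatrix("chr1", 1000, m, np.ones(60, bool))
        one = aggregate_chromosome_analysis([cm], grid=20)
        two = aggregate_chromosome_analysis([cm, cm], grid=20)
        assert np.allclose(two, 2 * one)

    def test_mass_conservation(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(0, 1, (37, 37))
        m = (m + m.T) / 2
        cm = ContactMatrix("chr1", 1000, m, np.ones(37, bool))
        grid = 10
        aca = aggregate_chromosome_analysis([cm], grid=grid)
        assign = (np.arange(37) * grid) // 37
        sizes = np.bincount(assign, minlength=grid).astype(float)
        weights = np.outer(sizes, sizes)
        assert np.average(aca, weights=weights) == pytest.approx(m.mean())

    def test_chromosome_order_invariance(self):
        rng = np.random.default_rng(8)
        mats = []
        for n in (31, 47):
            m = rng.uniform(0, 1, (n, n))
            mats.append(ContactMatrix("c", 1000, (m + m.T) / 2, np.ones(n, bool)))
        assert np.allclose(
            aggregate_chromosome_analysis(mats, grid=10),
            aggregate_chromosome_analysis(mats[::-1], grid=10),
        )

    def test_small_grid_is_error(self):
        with pytest.raises(ValueError):
            aggregate_chromosome_analysis([], grid=1)


class TestSegmentDomains:
    SIZES = {"chr1": 200_000}

    def test_only_active_loops_give_aid_and_gap(self):
        loops = {"H3K4me3": [make_loop("chr1", 20_000, 80_000)]}
        segments, _ = segment_domains(loops, self.SIZES, bin_size=10_000)
        assert {s.label for s in segments} == {"AID", "gap"}

    def test_bin_with_two_groups_is_mid(self):
        loops = {
            "H3K4me3": [make_loop("chr1", 20_000, 80_000)],
            "H3K27me3": [make_loop("chr1", 21_000, 120_000, mark="H3K27me3")],
        }
        segments, _ = segment_domains(loops, self.SIZES, bin_size=10_000, gap_tolerance_bins=0)
        by_label = {s.label for s in segments}
        assert "MID" in by_label
        mid = [s for s in segments if s.label == "MID"]
        assert any(s.interval.start == 20_000 for s in mid)

    def test_segments_tile_chromosome(self):
        loops = {
            "H3K4me3": [make_loop("chr1", 20_000, 80_000)],
            "H3K9me2": [make_loop("chr1", 150_000, 180_000, mark="H3K9me2")],
        }
        segments, summary = segment_domains(loops, self.SIZES, bin_size=10_000)
        segs = sorted(segments, key=lambda s: s.interval.start)
        assert segs[0].interval.start == 0
        assert segs[-1].interval.end == self.SIZES["chr1"]
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.interval.end == b.interval.start
        assert summary.bp.sum() == self.SIZES["chr1"]

    def test_gap_tolerance_merges_short_gaps(self):
        loops = {"H3K4me3": [make_loop("chr1", 0, 20_000)]}
        # anchors cover bins 0 and 2; bin 1 is a 1-bin gap
        merged, _ = segment_domains(loops, self.SIZES, bin_size=10_000, gap_tolerance_bins=1)
        strict, _ = segment_domains(loops, self.SIZES, bin_size=10_000, gap_tolerance_bins=0)
        aid_merged = [s for s in merged if s.label == "AID"]
        aid_strict = [s for s in strict if s.label == "AID"]
        assert len(aid_merged) == 1 and len(aid_strict) == 2

    def test_planted_layout_recovered(self, small_ds):
        cfg = small_ds.config
        segments, _ = segment_domains(small_ds.loops, small_ds.chrom_sizes)
        cen0 = cfg.chrom_length * cfg.centromere_span[0]
        cen1 = cfg.chrom_length * cfg.centromere_span[1]
        for seg in segments:
            if seg.label == "HID":
                assert seg.interval.start >= cen0 - 10_000
                assert seg.interval.end <= cen1 + 10_000
            if seg.label in ("AID", "RID", "MID"):
                mid = seg.interval.midpoint
                assert not (cen0 + 10_000 < mid < cen1 - 10_000)
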