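import numpy as np
import pytest

import larvaprint as lp
from larvaprint.intervals import (
    read_bed,
    read_fragment_bed,
    read_gene_table,
    tss_from_span,
    write_bed,
    write_fragment_bed,
    write_gene_table,
)

GI = lp.GenomicInterval


class TestShiftReads:
    def test_plus_strand_offset_4(self):
        assert lp.shift_reads(GI("chr1", 100, 150, "+")) == GI("chr1", 104, 150, "+")

    def test_minus_strand_offset_minus_5(self):
        assert lp.shift_reads(GI("chr1", 100, 150, "-")) == GI("chr1", 100, 145, "-")

    def test_collapsed_read_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            lp.shift_reads(GI("chr1", 0, 3, "+"))
        with pytest.raises(ValueError, match="collapses"):
            lp.shift_reads(GI("chr1", 10, 14, "-"))

    def test_unstranded_read_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            lp.shift_reads(GI("chr1", 0, 10, "."))


class TestFilterFragments:
    def _frag(self, mapq, insert, name="f"):
        return lp.FragmentRecord(
            interval=GI("chr1", 1000, 1000 + insert), mapq=mapq, name=name
        )

    @pytest.mark.parametrize(
        "mapq,insert,kept,reason",
        [
            (35, 80, True, None),
            (30, 100, True, None),  # thresholds are inclusive on the keep side
            (20, 80, False, "low_mapq"),
            (35, 150, False, "insert_too_long"),
            (29, 101, False, "low_mapq"),  # fails both; counted once under mapq
        ],
    )
    def test_effective_fragment_rule(self, mapq, insert, kept, reason):
        frags, dropped = lp.filter_fragments([self._frag(mapq, insert)])
        assert bool(frags) is kept
        if reason:
            assert dropped[reason] == 1

    def test_order_preserved_and_idempotent(self):
        frags = [self._frag(40, 50, f"f{i}") for i in range(5)] + [self._frag(10, 50)]
        kept, _ = lp.filter_fragments(frags)
        assert [f.name for f in kept] == [f"f{i}" for i in range(5)]
        again, dropped = lp.filter_fragments(kept)
        assert again == kept and sum(dropped.values()) == 0


class TestRpmCoverage:
    def test_definition(self):
        frags = [
            lp.FragmentRecord(interval=GI("chr1", 0, 100), mapq=60) for _ in range(5)
        ]
        # pad the total to 10 fragments elsewhere
        frags += [
            lp.FragmentRecord(interval=GI("chr2", 0, 50), mapq=60) for _ in range(5)
        ]
        cov = lp.rpm_coverage(frags, [GI("chr1", 50, 51)])
        assert cov[0] == pytest.approx(5 * 1e6 / 10)

    def test_no_overlap_zero(self):
        frags = [lp.FragmentRecord(interval=GI("chr1", 0, 10), mapq=60)]
        assert lp.rpm_coverage(frags, [GI("chr1", 10, 11)]) == [0.0]

    def test_empty_fragments_rejected(self):
        with pytest.raises(ValueError):
            lp.rpm_coverage([], [GI("chr1", 0, 1)])

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(40)
        frags = [
            lp.FragmentRecord(
                interval=GI("chr1", int(s), int(s + rng.integers(1, 100))), mapq=60
            )
            for s in rng.integers(0, 5000, 200)
        ]
        queries = [GI("chr1", int(p), int(p) + 1) for p in rng.integers(0, 5000, 50)]
        cov = lp.rpm_coverage(frags, queries)
        for q, got in zip(queries, cov):
            brute = sum(1 for f in frags if f.interval.overlaps(q))
            assert got == pytest.approx(brute * 1e6 / len(frags))


class TestConditionSpecificPeaks:
    def test_high_in_a_absent_in_b(self):
        a_high = [GI("chr1", 100, 200)]
        spec_a, spec_b = lp.condition_specific_peaks(a_high, a_high, [], [])
        assert spec_a == a_high and spec_b == []

    def test_overlap_with_other_low_disqualifies(self):
        spec_a, _ = lp.condition_specific_peaks(
            [GI("chr1", 100, 200)], [], [], [GI("chr1", 150, 250)]
        )
        assert spec_a == []

    def test_half_open_abutment_is_not_overlap(self):
        spec_a, _ = lp.condition_specific_peaks(
            [GI("chr1", 100, 200)], [], [], [GI("chr1", 200, 300)]
        )
        assert spec_a == [GI("chr1", 100, 200)]

    def test_same_condition_both_sides_yields_nothing(self):
        high = [GI("chr1", 10, 20), GI("chr2", 5, 9)]
        low = high + [GI("chr1", 100, 120)]
        spec_a, spec_b = lp.condition_specific_peaks(high, low, high, low)
        assert spec_a == [] and spec_b == []

    def test_chromosomes_do_not_cross_talk(self):
        spec_a, _ = lp.condition_specific_peaks(
            [GI("chr1", 100, 200)], [], [], [GI("chr2", 100, 200)]
        )
        assert spec_a == [GI("chr1", 100, 200)]


class TestPromoterAssociation:
    def test_peak_in_flank_is_associated(self):
        genes = [lp.GeneAnnotation("g1", "chr1", 1000, "+")]
        hits = lp.promoter_association([GI("chr1", 1500, 1600)], genes)
        assert hits["g1"] == [GI("chr1", 1500, 1600)]

    def test_half_open_boundary_excluded(self):
        genes = [lp.GeneAnnotation("g1", "chr1", 1000, "+")]
        # promoter = [0, 2000); a peak starting at 2000 shares no base
        hits = lp.promoter_association([GI("chr1", 2000, 2100)], genes)
        assert hits["g1"] == []

    def test_flank_clipped_at_zero(self):
        genes = [lp.GeneAnnotation("g1", "chr1", 200, "+")]
        hits = lp.promoter_association([GI("chr1", 0, 10)], genes)
        assert hits["g1"] == [GI("chr1", 0, 10)]

    def test_matches_brute_force_overlap_oracle(self):
        rng = np.random.default_rng(41)
        peaks = [
            GI("chr1", int(s), int(s + rng.integers(50, 500)))
            for s in rng.integers(0, 100_000, 60)
        ]
        genes = [
            lp.GeneAnnotation(f"g{i}", "chr1", int(t), "+")
            for i, t in enumerate(rng.integers(0, 100_000, 40))
        ]
        hits = lp.promoter_association(peaks, genes, flank=1000)
        for g in genes:
            lo, hi = max(0, g.tss - 1000), g.tss + 1000
            brute = sorted(
                pk for pk in peaks if pk.start < hi and lo < pk.end
            )
            assert hits[g.gene] == brute

    @pytest.mark.parametrize("start,end,strand,tss", [(100, 200, "+", 100), (100, 200, "-", 199)])
    def test_tss_from_span(self, start, end, strand, tss):
        assert tss_from_span(start, end, strand) == tss


class TestBedRoundTrips:
    def test_bed3_round_trip(self, tmp_path):
        ivs = [GI("chr1", 0, 10), GI("chr2", 5, 500)]
        write_bed(ivs, tmp_path / "a.bed")
        assert read_bed(tmp_path / "a.bed") == ivs
        # byte-identical on re-write
        write_bed(read_bed(tmp_path / "a.bed"), tmp_path / "b.bed")
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()

    def test_fragment_bed_round_trip(self, tmp_path):
        frags = [
            lp.FragmentRecord(interval=GI("chr1", 0, 80, "+"), mapq=60, name="f1"),
            lp.FragmentRecord(interval=GI("chr1", 40, 90, "-"), mapq=12, name="f2"),
        ]
        write_fragment_bed(frags, tmp_path / "f.bed")
        assert read_fragment_bed(tmp_path / "f.bed") == frags

    def test_gene_table_round_trip(self, tmp_path):
        genes = [
            lp.GeneAnnotation("g1", "chr1", 1000, "+"),
            lp.GeneAnnotation("g2", "chr5", 0, "-"),
        ]
        write_gene_table(genes, tmp_path / "g.csv")
        assert read_gene_table(tmp_path / "g.csv") == genes

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GI("chr1", 10, 10)
        with pytest.raises(ValueError):
            GI("chr1", -1, 10)
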