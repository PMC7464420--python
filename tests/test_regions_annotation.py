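import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from greyscan import published
from greyscan.genotype_io import LocusInfo
from greyscan.multicohort import OccurrenceTable
from greyscan.regions_annotation import (
    AnnotationParseError,
    GeneRecord,
    GenomicWindow,
    delimited_interval,
    genes_in_regions,
    merge_windows,
    read_gene_annotation,
    report_table,
    snp_window,
)

from _oracles import merge_bitmap, overlaps_quadratic


class TestSnpWindow:
    def test_reported_interval_bounds(self):
        for chrom, snp_id, _, pos, (start, end), _ in published.REPORTED_OUTLIERS:
            w = snp_window(LocusInfo(chrom, snp_id, pos))
            assert (w.start_bp, w.end_bp) == (start, end)

    def test_clamped_at_chromosome_start(self):
        w = snp_window(LocusInfo("1", "s", 100_000), half_width=250_000)
        assert w.start_bp == 1 and w.end_bp == 350_000

    def test_zero_half_width_degenerate(self):
        w = snp_window(LocusInfo("1", "s", 42), half_width=0)
        assert (w.start_bp, w.end_bp) == (42, 42)

    def test_monotone_in_half_width(self):
        loc = LocusInfo("1", "s", 1_000_000)
        small = snp_window(loc, 100_000)
        big = snp_window(loc, 400_000)
        assert big.start_bp <= small.start_bp and big.end_bp >= small.end_bp


class TestMergeWindows:
    def test_overlapping_reported_windows_merge(self):
        w1 = GenomicWindow("14", 22_531_305, 23_031_305, ["BTB-01532239"])
        w2 = GenomicWindow("14", 22_617_321, 23_117_321, ["BTB-01530788"])
        merged = merge_windows([w1, w2])
        assert len(merged) == 1
        assert (merged[0].start_bp, merged[0].end_bp) == (22_531_305, 23_117_321)
        assert set(merged[0].source_snps) == {"BTB-01532239", "BTB-01530788"}

    def test_different_chromosomes_never_merge(self):
        w1 = GenomicWindow("1", 10, 20)
        w2 = GenomicWindow("2", 10, 20)
        assert len(merge_windows([w1, w2])) == 2

    def test_book_ended_windows_merge(self):
        merged = merge_windows([GenomicWindow("1", 1, 5), GenomicWindow("1", 6, 9)])
        assert len(merged) == 1 and merged[0].end_bp == 9

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 60), st.integers(0, 15)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_bitmap_oracle(self, intervals):
        windows = [GenomicWindow("7", s, e) for s, e in intervals]
        merged = merge_windows(windows)
        got = [(w.start_bp, w.end_bp) for w in merged]
        assert got == merge_bitmap(intervals, size=100)
        # non-overlapping and sorted
        for w1, w2 in zip(merged, merged[1:]):
            assert w1.end_bp + 1 < w2.start_bp


class TestDelimitedInterval:
    def test_bta14_markers_span(self):
        w = delimited_interval(published.bta14_loci())
        assert (w.start_bp, w.end_bp) == (22_781_305, 25_472_332)

    def test_identical_positions_zero_width(self):
        loci = [LocusInfo("1", "a", 50), LocusInfo("1", "b", 50)]
        w = delimited_interval(loci)
        assert w.start_bp == w.end_bp == 50

    def test_order_invariance(self):
        loci = published.bta14_loci()
        w1 = delimited_interval(loci)
        w2 = delimited_interval(list(reversed(loci)))
        assert (w1.start_bp, w1.end_bp) == (w2.start_bp, w2.end_bp)

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            delimited_interval([LocusInfo("1", "a", 5), LocusInfo("2", "b", 9)])


class TestReadGeneAnnotation:
    def test_bed_coordinate_conversion(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("14\t23300000\t23400000\tSDR16C5\n")
        (rec,) = read_gene_annotation(bed, format="bed")
        assert rec == GeneRecord("14", 23_300_001, 23_400_000, "SDR16C5")

    def test_gff3_round_trips_coordinates(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "14\t.\tgene\t23300001\t23400000\t.\t+\t.\tID=g1;Name=SDR16C5\n"
            "14\t.\tmRNA\t23300001\t23350000\t.\t+\t.\tID=t1;Parent=g1\n"
            "14\t.\texon\t23300001\t23300500\t.\t+\t.\tParent=t1\n"
        )
        recs = read_gene_annotation(gff)
        assert recs == [GeneRecord("14", 23_300_001, 23_400_000, "SDR16C5")]

    def test_malformed_line_reports_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("14\t100\t200\tOK\n14\tnot_an_int\t300\tBAD\n")
        with pytest.raises(AnnotationParseError, match=":2"):
            read_gene_annotation(bed, format="bed")


class TestGenesInRegions:
    def test_inside_straddling_outside(self):
        region = GenomicWindow("1", 1000, 2000)
        genes = [
            GeneRecord("1", 1200, 1300, "INSIDE"),
            GeneRecord("1", 1900, 2500, "STRADDLE"),
            GeneRecord("1", 2001, 2500, "OUTSIDE"),
            GeneRecord("2", 1200, 1300, "WRONG_CHROM"),
        ]
        (ann,) = genes_in_regions([region], genes)
        assert ann.genes == ["INSIDE", "STRADDLE"]

    def test_empty_annotation(self):
        (ann,) = genes_in_regions([GenomicWindow("1", 1, 10)], [])
        assert ann.genes == []

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_matches_quadratic_oracle(self, data):
        regions = [
            GenomicWindow("1", s, s + w)
            for s, w in data.draw(
                st.lists(st.tuples(st.integers(1, 80), st.integers(0, 30)), max_size=6)
            )
        ]
        genes = [
            GeneRecord("1", s, s + w, f"G{i}")
            for i, (s, w) in enumerate(
                data.draw(
                    st.lists(
                        st.tuples(st.integers(1, 80), st.integers(0, 30)), max_size=12
                    )
                )
            )
        ]
        got = [ann.genes for ann in genes_in_regions(regions, genes)]
        assert got == overlaps_quadratic(regions, genes)


class TestReportTable:
    def _published_occurrence(self):
        counts = np.array([row[2] for row in published.REPORTED_OUTLIERS])
        return OccurrenceTable(
            reference_breeds=published.REFERENCE_ORDER,
            snp_ids=[row[1] for row in published.REPORTED_OUTLIERS],
            counts=counts,
            total_contrasts=60,
        )

    def test_reproduces_reported_layout(self):
        occ = self._published_occurrence()
        loci_by_id = {l.snp_id: l for l in published.reported_loci()}
        regions = [
            GenomicWindow(row[0], row[4][0], row[4][1], [row[1]])
            for row in published.REPORTED_OUTLIERS
        ]
        annotated = genes_in_regions(
            regions,
            [
                GeneRecord(row[0], row[4][0] + 10, row[4][0] + 20, row[5][0])
                for row in published.REPORTED_OUTLIERS
            ],
        )
        text = report_table(occ, annotated, loci_by_id)
        lines = text.strip().split("\n")
        assert lines[0].split("\t") == [
            "CHR", "SNP ID", "ANGUS", "CHAROLAIS", "HOLSTEIN", "LIMOUSIN",
            "OVERALL", "POSITION", "CONSIDERED INTERVAL", "GENES",
        ]
        first = lines[1].split("\t")
        assert first[:2] == ["2", "Hapmap49624-BTA-47893"]
        assert first[6] == "15" and first[7] == "6760630"
        assert first[8] == "6510630-7010630"

    def test_empty_input_is_header_only(self):
        occ = OccurrenceTable(
            reference_breeds=["Angus"], snp_ids=[],
            counts=np.empty((0, 1), dtype=np.int64), total_contrasts=60,
        )
        text = report_table(occ, [], {})
        assert text.count("\n") == 1 and text.startswith("CHR\t")

    def test_round_trip_recovers_counts(self):
        occ = self._published_occurrence()
        loci_by_id = {l.snp_id: l for l in published.reported_loci()}
        regions = [
            GenomicWindow(row[0], row[4][0], row[4][1], [row[1]])
            for row in published.REPORTED_OUTLIERS
        ]
        text = report_table(occ, genes_in_regions(regions, []), loci_by_id)
        rows = [line.split("\t") for line in text.strip().split("\n")[1:]]
        parsed = {r[1]: int(r[6]) for r in rows}
        for row in published.REPORTED_OUTLIERS:
            assert parsed[row[1]] == sum(row[2])
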