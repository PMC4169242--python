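"""Coordinate model, interval algebra and BED/GFF3 round trips."""

import numpy as np
import pytest

from regloop.genomics_core import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    ParseError,
    PeakSet,
    ValidationError,
    basepair_overlap,
    directional_peak_overlap_counts,
    merge_interval_arrays,
    merge_intervals,
    read_bed,
    read_gff3,
    write_bed,
    write_gff3,
)
from conftest import mask_of, random_disjoint_intervals


class TestTypes:
    def test_genome_layout_rejects_duplicates_and_nonpositive_lengths(self):
        with pytest.raises(ValidationError):
            GenomeLayout([("chr1", 10), ("chr1", 20)])
        with pytest.raises(ValidationError):
            GenomeLayout([("chr1", 0)])

    def test_interval_invariants(self):
        with pytest.raises(ValidationError):
            GenomicInterval("c", 10, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("c", -1, 5)
        assert GenomicInterval("c", 2, 7).length == 5

    def test_peakset_requires_sorted_disjoint(self):
        good = PeakSet([GenomicInterval("c", 0, 5), GenomicInterval("c", 5, 9)])
        assert len(good) == 2 and good.total_bp == 9
        with pytest.raises(ValidationError):
            PeakSet([GenomicInterval("c", 0, 5), GenomicInterval("c", 4, 9)])
        with pytest.raises(ValidationError):
            PeakSet([GenomicInterval("c", 5, 9), GenomicInterval("c", 0, 4)])

    def test_gene_model_exon_invariants(self):
        span = GenomicInterval("c", 100, 200)
        with pytest.raises(ValidationError):
            GeneModel("g", span, "+", (GenomicInterval("c", 90, 150),))
        with pytest.raises(ValidationError):
            GeneModel(
                "g", span, "+",
                (GenomicInterval("c", 100, 160), GenomicInterval("c", 150, 200)),
            )


class TestBed:
    def test_read_single_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\t200\tpk1\t3.1\n")
        ps = read_bed(p)
        iv = ps.intervals[0]
        assert (iv.chrom, iv.start, iv.end, iv.name, iv.score) == ("chr2L", 100, 200, "pk1", 3.1)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_overlapping_lines_merged_with_warning(self, tmp_path, caplog):
        p = tmp_path / "o.bed"
        p.write_text("chr1\t0\t100\nchr1\t50\t150\n")
        with caplog.at_level("WARNING"):
            ps = read_bed(p)
        assert [(i.start, i.end) for i in ps] == [(0, 150)]
        assert any("merged" in r.message for r in caplog.records)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\tfoo\t200\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(p)

    def test_end_not_after_start_is_validation_error(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(ValidationError):
            read_bed(p)

    def test_round_trip_identity_random_sets(self, tmp_path):
        rng = np.random.default_rng(11)
        ivs = random_disjoint_intervals(rng, ["chr1", "chr2"], max_n=500, genome_len=100_000)
        ps = PeakSet(sorted(ivs, key=lambda i: (i.chrom, i.start)))
        path = tmp_path / "rt.bed"
        write_bed(ps, path)
        assert read_bed(path) == ps

    def test_write_empty(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_bed(PeakSet([]), path)
        assert path.read_text() == ""
        assert len(read_bed(path)) == 0


class TestGff3:
    def test_coordinate_conversion_and_exons(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\texon\t1\t40\t.\t+\t.\tID=g1.e1;Parent=g1\n"
            "chr1\tsrc\texon\t61\t100\t.\t+\t.\tID=g1.e2;Parent=g1\n"
        )
        genes = read_gff3(p)
        assert len(genes) == 1
        g = genes[0]
        assert (g.span.start, g.span.end) == (0, 100)
        assert len(g.exons) == 2
        assert (g.exons[0].start, g.exons[0].end) == (0, 40)

    def test_exon_outside_gene_span_rejected(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t10\t100\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\texon\t1\t40\t.\t+\t.\tID=g1.e1;Parent=g1\n"
        )
        with pytest.raises(ValidationError):
            read_gff3(p)

    def test_round_trip(self, tmp_path):
        genes = [
            GeneModel("gX", GenomicInterval("chr2", 500, 900), "-",
                      (GenomicInterval("chr2", 500, 600), GenomicInterval("chr2", 700, 900))),
            GeneModel("gY", GenomicInterval("chr1", 0, 100), "+"),
        ]
        path = tmp_path / "rt.gff3"
        write_gff3(genes, path)
        back = read_gff3(path)
        by_id = {g.gene_id: g for g in back}
        assert set(by_id) == {"gX", "gY"}
        assert by_id["gX"].span == GenomicInterval("chr2", 500, 900)
        assert by_id["gX"].strand == "-"
        assert [(e.start, e.end) for e in by_id["gX"].exons] == [(500, 600), (700, 900)]
        assert by_id["gY"].span == GenomicInterval("chr1", 0, 100)


class TestIntervalAlgebra:
    CHROMS = ["chr1", "chr2"]

    @pytest.mark.parametrize("seed", range(8))
    def test_union_matches_boolean_mask_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ivs = random_disjoint_intervals(rng, self.CHROMS) + random_disjoint_intervals(
            rng, self.CHROMS
        )
        merged = merge_intervals(ivs)
        got = mask_of(merged, self.CHROMS)
        want = mask_of(ivs, self.CHROMS)
        for c in self.CHROMS:
            assert np.array_equal(got[c], want[c])
        # merged output is disjoint and sorted: constructing a PeakSet validates
        PeakSet(merged)

    @pytest.mark.parametrize("seed", range(8))
    def test_basepair_overlap_matches_mask_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = PeakSet(random_disjoint_intervals(rng, self.CHROMS))
        b = PeakSet(random_disjoint_intervals(rng, self.CHROMS))
        ma, mb = mask_of(a, self.CHROMS), mask_of(b, self.CHROMS)
        want = sum(int((ma[c] & mb[c]).sum()) for c in self.CHROMS)
        assert basepair_overlap(a, b) == want
        assert basepair_overlap(b, a) == want  # symmetric
        assert basepair_overlap(a, a) == a.total_bp

    @pytest.mark.parametrize("seed", range(6))
    def test_intersection_and_complement_match_mask_oracle(self, seed):
        from regloop.genomics_core import complement_intervals, intersect_intervals

        rng = np.random.default_rng(200 + seed)
        genome = GenomeLayout([(c, 10_000) for c in self.CHROMS])
        a = random_disjoint_intervals(rng, self.CHROMS)
        b = random_disjoint_intervals(rng, self.CHROMS)
        ma, mb = mask_of(a, self.CHROMS), mask_of(b, self.CHROMS)
        inter = mask_of(intersect_intervals(a, b), self.CHROMS)
        comp = mask_of(complement_intervals(a, genome), self.CHROMS)
        for c in self.CHROMS:
            assert np.array_equal(inter[c], ma[c] & mb[c])
            assert np.array_equal(comp[c], ~ma[c])

    def test_merge_interval_arrays_matches_object_merge(self):
        rng = np.random.default_rng(5)
        ivs = random_disjoint_intervals(rng, ["c"]) + random_disjoint_intervals(rng, ["c"])
        s = np.array([i.start for i in ivs])
        e = np.array([i.end for i in ivs])
        ms, me = merge_interval_arrays(s, e)
        want = merge_intervals(ivs)
        assert list(ms) == [i.start for i in want]
        assert list(me) == [i.end for i in want]

    def test_simple_overlap_values(self):
        a = PeakSet([GenomicInterval("c", 100, 200)])
        b = PeakSet([GenomicInterval("c", 150, 250)])
        assert basepair_overlap(a, b) == 50
        disjoint = PeakSet([GenomicInterval("c", 500, 600)])
        assert basepair_overlap(a, disjoint) == 0


class TestDirectionalCounts:
    def test_one_to_many(self):
        a = PeakSet([GenomicInterval("c", 0, 100)])
        b = PeakSet([GenomicInterval("c", 50, 60), GenomicInterval("c", 70, 80)])
        assert directional_peak_overlap_counts(a, b) == (1, 2, 1.5)

    def test_identical_and_disjoint(self):
        ivs = [GenomicInterval("c", i * 100, i * 100 + 50) for i in range(7)]
        a = PeakSet(ivs)
        assert directional_peak_overlap_counts(a, a) == (7, 7, 7.0)
        far = PeakSet([GenomicInterval("c", 10_000, 10_050)])
        assert directional_peak_overlap_counts(a, far) == (0, 0, 0.0)
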