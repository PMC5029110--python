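"""GFF3/SAM parsing, alignment stats, feature-type counting, coverage."""

import numpy as np
import pytest

from ngsflow.annotation_counts import (AnnotationError, GenomicRangeSet,
                                       GffRecord, align_stats,
                                       feature_coverage, featuretype_counts,
                                       genome_depth, read_gff3, read_sam,
                                       write_gff3)

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"


def write_sam(path, body_lines):
    path.write_text(SAM_HEADER + "".join(l + "\n" for l in body_lines))
    return path


def sam_line(qname, flag, pos, cigar, seq="*"):
    return f"{qname}\t{flag}\tchr1\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*"


class TestGff3:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\n"
                     "chr1\tsrc\texon\t11\t20\t.\t+\t.\tID=e1;Parent=t1\n")
        rs = read_gff3(p)
        r = rs.records[0]
        assert (r.seqid, r.start, r.end, r.strand, r.feature_type) == \
            ("chr1", 11, 20, "+", "exon")
        assert r.id == "e1" and r.parent == "t1"

    def test_directives_skipped(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("###\n##sequence-region chr1 1 100\n"
                     "chr1\tsrc\tgene\t1\t10\t.\t-\t.\tID=g1\n")
        assert len(read_gff3(p).records) == 1

    def test_start_after_end_rejected(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("chr1\tsrc\texon\t30\t20\t.\t+\t.\tID=e1\n")
        with pytest.raises(AnnotationError, match="line 1"):
            read_gff3(p)

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("chr1\tsrc\texon\tten\t20\t.\t+\t.\tID=e1\n")
        with pytest.raises(AnnotationError, match="line 1"):
            read_gff3(p)

    def test_roundtrip_identity(self, tmp_path):
        records = [
            GffRecord("chr1", "s", "gene", 1, 100, ".", "+", ".",
                      {"ID": "g1", "Name": "foo"}),
            GffRecord("chr1", "s", "CDS", 10, 60, ".", "-", "0",
                      {"ID": "c1", "Parent": "t1"}),
        ]
        p = write_gff3(GenomicRangeSet(records), tmp_path / "rt.gff3")
        assert read_gff3(p).records == records


class TestSam:
    def test_simple_match_block(self, tmp_path):
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 0, 100, "10M")])
        rec = next(read_sam(p))
        assert rec.blocks == [(100, 109)]
        assert rec.strand == "+"

    def test_skip_splits_blocks(self, tmp_path):
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 0, 100, "5M20N5M")])
        assert next(read_sam(p)).blocks == [(100, 104), (125, 129)]

    def test_deletion_extends_block(self, tmp_path):
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 0, 100, "5M3D5M")])
        assert next(read_sam(p)).blocks == [(100, 112)]

    def test_soft_clip_insert_consume_no_reference(self, tmp_path):
        p = write_sam(tmp_path / "a.sam",
                      [sam_line("r1", 0, 100, "2S5M1I5M2H")])
        assert next(read_sam(p)).blocks == [(100, 109)]

    def test_unmapped_has_no_blocks(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER + "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
        rec = next(read_sam(p))
        assert rec.is_unmapped and rec.blocks == []

    def test_minus_strand_flag(self, tmp_path):
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 16, 50, "4M")])
        assert next(read_sam(p)).strand == "-"


class TestAlignStats:
    def test_two_of_three_mapped(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER
                     + sam_line("r1", 0, 10, "4M") + "\n"
                     + sam_line("r2", 0, 20, "4M") + "\n"
                     + "r3\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
        row = align_stats([p], ["lib"]).iloc[0]
        assert (row.total_reads, row.aligned, row.align_pct) == (3, 2, 66.7)

    def test_all_mapped_is_100(self, tmp_path):
        p = write_sam(tmp_path / "a.sam",
                      [sam_line(f"r{i}", 0, 10 + i, "4M") for i in range(4)])
        assert align_stats([p], ["x"]).iloc[0].align_pct == 100.0

    def test_secondary_excluded_from_total(self, tmp_path):
        p = write_sam(tmp_path / "a.sam",
                      [sam_line("r1", 0, 10, "4M"),
                       sam_line("r1", 256, 50, "4M"),  # secondary
                       sam_line("r2", 0, 20, "4M"),
                       sam_line("r3", 0, 30, "4M")])
        row = align_stats([p], ["x"]).iloc[0]
        assert (row.total_reads, row.secondary) == (3, 1)

    def test_empty_body_warns_zero_row(self, tmp_path):
        p = tmp_path / "e.sam"
        p.write_text(SAM_HEADER)
        with pytest.warns(UserWarning):
            row = align_stats([p], ["x"]).iloc[0]
        assert (row.total_reads, row.align_pct) == (0, 0.0)


def _annotation():
    return GenomicRangeSet([
        GffRecord("chr1", "s", "gene", 50, 200, ".", "+", ".", {"ID": "g1"}),
        GffRecord("chr1", "s", "exon", 105, 120, ".", "+", ".",
                  {"ID": "e1", "Parent": "g1"}),
        GffRecord("chr1", "s", "intron", 300, 400, ".", "+", ".", {"ID": "i1"}),
    ])


class TestFeaturetypeCounts:
    def test_read_counted_once_per_type(self, tmp_path):
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 0, 100, "10M")])
        t = featuretype_counts(p, _annotation()).set_index(
            ["feature_type", "strand"])["count"]
        assert t[("exon", "+")] == 1
        assert t[("gene", "+")] == 1
        assert t[("intron", "+")] == 0 and t[("intron", "-")] == 0

    def test_sense_mode_respects_feature_strand(self, tmp_path):
        ann = GenomicRangeSet([GffRecord("chr1", "s", "exon", 105, 120, ".",
                                         "-", ".", {"ID": "e1"})])
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 0, 100, "10M")])
        t = featuretype_counts(p, ann, strand_mode="sense")
        assert t["count"].sum() == 0
        t2 = featuretype_counts(p, ann, strand_mode="antisense")
        assert t2.set_index(["feature_type", "strand"])["count"][("exon", "+")] == 1

    def test_matches_bruteforce_oracle(self, tmp_path, sim_dataset):
        from ngsflow.annotation_counts import read_gff3, read_sam
        ann = read_gff3(sim_dataset["gff"])
        sam = sim_dataset["sam"]
        for mode in ("both", "sense", "antisense"):
            got = featuretype_counts(sam, ann, strand_mode=mode)
            expect = brute_force_counts(sam, ann, mode)
            assert got.set_index(["feature_type", "strand"])["count"] \
                .to_dict() == expect


def brute_force_counts(sam_path, ann, mode):
    """O(reads x features) overlap oracle."""
    counts = {(ft, s): 0 for ft in ann.feature_types for s in ("+", "-")}
    for rec in read_sam(sam_path):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        hit = set()
        for f in ann.records:
            if f.seqid != rec.seqid:
                continue
            if mode == "sense" and f.strand != "." and f.strand != rec.strand:
                continue
            if mode == "antisense" and f.strand != "." and f.strand == rec.strand:
                continue
            if any(bs <= f.end and f.start <= be for bs, be in rec.blocks):
                hit.add(f.feature_type)
        for ft in hit:
            counts[(ft, rec.strand)] += 1
    return counts


class TestCoverage:
    def _single_tx(self, strand="+"):
        return GenomicRangeSet([
            GffRecord("chr1", "s", "mRNA", 81, 180, ".", strand, ".",
                      {"ID": "t1"}),
            GffRecord("chr1", "s", "CDS", 101, 160, ".", strand, "0",
                      {"ID": "c1", "Parent": "t1"}),
        ])

    def test_first_bin_fully_covered(self, tmp_path):
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 0, 101, "10M")])
        prof = feature_coverage(p, self._single_tx(), U=10, D=10, B=6)[0]
        assert np.array_equal(prof.upstream, np.zeros(10))
        assert prof.cds_binned.tolist() == [1.0, 0, 0, 0, 0, 0]
        assert prof.start_codon.tolist() == [1, 1, 1]

    def test_minus_strand_orientation(self, tmp_path):
        # read covers the transcript's 5' end = genomic 151..160
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 16, 151, "10M")])
        prof = feature_coverage(p, self._single_tx("-"), U=10, D=10, B=6)[0]
        assert prof.cds_binned.tolist() == [1.0, 0, 0, 0, 0, 0]
        assert prof.start_codon.tolist() == [1, 1, 1]

    def test_upstream_depth_oriented(self, tmp_path):
        # plus strand: 10 nt upstream are genomic 91..100
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 0, 91, "10M")])
        prof = feature_coverage(p, self._single_tx(), U=10, D=10, B=6)[0]
        assert prof.upstream.tolist() == [1] * 10
        assert prof.cds_binned.sum() == 0

    def test_transcript_without_cds_skipped(self, tmp_path):
        ann = GenomicRangeSet([GffRecord("chr1", "s", "mRNA", 1, 50, ".",
                                         "+", ".", {"ID": "t1"})])
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 0, 10, "5M")])
        with pytest.warns(UserWarning, match="no CDS"):
            assert feature_coverage(p, ann, U=5, D=5, B=2) == []

    def test_short_cds_skipped(self, tmp_path):
        ann = GenomicRangeSet([GffRecord("chr1", "s", "CDS", 1, 9, ".", "+",
                                         "0", {"ID": "c", "Parent": "t1"})])
        p = write_sam(tmp_path / "a.sam", [sam_line("r1", 0, 1, "5M")])
        with pytest.warns(UserWarning, match="shorter"):
            assert feature_coverage(p, ann, U=5, D=5, B=20) == []

    def test_base_conservation(self, sim_dataset):
        depth = genome_depth(sim_dataset["sam"])
        total_depth = sum(int(a.sum()) for a in depth.values())
        total_bases = 0
        for rec in read_sam(sim_dataset["sam"]):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            total_bases += sum(e - s + 1 for s, e in rec.blocks)
        assert total_depth == total_bases

    def test_aggregate_sums_transcripts(self, sim_dataset):
        ann = read_gff3(sim_dataset["gff"])
        singles = feature_coverage(sim_dataset["sam"], ann, U=10, D=10, B=5)
        agg = feature_coverage(sim_dataset["sam"], ann, U=10, D=10, B=5,
                               aggregate=True)
        assert agg.n_transcripts_aggregated == len(singles)
        assert np.allclose(
            agg.cds_binned, np.sum([p.cds_binned for p in singles], axis=0))
        assert np.array_equal(
            agg.upstream, np.sum([p.upstream for p in singles], axis=0))
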