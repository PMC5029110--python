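"""FASTQ streaming, preprocessing and the quality/diversity summary."""

import gzip
import random

import numpy as np
import pytest

from ngsflow.fastq_tools import (FastqFormatError, adaptor_trim,
                                 compose_filters, fastq_quality_summary,
                                 mean_quality_filter, min_length,
                                 preprocess_reads, quality_trim,
                                 render_fastq_report, stream_fastq)


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path


def random_reads(n, length=30, seed=0):
    rng = random.Random(seed)
    return [
        (f"r{i}",
         "".join(rng.choice("ACGT") for _ in range(length)),
         "".join(chr(33 + rng.randint(2, 40)) for _ in range(length)))
        for i in range(n)
    ]


class TestStreaming:
    def test_batches_bounded(self, tmp_path):
        p = write_fastq(tmp_path / "r.fq", random_reads(10))
        sizes = [len(b) for b in stream_fastq(p, batch_size=4)]
        assert sizes == [4, 4, 2]

    def test_gzip_identical(self, tmp_path):
        reads = random_reads(20)
        plain = write_fastq(tmp_path / "r.fq", reads)
        gz = tmp_path / "r.fq.gz"
        with gzip.open(gz, "wt") as fh:
            for rid, seq, qual in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        a = [r for b in stream_fastq(plain, 7) for r in b]
        b = [r for b in stream_fastq(gz, 7) for r in b]
        assert a == b

    def test_length_mismatch_names_record(self, tmp_path):
        p = tmp_path / "bad.fq"
        p.write_text("@r0\nACGTA\n+\nIIII\n")
        with pytest.raises(FastqFormatError, match="record 0"):
            list(stream_fastq(p, 10))

    def test_truncated_record_rejected(self, tmp_path):
        p = tmp_path / "bad.fq"
        p.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n")
        with pytest.raises(FastqFormatError):
            list(stream_fastq(p, 10))


class TestPreprocess:
    def test_adaptor_suffix_trim(self):
        trim = adaptor_trim("AAAA", min_overlap=4)
        assert trim(("r", "ACGTACGTAAAA", "IIIIIIIIIIII"))[1] == "ACGTACGT"

    def test_adaptor_partial_overlap(self):
        trim = adaptor_trim("AAGG", min_overlap=2)
        # read ends with the first two adaptor bases
        assert trim(("r", "CCCCAA", "IIIIII"))[1] == "CCCC"

    def test_adaptor_below_min_overlap_untouched(self):
        trim = adaptor_trim("AAGG", min_overlap=3)
        assert trim(("r", "CCCCAA", "IIIIII"))[1] == "CCCCAA"

    def test_min_length_drops_trimmed_read(self, tmp_path):
        src = write_fastq(tmp_path / "in.fq",
                          [("r0", "ACGTACGTAAAA", "I" * 12)])
        f = compose_filters(adaptor_trim("AAAA", 4), min_length(10))
        stats = preprocess_reads(src, tmp_path / "out.fq", f)
        assert (stats.kept, stats.dropped) == (0, 1)
        assert stats.bases_removed == 12

    def test_quality_trim_3prime(self):
        qual = "IIII##"  # two trailing Q=2 bases
        trim = quality_trim(threshold=20)
        assert trim(("r", "ACGTAC", qual))[1] == "ACGT"

    def test_mean_quality_filter_matches_bruteforce(self, tmp_path):
        reads = random_reads(100, seed=3)
        src = write_fastq(tmp_path / "in.fq", reads)
        stats = preprocess_reads(src, tmp_path / "out.fq",
                                 mean_quality_filter(22.0))
        expect = {rid for rid, seq, qual in reads
                  if sum(ord(c) - 33 for c in qual) / len(qual) >= 22.0}
        kept = [r for b in stream_fastq(tmp_path / "out.fq", 50) for r in b]
        assert {r[0] for r in kept} == expect
        assert stats.kept + stats.dropped == 100

    def test_order_preserved(self, tmp_path):
        reads = random_reads(50, seed=5)
        src = write_fastq(tmp_path / "in.fq", reads)
        preprocess_reads(src, tmp_path / "out.fq", min_length(0))
        kept = [r[0] for b in stream_fastq(tmp_path / "out.fq", 9) for r in b]
        assert kept == [r[0] for r in reads]


class TestSummary:
    def test_phred_worked_example(self, tmp_path):
        p = write_fastq(tmp_path / "p.fq",
                        [("a", "AC", "II"), ("b", "AG", "I5")])
        s = fastq_quality_summary(p, k=1)
        assert s.cycle_quality.loc[1, "mean"] == 40.0
        assert s.cycle_quality.loc[2, "mean"] == 30.0
        assert s.cycle_base_freq.loc[1, "A"] == 1.0
        assert s.cycle_base_freq.loc[2, "C"] == 0.5

    def test_duplication_histogram(self, tmp_path):
        p = write_fastq(tmp_path / "d.fq",
                        [(f"r{i}", "ACGTACGT", "IIIIIIII") for i in range(5)])
        s = fastq_quality_summary(p)
        assert s.duplication_hist == {5: 1}
        assert sum(m * c for m, c in s.duplication_hist.items()) == s.n_reads

    def test_kmer_diversity_bounded(self, tmp_path):
        reads = random_reads(1000, length=20, seed=9)
        p = write_fastq(tmp_path / "k.fq", reads)
        s = fastq_quality_summary(p, k=4)
        assert s.kmer_diversity[3] <= min(256, 1000)
        # exact distinct-count oracle at cycle 4
        assert s.kmer_diversity[3] == len({r[1][:4] for r in reads})

    def test_invariants_hold(self, tmp_path):
        rng = random.Random(1)
        reads = [(f"r{i}",
                  "".join(rng.choice("ACGTN") for _ in range(rng.randint(5, 25))),
                  None) for i in range(200)]
        reads = [(rid, seq, "".join(chr(33 + rng.randint(0, 40)) for _ in seq))
                 for rid, seq, _ in reads]
        p = write_fastq(tmp_path / "i.fq", reads)
        s = fastq_quality_summary(p)
        s.check_invariants()
        assert sum(s.length_hist.values()) == 200

    def test_streaming_equivalence(self, tmp_path):
        p = write_fastq(tmp_path / "s.fq", random_reads(500, seed=2))
        a = fastq_quality_summary(p, batch_size=1)
        b = fastq_quality_summary(p, batch_size=10**6)
        assert a.cycle_quality.equals(b.cycle_quality)
        assert a.cycle_base_freq.equals(b.cycle_base_freq)
        assert a.duplication_hist == b.duplication_hist
        assert a.kmer_diversity == b.kmer_diversity
        assert np.array_equal(a.gc_hist, b.gc_hist)

    def test_shuffle_invariance(self, tmp_path):
        reads = random_reads(300, seed=7)
        shuffled = list(reads)
        random.Random(0).shuffle(shuffled)
        a = fastq_quality_summary(write_fastq(tmp_path / "a.fq", reads))
        b = fastq_quality_summary(write_fastq(tmp_path / "b.fq", shuffled))
        assert a.cycle_quality.equals(b.cycle_quality)
        assert a.duplication_hist == b.duplication_hist
        assert a.length_hist == b.length_hist
        assert np.array_equal(a.gc_hist, b.gc_hist)

    def test_subsample_reproducible(self, tmp_path):
        p = write_fastq(tmp_path / "s.fq", random_reads(400, seed=4))
        a = fastq_quality_summary(p, subsample=50, seed=123)
        b = fastq_quality_summary(p, subsample=50, seed=123)
        assert a.n_reads == b.n_reads == 50
        assert a.cycle_quality.equals(b.cycle_quality)

    def test_bad_quality_encoding_rejected(self, tmp_path):
        p = tmp_path / "bad.fq"
        p.write_text("@r\nAC\n+\n\x18I\n")
        with pytest.raises(FastqFormatError, match="Phred"):
            fastq_quality_summary(p)


class TestReport:
    def test_tsv_columns_per_file(self, tmp_path):
        sums = {}
        for i in range(3):
            p = write_fastq(tmp_path / f"f{i}.fq", random_reads(30, seed=i))
            sums[f"f{i}"] = fastq_quality_summary(p)
        fig, tsv = render_fastq_report(sums, tmp_path / "qc.png")
        header = tsv.read_text().splitlines()[0].split("\t")
        assert header[2:] == ["f0", "f1", "f2"]
        assert fig.exists()

    def test_rerender_byte_identical(self, tmp_path):
        p = write_fastq(tmp_path / "f.fq", random_reads(30))
        sums = {"f": fastq_quality_summary(p)}
        _, tsv1 = render_fastq_report(sums, tmp_path / "a.png")
        first = tsv1.read_bytes()
        _, tsv2 = render_fastq_report(sums, tmp_path / "b.png")
        assert tsv2.read_bytes() == first

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            render_fastq_report({}, tmp_path / "x.png")
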