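"""Synthetic data generation: genome, annotation, reads, alignments.

Everything downstream of a sequencer can be emulated here with known ground
truth, so every workflow component is testable without downloading data:

- :func:`make_genome` writes a random FASTA genome with a target GC content.
- :func:`make_annotation` plants non-overlapping protein-coding genes into
  the genome sequence itself (ATG ... stop, no internal in-frame stop, and a
  stop codon immediately upstream in-frame), then writes a GFF3 with
  gene/mRNA/exon/CDS records.  Because the codons are physically written
  into the FASTA, ORF prediction and coverage tools see consistent ground
  truth.
- :func:`simulate_reads` draws reads from transcripts and genomic
  background, writes FASTQ (per-cycle quality decay model), a truth table of
  true origins, and a SAM encoding the true alignments.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation_counts import GenomicRangeSet, GffRecord, write_gff3
from .orf_tools import revcomp

__all__ = ["make_genome", "make_annotation", "simulate_reads"]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
#: sense codons only (no start/stop ambiguity inside a synthetic CDS)
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]


def make_genome(
    n_chroms: int,
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    out: str | Path = "genome.fasta",
) -> Path:
    """Write a random FASTA genome; deterministic given ``seed``.

    Base composition is i.i.d. with P(G)=P(C)=gc/2, so the realized GC
    fraction is within 3 s.d. of ``gc`` with overwhelming probability.
    """
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for i in range(n_chroms):
        seq = "".join(rng.choice(_BASES, size=length, p=p))
        records.append(SeqRecord(Seq(seq), id=f"chr{i + 1}", description=""))
    out = Path(out)
    SeqIO.write(records, str(out), "fasta")
    return out


def _make_cds_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n_codons-2) sense codons + stop: a clean single-ORF CDS."""
    body = "".join(rng.choice(_SAFE_CODONS) for _ in range(n_codons - 2))
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + body + stop


def make_annotation(
    genome: str | Path,
    n_genes: int,
    exons_per_gene: tuple[int, int] = (1, 1),
    cds_codons: tuple[int, int] = (40, 120),
    flank: int = 30,
    seed: int = 0,
    out: Optional[str | Path] = None,
) -> Path:
    """Plant genes into a genome and write the matching GFF3.

    Each gene carries an mRNA, exon(s) and one contiguous CDS whose codons
    (leading in-frame stop, ATG, sense codons, stop) are written into the
    genome FASTA in place, so the CDS is exactly one maximal ORF on its
    strand.  Genes never overlap; ``flank`` nt of UTR separate the CDS from
    the gene boundaries.  Fails if the requested genes cannot be placed
    without overlap.
    """
    genome = Path(genome)
    rng = np.random.default_rng(seed)
    chroms = {rec.id: list(str(rec.seq).upper())
              for rec in SeqIO.parse(str(genome), "fasta")}
    records: list[GffRecord] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    chrom_ids = list(chroms)
    placed = 0
    attempts = 0
    while placed < n_genes and attempts < n_genes * 200:
        attempts += 1
        chrom = chrom_ids[rng.integers(len(chrom_ids))]
        seqlist = chroms[chrom]
        n_codons = int(rng.integers(cds_codons[0], cds_codons[1] + 1))
        cds_len = 3 * n_codons
        gene_len = cds_len + 2 * flank + 3  # +3 for the upstream in-frame stop
        if gene_len >= len(seqlist):
            raise ValueError("chromosome too short for requested gene sizes; "
                             "use fewer/shorter genes")
        start = int(rng.integers(1, len(seqlist) - gene_len))  # 1-based
        end = start + gene_len - 1
        if any(s <= end and start <= e for s, e in occupied[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        cds_seq = _make_cds_sequence(n_codons, rng)
        guard_stop = _STOPS[rng.integers(len(_STOPS))]
        # forward-orientation layout inside the gene:
        #   [flank UTR][guard stop][CDS][flank UTR]
        insert = guard_stop + cds_seq
        if strand == "-":
            insert = revcomp(insert)
            cds_start = start + flank            # genomic low coord of CDS
            cds_end = cds_start + cds_len - 1
            ins_start = start + flank            # revcomp(guard+cds): cds first
        else:
            cds_start = start + flank + 3
            cds_end = cds_start + cds_len - 1
            ins_start = start + flank
        seqlist[ins_start - 1: ins_start - 1 + len(insert)] = list(insert)
        placed += 1
        occupied[chrom].append((start, end))
        gid = f"g{placed}"
        tid = f"t{placed}"
        records.append(GffRecord(chrom, "ngsflow", "gene", start, end, ".",
                                 strand, ".", {"ID": gid}))
        records.append(GffRecord(chrom, "ngsflow", "mRNA", start, end, ".",
                                 strand, ".", {"ID": tid, "Parent": gid}))
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        if n_exons <= 1:
            exon_bounds = [(start, end)]
        else:
            # split the UTR flanks off as extra exons; CDS stays in one exon
            exon_bounds = [(start, cds_start - 1), (cds_start, end)]
        for k, (es, ee) in enumerate(exon_bounds, start=1):
            records.append(GffRecord(chrom, "ngsflow", "exon", es, ee, ".",
                                     strand, ".",
                                     {"ID": f"{tid}.e{k}", "Parent": tid}))
        records.append(GffRecord(chrom, "ngsflow", "CDS", cds_start, cds_end,
                                 ".", strand, "0",
                                 {"ID": f"{tid}.cds", "Parent": tid}))
    if placed < n_genes:
        raise ValueError(
            f"could only place {placed}/{n_genes} genes without overlap; "
            f"use fewer genes or a larger genome")
    # rewrite genome with planted codons
    new_records = [SeqRecord(Seq("".join(chroms[c])), id=c, description="")
                   for c in chroms]
    SeqIO.write(new_records, str(genome), "fasta")
    records.sort(key=lambda r: (r.seqid, r.start,
                                {"gene": 0, "mRNA": 1, "exon": 2, "CDS": 3}
                                .get(r.feature_type, 9)))
    out = Path(out) if out else genome.with_suffix(".gff3")
    write_gff3(GenomicRangeSet(records), out)
    return out


def _quality_string(read_len: int, rng: np.random.Generator) -> str:
    """Per-cycle decay model: Q(c) = clip(40 - 0.15 c + N(0, 3), 2, 40)."""
    q = 40.0 - 0.15 * np.arange(read_len) + rng.normal(0, 3, read_len)
    q = np.clip(np.round(q), 2, 40).astype(int)
    return "".join(chr(33 + v) for v in q)


def simulate_reads(
    genome: str | Path,
    annotation: str | Path | GenomicRangeSet,
    n_reads: int,
    read_len: int = 50,
    error_rate: float = 0.0,
    transcript_frac: float = 0.7,
    seed: int = 0,
    out_prefix: str | Path = "reads",
) -> tuple[Path, Path, Path]:
    """Simulate reads with known origins; write FASTQ, truth TSV and SAM.

    A fraction ``transcript_frac`` of reads starts inside a random gene (on
    the gene's strand), the rest uniformly on the genome (random strand).
    Substitution errors are applied at ``error_rate`` per base.  The SAM
    encodes the *true* alignments (CIGAR all-match, MAPQ 60).

    Returns ``(fastq_path, truth_path, sam_path)``.
    """
    from .annotation_counts import read_gff3

    genome = Path(genome)
    chrom_seqs = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(genome), "fasta")}
    if isinstance(annotation, GenomicRangeSet):
        ranges = annotation
    else:
        ranges = read_gff3(annotation)
    genes = [r for r in ranges.records if r.feature_type == "gene"]
    rng = np.random.default_rng(seed)
    out_prefix = Path(out_prefix)
    fastq_path = out_prefix.with_suffix(".fastq")
    truth_path = out_prefix.with_suffix(".truth.tsv")
    sam_path = out_prefix.with_suffix(".sam")

    chrom_ids = list(chrom_seqs)
    truth_rows = []
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(chrom_seqs[c])} for c in chrom_ids],
    }
    tid_of = {c: i for i, c in enumerate(chrom_ids)}
    with open(fastq_path, "w", encoding="ascii") as fq, \
            pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
        for i in range(n_reads):
            from_tx = bool(genes) and rng.random() < transcript_frac
            if from_tx:
                gene = genes[rng.integers(len(genes))]
                chrom, strand = gene.seqid, gene.strand
                lo = gene.start
                hi = max(gene.start, gene.end - read_len + 1)
                hi = min(hi, len(chrom_seqs[chrom]) - read_len + 1)
                pos = int(rng.integers(lo, hi + 1))
            else:
                chrom = chrom_ids[rng.integers(len(chrom_ids))]
                strand = "+" if rng.random() < 0.5 else "-"
                pos = int(rng.integers(1, len(chrom_seqs[chrom]) - read_len + 2))
            ref = chrom_seqs[chrom][pos - 1: pos - 1 + read_len]
            seq = revcomp(ref) if strand == "-" else ref
            if error_rate > 0:
                chars = list(seq)
                for j in np.nonzero(rng.random(read_len) < error_rate)[0]:
                    chars[j] = str(rng.choice(
                        [b for b in "ACGT" if b != chars[j]]))
                seq = "".join(chars)
            rid = f"read{i}"
            fq.write(f"@{rid}\n{seq}\n+\n{_quality_string(read_len, rng)}\n")
            truth_rows.append((rid, chrom, pos, strand))
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rid
            a.query_sequence = seq
            a.flag = 16 if strand == "-" else 0
            a.reference_id = tid_of[chrom]
            a.reference_start = pos - 1
            a.mapping_quality = 60
            a.cigarstring = f"{read_len}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            sam.write(a)
    pd.DataFrame(truth_rows, columns=["read_id", "seqid", "pos", "strand"]) \
        .to_csv(truth_path, sep="\t", index=False)
    return fastq_path, truth_path, sam_path
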