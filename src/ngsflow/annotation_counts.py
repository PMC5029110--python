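"""Annotation-aware read counting and coverage from SAM + GFF3.

All external coordinates are 1-based inclusive (GFF3/SAM native); the
conversion to numpy's 0-based indexing happens only inside depth computation.

Counting convention: a read is counted once per *feature type* it overlaps
(>= 1 bp overlap between any of its reference blocks and any record of that
type), split by read strand.  Primary alignments only; each mate of a pair
counts independently.

Coverage profiles are metagene-style: nucleotide resolution upstream of the
start codon and downstream of the stop codon (in transcript orientation),
with the spliced CDS compressed into a fixed number of bins of mean depth.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import pysam
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

__all__ = [
    "AnnotationError",
    "GffRecord",
    "GenomicRangeSet",
    "AlignmentRecord",
    "CoverageProfile",
    "read_gff3",
    "write_gff3",
    "read_sam",
    "align_stats",
    "featuretype_counts",
    "feature_coverage",
    "genome_depth",
]


class AnnotationError(ValueError):
    pass


@dataclass
class GffRecord:
    """One GFF3 feature line; coordinates 1-based inclusive."""

    seqid: str
    source: str
    feature_type: str
    start: int
    end: int
    score: str
    strand: str  # "+", "-" or "."
    phase: str
    attributes: dict[str, str]

    @property
    def id(self) -> Optional[str]:
        return self.attributes.get("ID")

    @property
    def parent(self) -> Optional[str]:
        return self.attributes.get("Parent")


@dataclass
class GenomicRangeSet:
    """Stranded, typed 1-based genomic intervals (annotation or ORF results)."""

    records: list[GffRecord]

    @property
    def feature_types(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.feature_type not in seen:
                seen.append(r.feature_type)
        return seen

    def by_type(self, feature_type: str) -> list[GffRecord]:
        return [r for r in self.records if r.feature_type == feature_type]


def read_gff3(path: str | Path) -> GenomicRangeSet:
    """Parse GFF3 into a :class:`GenomicRangeSet`; directives are skipped."""
    records: list[GffRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"line {lineno}: expected 9 columns, "
                                      f"got {len(cols)}")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from exc
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise AnnotationError(
                    f"line {lineno}: non-integer coordinates "
                    f"{cols[3]!r}/{cols[4]!r}") from None
            if start > end:
                raise AnnotationError(f"line {lineno}: start {start} > end {end}")
            if feat.strand not in ("+", "-", "."):
                raise AnnotationError(f"line {lineno}: bad strand {feat.strand!r}")
            attrs = {k: ",".join(v) for k, v in feat.attributes.items()}
            records.append(GffRecord(
                seqid=feat.seqid, source=feat.source,
                feature_type=feat.featuretype, start=start, end=end,
                score=cols[5], strand=feat.strand, phase=cols[7],
                attributes=attrs))
    return GenomicRangeSet(records=records)


def write_gff3(ranges: GenomicRangeSet, path: str | Path) -> Path:
    path = Path(path)
    lines = ["##gff-version 3"]
    for r in ranges.records:
        attrs = ";".join(f"{k}={v}" for k, v in r.attributes.items())
        lines.append("\t".join([
            r.seqid, r.source, r.feature_type, str(r.start), str(r.end),
            r.score, r.strand, r.phase, attrs]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# SAM


@dataclass
class AlignmentRecord:
    """Minimal alignment view: 1-based inclusive reference blocks per read."""

    qname: str
    seqid: Optional[str]        # None when unmapped
    pos: Optional[int]          # 1-based leftmost
    strand: Optional[str]
    blocks: list[tuple[int, int]]
    mapq: int
    is_secondary: bool = False
    is_supplementary: bool = False

    @property
    def is_unmapped(self) -> bool:
        return self.seqid is None


#: CIGAR ops consuming the reference *within* a block (M, D, =, X); N splits.
_BLOCK_OPS = {0, 2, 7, 8}
_SKIP_OP = 3
_NOREF_OPS = {1, 4, 5, 6}  # I, S, H, P


def _blocks_from_cigar(pos: int, cigartuples) -> list[tuple[int, int]]:
    blocks: list[tuple[int, int]] = []
    cur_start = pos
    cur = pos
    for op, length in cigartuples:
        if op in _BLOCK_OPS:
            cur += length
        elif op == _SKIP_OP:
            if cur > cur_start:
                blocks.append((cur_start, cur - 1))
            cur += length
            cur_start = cur
        elif op in _NOREF_OPS:
            continue
        else:
            raise AnnotationError(f"unknown CIGAR op code {op}")
    if cur > cur_start:
        blocks.append((cur_start, cur - 1))
    return blocks


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream alignments from a SAM file (with header) via pysam."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                yield AlignmentRecord(
                    qname=aln.query_name or "", seqid=None, pos=None,
                    strand=None, blocks=[], mapq=aln.mapping_quality,
                    is_secondary=aln.is_secondary,
                    is_supplementary=aln.is_supplementary)
                continue
            pos1 = aln.reference_start + 1  # pysam is 0-based
            yield AlignmentRecord(
                qname=aln.query_name or "",
                seqid=aln.reference_name,
                pos=pos1,
                strand="-" if aln.is_reverse else "+",
                blocks=_blocks_from_cigar(pos1, aln.cigartuples or []),
                mapq=aln.mapping_quality,
                is_secondary=aln.is_secondary,
                is_supplementary=aln.is_supplementary)


def align_stats(paths: list[str | Path], labels: list[str]) -> pd.DataFrame:
    """Alignment statistics table: total/aligned primary reads per file.

    Secondary (0x100) and supplementary (0x800) records are excluded from the
    totals and tallied in their own column.  ``align_pct`` is rounded to one
    decimal.
    """
    if len(paths) != len(labels):
        raise ValueError("paths and labels differ in length")
    rows = []
    for path, label in zip(paths, labels):
        total = aligned = secondary = 0
        for rec in read_sam(path):
            if rec.is_secondary or rec.is_supplementary:
                secondary += 1
                continue
            total += 1
            if not rec.is_unmapped:
                aligned += 1
        if total == 0:
            warnings.warn(f"{path}: no primary records")
            pct = 0.0
        else:
            pct = round(100.0 * aligned / total, 1)
        rows.append((label, total, aligned, pct, secondary))
    return pd.DataFrame(
        rows, columns=["label", "total_reads", "aligned", "align_pct",
                       "secondary"])


# ---------------------------------------------------------------------------
# feature-type counting


def _strand_ok(read_strand: str, feat_strand: str, mode: str) -> bool:
    if mode == "both" or feat_strand == ".":
        return True
    if mode == "sense":
        return feat_strand == read_strand
    if mode == "antisense":
        return feat_strand != read_strand
    raise ValueError(f"unknown strand_mode {mode!r}")


def featuretype_counts(
    aln_path: str | Path,
    annotation: GenomicRangeSet,
    strand_mode: str = "both",
) -> pd.DataFrame:
    """Strand-specific read counts per annotation feature *type*.

    A read counts once for every feature type it overlaps by >= 1 bp on any
    reference block; counts are split by read strand.  Every feature type of
    the annotation appears in the output, including zero rows.
    """
    if strand_mode not in ("both", "sense", "antisense"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    trees: dict[str, IntervalTree] = {}
    for rec in annotation.records:
        # interval end is exclusive in intervaltree
        trees.setdefault(rec.seqid, IntervalTree()).addi(
            rec.start, rec.end + 1, (rec.feature_type, rec.strand))
    ftypes = annotation.feature_types
    counts: dict[tuple[str, str], int] = {
        (ft, s): 0 for ft in ftypes for s in ("+", "-")}
    for rec in read_sam(aln_path):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        tree = trees.get(rec.seqid)
        if tree is None:
            continue
        hit_types: set[str] = set()
        for bs, be in rec.blocks:
            for iv in tree.overlap(bs, be + 1):
                ftype, fstrand = iv.data
                if _strand_ok(rec.strand, fstrand, strand_mode):
                    hit_types.add(ftype)
        for ft in hit_types:
            counts[(ft, rec.strand)] += 1
    rows = [(ft, s, counts[(ft, s)]) for ft in ftypes for s in ("+", "-")]
    return pd.DataFrame(rows, columns=["feature_type", "strand", "count"])


# ---------------------------------------------------------------------------
# coverage


def genome_depth(aln_path: str | Path) -> dict[str, np.ndarray]:
    """Per-base depth per seqid (index 0 == position 1), primary records only."""
    ends: dict[str, int] = {}
    blocks_by_seq: dict[str, list[tuple[int, int]]] = {}
    for rec in read_sam(aln_path):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        for bs, be in rec.blocks:
            blocks_by_seq.setdefault(rec.seqid, []).append((bs, be))
            ends[rec.seqid] = max(ends.get(rec.seqid, 0), be)
    depth: dict[str, np.ndarray] = {}
    for seqid, blocks in blocks_by_seq.items():
        diff = np.zeros(ends[seqid] + 1, dtype=np.int64)
        for bs, be in blocks:
            diff[bs - 1] += 1
            diff[be] -= 1
        depth[seqid] = np.cumsum(diff)[:-1]
    return depth


@dataclass
class CoverageProfile:
    """Metagene coverage anchored at start/stop codons, 5'->3' orientation."""

    transcript_id: str
    upstream: np.ndarray       # U nt before the start codon
    start_codon: np.ndarray    # 3 nt
    cds_binned: np.ndarray     # B mean depths over the spliced CDS
    stop_codon: np.ndarray     # 3 nt
    downstream: np.ndarray     # D nt after the stop codon
    n_transcripts_aggregated: int = 1


def _spliced_cds_positions(cds_parts: list[GffRecord]) -> tuple[list[int], str, str]:
    """Genomic positions of the spliced CDS in 5'->3' transcript order."""
    strand = cds_parts[0].strand
    seqid = cds_parts[0].seqid
    parts = sorted(cds_parts, key=lambda r: r.start)
    positions: list[int] = []
    for part in parts:
        positions.extend(range(part.start, part.end + 1))
    if strand == "-":
        positions.reverse()
    return positions, strand, seqid


def _depth_at(depth: dict[str, np.ndarray], seqid: str,
              positions: list[int]) -> np.ndarray:
    arr = depth.get(seqid)
    out = np.zeros(len(positions), dtype=np.int64)
    if arr is None:
        return out
    for i, p in enumerate(positions):
        if 1 <= p <= len(arr):
            out[i] = arr[p - 1]
    return out


def feature_coverage(
    aln_path: str | Path,
    annotation: GenomicRangeSet,
    transcript_ids: Optional[list[str]] = None,
    U: int = 50,
    D: int = 50,
    B: int = 20,
    aggregate: bool = False,
) -> list[CoverageProfile] | CoverageProfile:
    """Read-depth profiles around start/stop codons with binned CDS coverage.

    The start codon is the first 3 nt of the spliced CDS in transcript
    orientation, the stop codon the last 3 nt (assumed included in the CDS
    span).  ``upstream`` covers the U nt 5' of the start codon, ``downstream``
    the D nt 3' of the stop codon; positions off the chromosome end
    contribute depth 0.  The spliced CDS of length L is partitioned into B
    contiguous bins with boundaries at floor(i*L/B); each bin reports mean
    per-nt depth.  With ``aggregate=True`` the per-transcript vectors are
    summed into one profile.

    Transcripts without CDS records, or with spliced CDS shorter than B nt,
    are skipped with a warning.
    """
    cds_by_tx: dict[str, list[GffRecord]] = {}
    for rec in annotation.records:
        if rec.feature_type == "CDS" and rec.parent:
            cds_by_tx.setdefault(rec.parent, []).append(rec)
    if transcript_ids is None:
        wanted = list(cds_by_tx)
        for rec in annotation.records:
            if rec.feature_type in ("mRNA", "transcript") and rec.id \
                    and rec.id not in cds_by_tx:
                warnings.warn(f"transcript {rec.id}: no CDS records, skipped")
    else:
        wanted = []
        for tid in transcript_ids:
            if tid not in cds_by_tx:
                warnings.warn(f"transcript {tid}: no CDS records, skipped")
            else:
                wanted.append(tid)
    depth = genome_depth(aln_path)
    profiles: list[CoverageProfile] = []
    for tid in wanted:
        positions, strand, seqid = _spliced_cds_positions(cds_by_tx[tid])
        L = len(positions)
        if L < B or L < 6:
            warnings.warn(f"transcript {tid}: spliced CDS of {L} nt shorter "
                          f"than bin count {B}, skipped")
            continue
        cds_depth = _depth_at(depth, seqid, positions)
        # flanks in genomic coordinates, oriented 5'->3'
        first, last = positions[0], positions[-1]
        if strand == "-":
            up_pos = list(range(first + U, first, -1))
            down_pos = list(range(last - 1, last - 1 - D, -1))
        else:
            up_pos = list(range(first - U, first))
            down_pos = list(range(last + 1, last + 1 + D))
        bins = np.floor(np.arange(B + 1) * L / B).astype(int)
        binned = np.array([
            cds_depth[bins[i]: bins[i + 1]].mean() for i in range(B)
        ])
        profiles.append(CoverageProfile(
            transcript_id=tid,
            upstream=_depth_at(depth, seqid, up_pos),
            start_codon=cds_depth[:3].copy(),
            cds_binned=binned,
            stop_codon=cds_depth[-3:].copy(),
            downstream=_depth_at(depth, seqid, down_pos),
        ))
    if not aggregate:
        return profiles
    if not profiles:
        raise AnnotationError("no usable transcripts for aggregation")
    agg = CoverageProfile(
        transcript_id="aggregate",
        upstream=np.sum([p.upstream for p in profiles], axis=0),
        start_codon=np.sum([p.start_codon for p in profiles], axis=0),
        cds_binned=np.sum([p.cds_binned for p in profiles], axis=0),
        stop_codon=np.sum([p.stop_codon for p in profiles], axis=0),
        downstream=np.sum([p.downstream for p in profiles], axis=0),
        n_transcripts_aggregated=len(profiles),
    )
    return agg
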