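"""Streamed FASTQ preprocessing and quality/diversity summaries.

Reads are streamed in bounded batches so arbitrarily large files can be
processed with flat memory for the per-cycle statistics (the duplication and
k-mer diversity panels keep one entry per *distinct* sequence/k-mer, which is
bounded by read diversity rather than file size).

Quality encoding is Phred+33 throughout; the encoding is a declared property
of the input, not auto-detected.

The eight summary panels:

1. per-cycle quality (min, Q1, median, Q3, max, mean)
2. per-cycle base proportions over A/C/G/T/N
3. per-read mean-quality histogram
4. read-length histogram
5. duplication histogram (exact full-sequence multiplicity)
6. per-cycle distinct k-mer diversity
7. per-read GC-fraction histogram
8. per-cycle N-call proportion
"""

from __future__ import annotations

import gzip
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Optional

import numpy as np
import pandas as pd

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FastqFormatError",
    "FastqSummary",
    "ProcessStats",
    "stream_fastq",
    "preprocess_reads",
    "fastq_quality_summary",
    "render_fastq_report",
    "adaptor_trim",
    "quality_trim",
    "min_length",
    "mean_quality_filter",
    "compose_filters",
]

Read = tuple[str, str, str]  # (id, sequence, quality string)

_MAXQ = 94  # Phred+33 printable range '!'..'~'
_GC_BINS = 50


class FastqFormatError(ValueError):
    pass


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, "rt", encoding="ascii")


def stream_fastq(path: str | Path, batch_size: int = 100_000) -> Iterator[list[Read]]:
    """Yield ``(id, seq, qual)`` batches of at most ``batch_size`` reads.

    Accepts plain or gzipped 4-line-record FASTQ.  Truncated records and
    sequence/quality length mismatches raise :class:`FastqFormatError` with
    the 0-based record index.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be positive")
    batch: list[Read] = []
    index = 0
    with _open_maybe_gzip(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqFormatError(f"record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"record {index}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            batch.append((title.split()[0] if title else "", seq, qual))
            index += 1
            if len(batch) >= batch_size:
                yield batch
                batch = []
    if batch:
        yield batch


# ---------------------------------------------------------------------------
# read transforms for preprocess_reads


def adaptor_trim(adaptor: str, min_overlap: int = 5) -> Callable[[Read], Read]:
    """Trim a 3' adaptor by exact suffix-overlap match.

    The longest read suffix equal to a prefix of ``adaptor`` (length >=
    ``min_overlap``) is removed; mismatches are not tolerated.
    """
    adaptor = adaptor.upper()

    def _trim(read: Read) -> Read:
        rid, seq, qual = read
        n = len(seq)
        lo = max(0, n - len(adaptor))
        for p in range(lo, n - min_overlap + 1):
            if seq[p:] == adaptor[: n - p]:
                return (rid, seq[:p], qual[:p])
        return read

    return _trim


def quality_trim(threshold: int, from_3prime: bool = True) -> Callable[[Read], Read]:
    """Remove the trailing (or leading) run of bases with quality < threshold."""

    def _trim(read: Read) -> Read:
        rid, seq, qual = read
        scores = [ord(c) - 33 for c in qual]
        if from_3prime:
            end = len(scores)
            while end > 0 and scores[end - 1] < threshold:
                end -= 1
            return (rid, seq[:end], qual[:end])
        start = 0
        while start < len(scores) and scores[start] < threshold:
            start += 1
        return (rid, seq[start:], qual[start:])

    return _trim


def min_length(L: int) -> Callable[[Read], Optional[Read]]:
    """Drop reads shorter than ``L`` nt."""

    def _filter(read: Read) -> Optional[Read]:
        return read if len(read[1]) >= L else None

    return _filter


def mean_quality_filter(Q: float) -> Callable[[Read], Optional[Read]]:
    """Drop reads whose mean Phred quality is below ``Q``."""

    def _filter(read: Read) -> Optional[Read]:
        _, seq, qual = read
        if not qual:
            return None
        mean = sum(ord(c) - 33 for c in qual) / len(qual)
        return read if mean >= Q else None

    return _filter


def compose_filters(*transforms: Callable[[Read], Optional[Read]]):
    """Chain transforms left to right; a ``None`` anywhere drops the read."""

    def _composed(read: Read) -> Optional[Read]:
        out: Optional[Read] = read
        for t in transforms:
            if out is None:
                return None
            out = t(out)
        return out

    return _composed


@dataclass
class ProcessStats:
    kept: int
    dropped: int
    bases_removed: int


def preprocess_reads(
    in_path: str | Path,
    out_path: str | Path,
    read_filter: Callable[[Read], Optional[Read]],
    batch_size: int = 100_000,
) -> ProcessStats:
    """Stream-apply a read transform/filter; write kept reads in input order.

    ``read_filter`` maps a read to a (possibly trimmed) read, or ``None`` to
    drop it.  Trimming never lengthens a read (enforced).
    """
    kept = dropped = bases_removed = 0
    out_path = Path(out_path)
    with open(out_path, "w", encoding="ascii") as out:
        for batch in stream_fastq(in_path, batch_size):
            for read in batch:
                result = read_filter(read)
                if result is None:
                    dropped += 1
                    bases_removed += len(read[1])
                    continue
                rid, seq, qual = result
                if len(seq) > len(read[1]):
                    raise ValueError(
                        f"read {rid}: transform lengthened the read"
                    )
                bases_removed += len(read[1]) - len(seq)
                kept += 1
                out.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return ProcessStats(kept=kept, dropped=dropped, bases_removed=bases_removed)


# ---------------------------------------------------------------------------
# quality summary


@dataclass
class FastqSummary:
    """Accumulated quality/diversity statistics for one FASTQ file.

    Per-cycle arrays are indexed by cycle (0-based internally; reported
    1-based).  ``cycle_quality`` holds exact percentiles derived from full
    per-cycle quality histograms, so results are independent of batch size.
    """

    n_reads: int
    cycle_quality: pd.DataFrame          # columns: min,q1,median,q3,max,mean
    cycle_base_freq: pd.DataFrame        # columns: A,C,G,T,N (proportions)
    read_meanq_hist: dict[int, int]      # floor(mean quality) -> n reads
    length_hist: dict[int, int]          # read length -> n reads
    duplication_hist: dict[int, int]     # multiplicity m -> n distinct seqs
    kmer_diversity: list[int]            # distinct k-mers ending at each cycle
    gc_hist: np.ndarray                  # _GC_BINS bins over [0,1]
    n_per_cycle: np.ndarray              # proportion of N calls per cycle
    k: int = 4

    def check_invariants(self) -> None:
        bf = self.cycle_base_freq[["A", "C", "G", "T", "N"]].to_numpy()
        if len(bf) and not np.allclose(bf.sum(axis=1), 1.0, atol=1e-9):
            raise AssertionError("per-cycle base proportions do not sum to 1")
        if sum(m * c for m, c in self.duplication_hist.items()) != self.n_reads:
            raise AssertionError("duplication histogram does not conserve reads")
        if sum(self.length_hist.values()) != self.n_reads:
            raise AssertionError("length histogram does not conserve reads")


class _Accumulator:
    def __init__(self, k: int):
        self.k = k
        self.n_reads = 0
        self.qual_counts = np.zeros((0, _MAXQ), dtype=np.int64)   # [cycle, Q]
        self.base_counts = np.zeros((0, 5), dtype=np.int64)       # [cycle, ACGTN]
        self.meanq_hist: Counter = Counter()
        self.length_hist: Counter = Counter()
        self.seq_counts: Counter = Counter()
        self.kmer_sets: list[set[str]] = []
        self.gc_hist = np.zeros(_GC_BINS, dtype=np.int64)
        self._base_index = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

    def _grow(self, length: int) -> None:
        if length > self.qual_counts.shape[0]:
            pad = length - self.qual_counts.shape[0]
            self.qual_counts = np.vstack(
                [self.qual_counts, np.zeros((pad, _MAXQ), dtype=np.int64)])
            self.base_counts = np.vstack(
                [self.base_counts, np.zeros((pad, 5), dtype=np.int64)])
            self.kmer_sets.extend(set() for _ in range(pad))

    def add(self, read: Read) -> None:
        _, seq, qual = read
        seq = seq.upper()
        self._grow(len(seq))
        self.n_reads += 1
        self.length_hist[len(seq)] += 1
        self.seq_counts[seq] += 1
        qsum = 0
        gc = 0
        bidx = self._base_index
        for c, (base, qc) in enumerate(zip(seq, qual)):
            q = ord(qc) - 33
            if q < 0:
                raise FastqFormatError(
                    f"quality character {qc!r} below '!' (not Phred+33)")
            self.qual_counts[c, q] += 1
            self.base_counts[c, bidx.get(base, 4)] += 1
            qsum += q
            if base in ("G", "C"):
                gc += 1
        if seq:
            self.meanq_hist[int(qsum / len(seq))] += 1
            self.gc_hist[min(int(gc / len(seq) * _GC_BINS), _GC_BINS - 1)] += 1
            for c in range(self.k, len(seq) + 1):
                self.kmer_sets[c - 1].add(seq[c - self.k: c])

    def finalize(self) -> FastqSummary:
        ncycles = self.qual_counts.shape[0]
        stats = np.zeros((ncycles, 6))
        for c in range(ncycles):
            counts = self.qual_counts[c]
            total = counts.sum()
            if total == 0:
                continue
            cum = np.cumsum(counts)
            qs = []
            for frac in (0.25, 0.5, 0.75):
                # weighted linear interpolation, matching np.percentile on
                # the expanded sample
                h = frac * (total - 1)
                lo = int(np.searchsorted(cum, np.floor(h) + 1))
                hi = int(np.searchsorted(cum, np.floor(h) + 2)) \
                    if np.floor(h) + 2 <= total else lo
                qs.append(lo + (h - np.floor(h)) * (hi - lo))
            vals = np.nonzero(counts)[0]
            mean = (counts * np.arange(_MAXQ)).sum() / total
            stats[c] = [vals.min(), qs[0], qs[1], qs[2], vals.max(), mean]
        cycle_quality = pd.DataFrame(
            stats, columns=["min", "q1", "median", "q3", "max", "mean"],
            index=pd.RangeIndex(1, ncycles + 1, name="cycle"))
        totals = self.base_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, self.base_counts / totals, 0.0)
        cycle_base_freq = pd.DataFrame(
            freq, columns=["A", "C", "G", "T", "N"],
            index=pd.RangeIndex(1, ncycles + 1, name="cycle"))
        duplication = Counter(self.seq_counts.values())
        n_prop = freq[:, 4]
        return FastqSummary(
            n_reads=self.n_reads,
            cycle_quality=cycle_quality,
            cycle_base_freq=cycle_base_freq,
            read_meanq_hist=dict(sorted(self.meanq_hist.items())),
            length_hist=dict(sorted(self.length_hist.items())),
            duplication_hist=dict(sorted(duplication.items())),
            kmer_diversity=[len(s) for s in self.kmer_sets],
            gc_hist=self.gc_hist.copy(),
            n_per_cycle=n_prop.copy(),
            k=self.k,
        )


def fastq_quality_summary(
    path: str | Path,
    k: int = 4,
    batch_size: int = 100_000,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> FastqSummary:
    """Single-pass quality/diversity summary of a FASTQ file.

    With ``subsample=None`` (all reads) the result is deterministic and
    independent of ``batch_size``.  With an integer ``subsample``, reservoir
    sampling with ``seed`` selects that many reads reproducibly.
    """
    if subsample is None:
        acc = _Accumulator(k)
        for batch in stream_fastq(path, batch_size):
            for read in batch:
                acc.add(read)
        return acc.finalize()
    rng = random.Random(seed)
    reservoir: list[Read] = []
    seen = 0
    for batch in stream_fastq(path, batch_size):
        for read in batch:
            if len(reservoir) < subsample:
                reservoir.append(read)
            else:
                j = rng.randrange(seen + 1)
                if j < subsample:
                    reservoir[j] = read
            seen += 1
    acc = _Accumulator(k)
    for read in reservoir:
        acc.add(read)
    return acc.finalize()


# ---------------------------------------------------------------------------
# report rendering


def summary_table(summaries: dict[str, FastqSummary]) -> pd.DataFrame:
    """Long-format table of every statistic of every summary (one file column set)."""
    frames = []
    for name, s in summaries.items():
        rows: list[tuple[str, str, float]] = [("n_reads", "", float(s.n_reads))]
        for col in s.cycle_quality.columns:
            for cyc, v in s.cycle_quality[col].items():
                rows.append((f"cycle_quality_{col}", str(cyc), float(v)))
        for col in s.cycle_base_freq.columns:
            for cyc, v in s.cycle_base_freq[col].items():
                rows.append((f"base_freq_{col}", str(cyc), float(v)))
        for label, hist in (("meanq_hist", s.read_meanq_hist),
                            ("length_hist", s.length_hist),
                            ("duplication_hist", s.duplication_hist)):
            for key, v in hist.items():
                rows.append((label, str(key), float(v)))
        for cyc, v in enumerate(s.kmer_diversity, start=1):
            rows.append((f"kmer{s.k}_diversity", str(cyc), float(v)))
        for b, v in enumerate(s.gc_hist):
            rows.append(("gc_hist", f"{b / _GC_BINS:.2f}", float(v)))
        for cyc, v in enumerate(s.n_per_cycle, start=1):
            rows.append(("n_per_cycle", str(cyc), float(v)))
        df = pd.DataFrame(rows, columns=["statistic", "key", name])
        df = df.set_index(["statistic", "key"])
        frames.append(df)
    return pd.concat(frames, axis=1)


def render_fastq_report(
    summaries: dict[str, FastqSummary],
    out: str | Path,
) -> tuple[Path, Path]:
    """Render the 8-panel x n-files QC figure plus a machine-readable TSV.

    Returns ``(figure_path, tsv_path)``; the TSV values exactly equal the
    in-memory summaries and re-rendering is byte-identical.
    """
    if not summaries:
        raise ValueError("no summaries given")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    names = list(summaries)
    fig, axes = plt.subplots(8, len(names), figsize=(4 * len(names), 20),
                             squeeze=False)
    for j, name in enumerate(names):
        s = summaries[name]
        cq = s.cycle_quality
        ax = axes[0][j]
        ax.fill_between(cq.index, cq["q1"], cq["q3"], alpha=0.4, label="IQR")
        ax.plot(cq.index, cq["median"], lw=1, label="median")
        ax.plot(cq.index, cq["mean"], lw=1, ls="--", label="mean")
        ax.set_title(f"{name}\nper-cycle quality", fontsize=8)
        ax = axes[1][j]
        for base in ("A", "C", "G", "T", "N"):
            ax.plot(s.cycle_base_freq.index, s.cycle_base_freq[base],
                    lw=1, label=base)
        ax.set_title("base proportions", fontsize=8)
        axes[2][j].bar(list(s.read_meanq_hist), list(s.read_meanq_hist.values()))
        axes[2][j].set_title("mean-quality hist", fontsize=8)
        axes[3][j].bar(list(s.length_hist), list(s.length_hist.values()))
        axes[3][j].set_title("length hist", fontsize=8)
        axes[4][j].bar(list(s.duplication_hist),
                       list(s.duplication_hist.values()))
        axes[4][j].set_title("duplication hist", fontsize=8)
        axes[5][j].plot(range(1, len(s.kmer_diversity) + 1), s.kmer_diversity)
        axes[5][j].set_title(f"distinct {s.k}-mers per cycle", fontsize=8)
        axes[6][j].bar(np.arange(_GC_BINS) / _GC_BINS, s.gc_hist,
                       width=1 / _GC_BINS)
        axes[6][j].set_title("GC fraction hist", fontsize=8)
        axes[7][j].plot(range(1, len(s.n_per_cycle) + 1), s.n_per_cycle)
        axes[7][j].set_title("N proportion per cycle", fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=100)
    plt.close(fig)
    tsv_path = out.with_suffix(".tsv")
    table = summary_table(summaries)
    table.to_csv(tsv_path, sep="\t", float_format="%.10g")
    return out, tsv_path
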