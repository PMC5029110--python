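"""Open reading frame prediction in DNA sequences, both strands.

An ORF is a maximal run from an ATG to the first in-frame stop codon
(TAA/TAG/TGA), stop included.  Within one frame, after an ORF terminates the
scan resumes beyond its stop, so internal ATGs sharing a stop are suppressed
in favour of the 5'-most (longest) one.  Codons containing N never match a
start or stop and never terminate scanning.

Minus-strand ORFs are found on the reverse complement and reported in
forward-strand coordinates (1-based inclusive).  Frame numbering is
``((start - 1) mod 3) + 1`` in scanning orientation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

__all__ = ["OrfRange", "pred_orf", "revcomp"]

_STOPS = {"TAA", "TAG", "TGA"}
_DNA_RE = re.compile(r"^[ACGTN]*$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class OrfRange:
    """One predicted ORF in forward-strand coordinates (1-based inclusive)."""

    seq_id: str
    start: int
    end: int
    strand: str            # "+" or "-"
    frame: int             # 1..3 in scanning orientation
    length_nt: int
    rank: int = 0          # 1 = longest, assigned after sorting
    has_stop: bool = True

    def overlaps(self, other: "OrfRange") -> bool:
        return self.start <= other.end and other.start <= self.end


def _scan_frames(seq: str) -> list[tuple[int, int, int, bool]]:
    """Yield (start0, end0, frame, has_stop) ORFs in scanning orientation."""
    out = []
    n = len(seq)
    for frame_off in range(3):
        open_start = None
        i = frame_off
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if "N" in codon:
                i += 3
                continue
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in _STOPS:
                out.append((open_start, i + 2, frame_off + 1, True))
                open_start = None
            i += 3
        if open_start is not None:
            # run off the end: ORF to the last complete codon, no stop
            last = open_start + ((n - open_start) // 3) * 3 - 1
            out.append((open_start, last, frame_off + 1, False))
    return out


def pred_orf(
    seq: str,
    n: Union[str, int] = "all",
    strand: str = "both",
    min_length: int = 0,
    require_stop: bool = True,
    longest_disjoint: bool = False,
    seq_id: str = "seq",
) -> list[OrfRange]:
    """Predict ORFs in a DNA sequence.

    Parameters
    ----------
    seq
        DNA over {A,C,G,T,N} (case-insensitive).
    n
        ``"all"``, ``"longest"`` (top-ranked only) or an integer k (top k).
    strand
        ``"+"``, ``"-"`` or ``"both"``.
    min_length
        Minimum ORF length in nt (start through stop inclusive).
    require_stop
        If True, ORFs running off the sequence end without a stop are dropped.
    longest_disjoint
        Greedily keep top-ranked ORFs not overlapping already kept ones
        (forward-coordinate overlap, either strand).

    Returns
    -------
    list of :class:`OrfRange`, sorted by descending length, then ascending
    forward start, then "+" before "-"; ``rank`` assigned after sorting.
    """
    seq = seq.upper()
    if not _DNA_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-DNA character(s) in sequence: {bad}")
    if strand not in ("+", "-", "both"):
        raise ValueError(f"bad strand {strand!r}")
    L = len(seq)
    found: list[OrfRange] = []
    if strand in ("+", "both"):
        for s0, e0, frame, has_stop in _scan_frames(seq):
            found.append(OrfRange(seq_id, s0 + 1, e0 + 1, "+", frame,
                                  e0 - s0 + 1, has_stop=has_stop))
    if strand in ("-", "both"):
        for s0, e0, frame, has_stop in _scan_frames(revcomp(seq)):
            # map reverse-complement coordinates back to forward strand
            found.append(OrfRange(seq_id, L - e0, L - s0, "-", frame,
                                  e0 - s0 + 1, has_stop=has_stop))
    found = [
        orf for orf in found
        if orf.length_nt >= min_length and (orf.has_stop or not require_stop)
    ]
    found.sort(key=lambda o: (-o.length_nt, o.start, 0 if o.strand == "+" else 1))
    if longest_disjoint:
        kept: list[OrfRange] = []
        for orf in found:
            if not any(orf.overlaps(k) for k in kept):
                kept.append(orf)
        found = kept
    if n == "longest":
        found = found[:1]
    elif n != "all":
        found = found[: int(n)]
    for i, orf in enumerate(found, start=1):
        orf.rank = i
    return found
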