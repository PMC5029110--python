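"""Workflow file formats: the *targets* sample sheet and the *param* command template.

The targets file is the single user-provided input of a workflow: a TSV
mapping raw input files (FASTQ, later SAM, ...) to sample names, condition
factors and named comparison (contrast) sets.  The param file is a declarative
TSV template for one external command line, with placeholder slots that are
substituted per sample.

Dialects
--------
targets file (TSV, UTF-8)::

    # free-text comment lines start with "#"
    # <CMP> CMPset1: A-B, A-C        <- comparison-set definition
    FileName1	FileName2	SampleName	Factor	...extras
    data/s1_1.fq	data/s1_2.fq	S1	A	...

``FileName1`` and ``SampleName`` are mandatory; a non-empty ``FileName2``
marks a paired-end sample.  Comparison lines use the literal sentinel
``# <CMP>`` followed by ``SETNAME: A-B, C-D`` (hyphen-separated factor pairs).

param file (TSV, UTF-8), columns ``slot_type  prefix  value``::

    software		bowtie2
    option	-p	4
    reference	-x	<Reference>
    infile		<FileName1>
    outfile	-S	<SampleName>.sam

Exactly one ``software`` row is required.  Placeholder vocabulary is fixed:
``<FileName1> <FileName2> <SampleName> <OutFile> <Reference>``; anything else
in angle brackets is rejected at parse time so data files can never inject
arbitrary shell text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "FormatError",
    "SampleRecord",
    "TargetsTable",
    "ArgSlot",
    "ParamSpec",
    "PLACEHOLDERS",
    "read_targets",
    "write_targets",
    "read_param",
]

PLACEHOLDERS = frozenset(
    {"<FileName1>", "<FileName2>", "<SampleName>", "<OutFile>", "<Reference>"}
)

SLOT_TYPES = ("software", "option", "infile", "outfile", "reference")

#: sample names must be safe inside file names; factors additionally exclude
#: "-" because it separates the two factors of a comparison pair "A-B"
_NAME_RE = re.compile(r"^[A-Za-z0-9_.-]+$")
_FACTOR_RE = re.compile(r"^[A-Za-z0-9_.]+$")
_CMP_RE = re.compile(r"^#\s*<CMP>\s*(?P<name>\S+?)\s*:\s*(?P<pairs>.+)$")
_TOKEN_RE = re.compile(r"<[^<>]*>")


class FormatError(ValueError):
    """Raised for malformed targets/param files or invalid tables."""


@dataclass
class SampleRecord:
    """One row of a targets table."""

    file1: str
    sample_name: str
    factor: str
    file2: Optional[str] = None
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class TargetsTable:
    """The sample sheet: ordered sample records plus named comparison sets.

    ``comparisons`` maps a set name to an ordered list of ``(factorA, factorB)``
    pairs; by convention log fold changes of comparison ``A-B`` are positive
    when abundance is higher in ``A``.
    """

    rows: list[SampleRecord]
    comparisons: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    source_path: Optional[str] = None

    def validate(self) -> None:
        if not self.rows:
            raise FormatError("targets table has no samples")
        seen: set[str] = set()
        factors: set[str] = set()
        for rec in self.rows:
            if rec.sample_name in seen:
                raise FormatError(f"duplicate sample name {rec.sample_name}")
            seen.add(rec.sample_name)
            if not _NAME_RE.match(rec.sample_name or ""):
                raise FormatError(
                    f"invalid sample name {rec.sample_name!r}: only [A-Za-z0-9_.-] allowed"
                )
            if not _FACTOR_RE.match(rec.factor or ""):
                raise FormatError(
                    f"invalid factor {rec.factor!r}: only [A-Za-z0-9_.] allowed "
                    f"('-' is reserved for comparison syntax)"
                )
            factors.add(rec.factor)
        for set_name, pairs in self.comparisons.items():
            for a, b in pairs:
                missing = [f for f in (a, b) if f not in factors]
                if missing:
                    raise FormatError(
                        f"comparison set {set_name}: pair {a}-{b} references "
                        f"factor(s) {', '.join(missing)} absent from the table"
                    )

    @property
    def sample_names(self) -> list[str]:
        return [r.sample_name for r in self.rows]

    @property
    def paired(self) -> bool:
        return any(r.file2 for r in self.rows)

    def __eq__(self, other: object) -> bool:  # source_path is provenance, not content
        if not isinstance(other, TargetsTable):
            return NotImplemented
        return self.rows == other.rows and self.comparisons == other.comparisons


def _parse_cmp_line(line: str, lineno: int) -> tuple[str, list[tuple[str, str]]]:
    m = _CMP_RE.match(line)
    if m is None:
        raise FormatError(f"line {lineno}: malformed comparison line: {line.strip()!r}")
    pairs: list[tuple[str, str]] = []
    for chunk in m.group("pairs").split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        bits = chunk.split("-")
        if len(bits) != 2 or not all(bits):
            raise FormatError(
                f"line {lineno}: malformed comparison pair {chunk!r} "
                f"(expected 'FactorA-FactorB')"
            )
        pairs.append((bits[0], bits[1]))
    if not pairs:
        raise FormatError(f"line {lineno}: comparison set {m.group('name')!r} is empty")
    return m.group("name"), pairs


def read_targets(path: str | Path) -> TargetsTable:
    """Parse a targets sample-sheet file.

    Comment lines starting ``# <CMP>`` define comparison sets; other ``#``
    lines are ignored metadata.  The single header row must name at least
    ``FileName1`` and ``SampleName``.
    """
    path = Path(path)
    comparisons: dict[str, list[tuple[str, str]]] = {}
    header: Optional[list[str]] = None
    rows: list[SampleRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "<CMP>" in line:
                    name, pairs = _parse_cmp_line(line, lineno)
                    comparisons[name] = pairs
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                for col in ("FileName1", "SampleName"):
                    if col not in header:
                        raise FormatError(f"missing mandatory column {col}")
                continue
            vals = dict(zip(header, (f.strip() for f in fields)))
            extra = {
                k: vals.get(k, "")
                for k in header
                if k not in ("FileName1", "FileName2", "SampleName", "Factor")
            }
            rows.append(
                SampleRecord(
                    file1=vals.get("FileName1", ""),
                    file2=vals.get("FileName2") or None,
                    sample_name=vals.get("SampleName", ""),
                    factor=vals.get("Factor", ""),
                    extra=extra,
                )
            )
    if header is None:
        raise FormatError(f"{path}: no header row found")
    table = TargetsTable(rows=rows, comparisons=comparisons, source_path=str(path))
    table.validate()
    return table


def write_targets(table: TargetsTable, path: str | Path) -> Path:
    """Write a targets table; the output re-reads into an equal table."""
    table.validate()
    path = Path(path)
    has_file2 = any(r.file2 for r in table.rows)
    extra_cols: list[str] = []
    for rec in table.rows:
        for k in rec.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    header = ["FileName1"] + (["FileName2"] if has_file2 else [])
    header += ["SampleName", "Factor"] + extra_cols
    lines = []
    for name, pairs in table.comparisons.items():
        body = ", ".join(f"{a}-{b}" for a, b in pairs)
        lines.append(f"# <CMP> {name}: {body}")
    lines.append("\t".join(header))
    for rec in table.rows:
        row = [rec.file1] + ([rec.file2 or ""] if has_file2 else [])
        row += [rec.sample_name, rec.factor]
        row += [rec.extra.get(k, "") for k in extra_cols]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@dataclass
class ArgSlot:
    """One argument slot of a command template: optional flag + optional value."""

    slot_type: str
    prefix: str = ""
    value: str = ""


@dataclass
class ParamSpec:
    """Declarative template for one external command line.

    ``slots`` are rendered in file order; ``outfile_template`` (the first
    outfile slot's value) names a step's canonical per-sample output, relative
    to ``outdir``.
    """

    software: str
    slots: list[ArgSlot]
    outfile_template: str
    outdir: str = "results"

    @property
    def placeholders(self) -> set[str]:
        toks: set[str] = set()
        for slot in self.slots:
            toks.update(_TOKEN_RE.findall(slot.value))
        return toks


def _check_placeholders(value: str, lineno: int) -> None:
    for tok in _TOKEN_RE.findall(value):
        if tok not in PLACEHOLDERS:
            raise FormatError(
                f"line {lineno}: unknown placeholder {tok} "
                f"(allowed: {', '.join(sorted(PLACEHOLDERS))})"
            )


def read_param(path: str | Path) -> ParamSpec:
    """Parse a param command-template file (TSV: slot_type, prefix, value)."""
    path = Path(path)
    software: Optional[str] = None
    slots: list[ArgSlot] = []
    outfiles: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = (line.split("\t") + ["", ""])[:3]
            slot_type, prefix, value = (p.strip() for p in parts)
            if slot_type not in SLOT_TYPES:
                raise FormatError(f"line {lineno}: unknown slot_type {slot_type!r}")
            _check_placeholders(value, lineno)
            if slot_type == "software":
                if software is not None:
                    raise FormatError(f"line {lineno}: multiple software rows")
                if not value:
                    raise FormatError(f"line {lineno}: software row has empty value")
                software = value
                continue
            if slot_type == "outfile":
                outfiles.append(value)
            slots.append(ArgSlot(slot_type=slot_type, prefix=prefix, value=value))
    if software is None:
        raise FormatError(f"{path}: no software row")
    if not outfiles:
        raise FormatError(f"{path}: no outfile row")
    first = Path(outfiles[0])
    outdir = str(first.parent) if str(first.parent) != "." else "results"
    return ParamSpec(
        software=software,
        slots=slots,
        outfile_template=first.name,
        outdir=outdir,
    )
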