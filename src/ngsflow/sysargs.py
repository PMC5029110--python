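"""Workflow-step control objects.

A :class:`SysArgs` instance represents one workflow step instantiated over all
samples of a targets table: per-sample fully rendered command lines, the input
files they consume and the output files they are expected to produce.  Steps
chain: :func:`chain_targets` derives the next step's targets table from the
current step's registered outputs, so only the initial sample sheet is ever
written by hand.

Commands are rendered as argument vectors, never shell strings; execution
(see :mod:`ngsflow.runner`) bypasses the shell entirely, so sample names and
file paths cannot inject shell metacharacters.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .formats import ParamSpec, SampleRecord, TargetsTable

__all__ = ["ConfigurationError", "SysArgs", "build_sysargs", "chain_targets", "completed"]


class ConfigurationError(ValueError):
    """A step cannot be constructed or run with the given configuration."""


@dataclass
class SysArgs:
    """One workflow step rendered over all samples.

    Invariants: ``len(argvs) == len(outfiles) == len(targets.rows)``; command
    order equals targets row order; every outfile lies under ``outdir``.
    """

    step_name: str
    software: str
    targets: TargetsTable
    argvs: list[list[str]]
    infiles: list[list[str]]
    outfiles: list[list[str]]
    outdir: str
    reference: Optional[str] = None

    @property
    def commands(self) -> list[str]:
        """Display form of the rendered commands, one string per sample."""
        return [" ".join(argv) for argv in self.argvs]

    @property
    def sample_names(self) -> list[str]:
        return self.targets.sample_names


def _substitute(value: str, mapping: dict[str, Optional[str]],
                sample: str) -> str:
    out = value
    for token, repl in mapping.items():
        if token in out:
            if repl is None:
                raise ConfigurationError(
                    f"sample {sample}: placeholder {token} cannot be resolved"
                )
            out = out.replace(token, repl)
    if "<" in out:
        raise ConfigurationError(
            f"sample {sample}: unresolved placeholder in {value!r}"
        )
    return out


def _render_sample(param: ParamSpec, rec: SampleRecord, outdir: str,
                   reference: Optional[str]) -> tuple[list[str], list[str], list[str]]:
    outfile_main = os.path.join(outdir, _substitute(
        param.outfile_template,
        {"<SampleName>": rec.sample_name, "<FileName1>": rec.file1,
         "<FileName2>": rec.file2, "<Reference>": reference},
        rec.sample_name,
    ))
    mapping: dict[str, Optional[str]] = {
        "<FileName1>": rec.file1,
        "<FileName2>": rec.file2,
        "<SampleName>": rec.sample_name,
        "<OutFile>": outfile_main,
        "<Reference>": reference,
    }
    argv = [param.software]
    infiles: list[str] = []
    outfiles: list[str] = []
    for slot in param.slots:
        if slot.prefix:
            argv.append(slot.prefix)
        if not slot.value:
            continue
        if slot.slot_type == "outfile":
            rendered = os.path.join(outdir, Path(_substitute(slot.value, mapping, rec.sample_name)).name)
            outfiles.append(rendered)
        else:
            rendered = _substitute(slot.value, mapping, rec.sample_name)
            if slot.slot_type == "infile":
                infiles.append(rendered)
        argv.append(rendered)
    if not outfiles:
        outfiles = [outfile_main]
    return argv, infiles, outfiles


def build_sysargs(
    targets: TargetsTable,
    param: ParamSpec,
    step_name: str,
    reference: Optional[str] = None,
    outdir: Optional[str] = None,
) -> SysArgs:
    """Instantiate a workflow step: render one command per sample.

    Parameters
    ----------
    targets
        The sample sheet for this step.
    param
        The command template.
    step_name
        Label used for log/status directories.
    reference
        Path substituted for ``<Reference>``; required iff the template uses it.
    outdir
        Output directory; defaults to the param file's relative outdir.
    """
    targets.validate()
    used = param.placeholders
    if "<Reference>" in used and reference is None:
        raise ConfigurationError(
            f"step {step_name}: param uses <Reference> but no reference was given"
        )
    if "<FileName2>" in used:
        for rec in targets.rows:
            if not rec.file2:
                raise ConfigurationError(
                    f"step {step_name}: param uses <FileName2> but sample "
                    f"{rec.sample_name} has no second input file"
                )
    outdir = outdir if outdir is not None else param.outdir
    argvs, infiles, outfiles = [], [], []
    for rec in targets.rows:
        argv, inf, outf = _render_sample(param, rec, outdir, reference)
        argvs.append(argv)
        infiles.append(inf or [rec.file1] + ([rec.file2] if rec.file2 else []))
        outfiles.append(outf)
    return SysArgs(
        step_name=step_name,
        software=param.software,
        targets=targets,
        argvs=argvs,
        infiles=infiles,
        outfiles=outfiles,
        outdir=outdir,
        reference=reference,
    )


def chain_targets(step: SysArgs) -> TargetsTable:
    """Derive the downstream targets table from a step's registered outputs.

    Each sample's ``FileName1`` becomes the step's first (canonical) outfile;
    sample names, factors, extra columns and comparison sets pass through
    unchanged, so contrast definitions follow the samples through the workflow.
    """
    rows = [
        SampleRecord(
            file1=outs[0],
            file2=None,
            sample_name=rec.sample_name,
            factor=rec.factor,
            extra=dict(rec.extra),
        )
        for rec, outs in zip(step.targets.rows, step.outfiles)
    ]
    return TargetsTable(rows=rows, comparisons=dict(step.targets.comparisons))


def completed(step: SysArgs) -> list[bool]:
    """Per-sample completion flags: all expected outputs exist and are non-empty.

    Zero-byte files do not count as completion — a crashed tool often leaves
    an empty output behind.
    """
    flags = []
    for outs in step.outfiles:
        flags.append(
            all(os.path.isfile(p) and os.path.getsize(p) > 0 for p in outs)
        )
    return flags
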