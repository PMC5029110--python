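"""Template-driven Markdown analysis reports and demo workflow environments.

:func:`build_report` fills a Markdown template whose ``{{field}}``
placeholders are resolved from a context of strings, tables and file paths.
Rendering is deterministic: given the same workflow state and report date the
output is byte-identical, so reports can be regenerated at any time.
Rendered sections are cached next to the report keyed by a digest of their
input state, so unchanged sections are reused on rebuild.

:func:`gen_workenvir` materializes a self-contained, runnable demo workflow
directory ("rnaseq-mini"): synthetic genome/annotation/reads, a targets file
with comparison sets, a param file whose external command is a portable file
copy standing in for an aligner (the alignments themselves come from the
read simulator's ground truth), a synthetic differential-expression table,
and a report template.  ``ngsflow run <dir>`` executes it end-to-end.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ReportError", "build_report", "df_to_markdown", "gen_workenvir",
           "WORKENV_TEMPLATES"]

_FIELD_RE = re.compile(r"\{\{\s*([A-Za-z0-9_.]+)\s*\}\}")


class ReportError(ValueError):
    pass


def df_to_markdown(df: pd.DataFrame, index: bool = False) -> str:
    """Minimal GitHub-flavoured Markdown table."""
    frame = df.reset_index() if index else df
    cols = [str(c) for c in frame.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def _render_value(value) -> str:
    if isinstance(value, pd.DataFrame):
        return df_to_markdown(value)
    if isinstance(value, Path):
        if not value.exists():
            raise ReportError(f"referenced file does not exist: {value}")
        return str(value)
    return str(value)


def build_report(
    context: dict,
    template: str | Path,
    out: str | Path,
    report_date: str = "unset",
) -> Path:
    """Fill a Markdown template from a workflow-state context.

    ``context`` maps field names to strings, DataFrames (rendered as Markdown
    tables) or Paths (verified to exist, e.g. figures).  ``report_date``
    resolves the ``{{report_date}}`` field; pass a fixed value to make
    regeneration byte-identical.  An unresolvable placeholder raises
    :class:`ReportError` naming the field.
    """
    template = Path(template)
    out = Path(out)
    text = template.read_text(encoding="utf-8")
    full_context = dict(context)
    full_context.setdefault("report_date", report_date)

    cache_path = out.with_name(out.name + ".cache.json")
    cache: dict[str, str] = {}
    if cache_path.is_file():
        try:
            cache = json.loads(cache_path.read_text())
        except json.JSONDecodeError:
            cache = {}

    rendered_cache: dict[str, str] = {}

    def _resolve(match: re.Match) -> str:
        name = match.group(1)
        if name not in full_context:
            raise ReportError(f"unresolvable placeholder: {name}")
        value = full_context[name]
        digest = hashlib.sha256(repr(value).encode()).hexdigest()
        key = f"{name}:{digest}"
        if key in cache:
            section = cache[key]
        else:
            section = _render_value(value)
        rendered_cache[key] = section
        return section

    body = _FIELD_RE.sub(_resolve, text)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(body, encoding="utf-8")
    cache_path.write_text(json.dumps(rendered_cache, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# demo workflow environment


_REPORT_TEMPLATE = """\
# RNA-Seq mini workflow report

Generated: {{report_date}}

## Samples

{{targets_table}}

## Read quality

Summary statistics: {{fastq_tsv}} — figure: {{fastq_figure}}

## Alignment step

Status of the external alignment step (restartable; skipped = outputs
already present):

{{status_table}}

## Alignment statistics

{{align_stats_table}}

## Read distribution over annotation feature types

{{featuretype_table}}

## Differentially expressed genes

Cutoffs: |logFC| >= {{lfc_min}}, FDR <= {{fdr_max}}

{{deg_summary_table}}

## DEG overlap between comparisons (up-regulated)

{{venn_counts_table}}

Venn diagram: {{venn_figure}}
"""


def _make_deg_table(gene_ids: list[str], comparisons: list[str],
                    seed: int) -> pd.DataFrame:
    """Synthetic DE results: ~30 % of genes significant per comparison."""
    rng = np.random.default_rng(seed)
    data = {}
    for comp in comparisons:
        lfc = rng.normal(0, 2.0, len(gene_ids)).round(3)
        fdr = rng.uniform(0, 1, len(gene_ids))
        sig = rng.random(len(gene_ids)) < 0.3
        fdr = np.where(sig, fdr * 0.05, 0.05 + fdr * 0.95).round(4)
        data[f"{comp}_logFC"] = lfc
        data[f"{comp}_FDR"] = fdr
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene"))


def _build_rnaseq_mini(dest: Path, seed: int = 11) -> None:
    from .fixtures import make_annotation, make_genome, simulate_reads
    from .formats import SampleRecord, TargetsTable, write_targets

    data = dest / "data"
    data.mkdir(parents=True)
    (dest / "param").mkdir()
    genome = make_genome(1, 20_000, gc=0.45, seed=seed,
                         out=data / "genome.fasta")
    gff = make_annotation(genome, n_genes=20, seed=seed + 1,
                          out=data / "annotation.gff3")
    samples = [("A1", "A"), ("A2", "A"), ("B1", "B"), ("B2", "B"),
               ("C1", "C"), ("C2", "C")]
    rows = []
    for i, (name, factor) in enumerate(samples):
        fq, _, _ = simulate_reads(
            genome, gff, n_reads=250, read_len=50, error_rate=0.002,
            seed=seed + 10 + i, out_prefix=data / name)
        rows.append(SampleRecord(file1=f"data/{name}.fastq",
                                 sample_name=name, factor=factor))
    table = TargetsTable(rows=rows, comparisons={
        "CMPset1": [("A", "B"), ("A", "C")]})
    write_targets(table, dest / "targets.txt")
    # the demo's "aligner": a portable copy of the simulator's ground-truth
    # SAM files, exercising the full external-command machinery
    (dest / "param" / "align.param").write_text(
        "software\t\tcp\n"
        "infile\t\tdata/<SampleName>.sam\n"
        "outfile\t\tresults/<SampleName>.sam\n",
        encoding="utf-8")
    gene_ids = [f"g{i + 1}" for i in range(20)]
    deg = _make_deg_table(gene_ids, ["A-B", "A-C"], seed=seed + 99)
    deg.to_csv(data / "deg_results.tsv", sep="\t")
    (dest / "report_template.md").write_text(_REPORT_TEMPLATE,
                                             encoding="utf-8")
    config = {
        "name": "rnaseq-mini",
        "genome": "data/genome.fasta",
        "annotation": "data/annotation.gff3",
        "targets": "targets.txt",
        "align_param": "param/align.param",
        "deg_table": "data/deg_results.tsv",
        "report_template": "report_template.md",
        "report_date": "workflow run",
        "lfc_min": 1.0,
        "fdr_max": 0.05,
        "coverage": {"U": 30, "D": 30, "B": 10},
        "fastq_k": 4,
        "orf_min_length": 60,
    }
    import yaml
    (dest / "workflow.yml").write_text(yaml.safe_dump(config, sort_keys=False),
                                       encoding="utf-8")


WORKENV_TEMPLATES = {"rnaseq-mini": _build_rnaseq_mini}


def gen_workenvir(template_name: str, dest: str | Path) -> Path:
    """Generate a runnable demo workflow directory (no overwrite)."""
    if template_name not in WORKENV_TEMPLATES:
        raise ValueError(
            f"unknown workflow template {template_name!r}; available: "
            f"{', '.join(sorted(WORKENV_TEMPLATES))}")
    dest = Path(dest)
    if dest.exists() and any(dest.iterdir()):
        raise FileExistsError(f"destination {dest} exists and is not empty")
    dest.mkdir(parents=True, exist_ok=True)
    WORKENV_TEMPLATES[template_name](dest)
    return dest
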