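"""End-to-end execution of a generated workflow directory.

Glue over the library modules: reads ``workflow.yml``, runs FASTQ QC, the
external alignment step (restartable), alignment statistics, feature-type
counts, metagene coverage, ORF prediction, DEG filtering with Venn overlap,
and assembles the Markdown report.  All relative paths in the configuration
resolve against the workflow directory.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .annotation_counts import align_stats, feature_coverage, featuretype_counts, read_gff3
from .fastq_tools import fastq_quality_summary, render_fastq_report
from .formats import read_param, read_targets
from .orf_tools import pred_orf
from .report import build_report, df_to_markdown
from .runner import run_parallel, run_serial
from .set_stats import filter_degs, overlapper, venn_counts_plot
from .sysargs import build_sysargs, chain_targets

__all__ = ["run_workflow"]


def _resolve_targets_paths(table, base: Path):
    for rec in table.rows:
        if not Path(rec.file1).is_absolute():
            rec.file1 = str(base / rec.file1)
        if rec.file2 and not Path(rec.file2).is_absolute():
            rec.file2 = str(base / rec.file2)
    return table


def run_workflow(workdir: str | Path, force: bool = False,
                 workers: int = 1) -> Path:
    """Run a workflow directory end-to-end; returns the report path."""
    workdir = Path(workdir)
    cfg = yaml.safe_load((workdir / "workflow.yml").read_text())
    results = workdir / "results"
    results.mkdir(exist_ok=True)

    targets = _resolve_targets_paths(
        read_targets(workdir / cfg["targets"]), workdir)

    # 1. FASTQ quality summaries
    summaries = {
        rec.sample_name: fastq_quality_summary(rec.file1, k=cfg["fastq_k"])
        for rec in targets.rows
    }
    fastq_fig, fastq_tsv = render_fastq_report(summaries,
                                               results / "fastq_qc.png")

    # 2. external alignment step (restartable, logged)
    param = read_param(workdir / cfg["align_param"])
    # the param's input slots are relative to the workflow dir
    for slot in param.slots:
        if slot.slot_type == "infile" and not Path(slot.value).is_absolute():
            slot.value = str(workdir / slot.value)
    step = build_sysargs(targets, param, step_name="align",
                         outdir=str(results))
    if workers > 1:
        run_results = run_parallel(step, workers=workers, force=force,
                                   logdir=workdir / "logs")
    else:
        run_results = run_serial(step, force=force, logdir=workdir / "logs")
    status_df = pd.DataFrame(
        [(r.sample_name, r.state,
          "" if r.exit_code is None else r.exit_code) for r in run_results],
        columns=["sample", "state", "exit_code"])

    # 3. downstream targets + alignment statistics
    chained = chain_targets(step)
    from .formats import write_targets
    write_targets(chained, workdir / "targets_align.txt")
    sam_paths = [rec.file1 for rec in chained.rows]
    stats = align_stats(sam_paths, chained.sample_names)
    stats.to_csv(results / "align_stats.tsv", sep="\t", index=False)

    # 4. feature-type counts (summed over samples) and metagene coverage
    annotation = read_gff3(workdir / cfg["annotation"])
    ft_total = None
    for sam in sam_paths:
        ft = featuretype_counts(sam, annotation)
        ft_total = ft if ft_total is None else ft_total.assign(
            count=ft_total["count"] + ft["count"])
    ft_total.to_csv(results / "featuretype_counts.tsv", sep="\t", index=False)
    cov_cfg = cfg["coverage"]
    profile = feature_coverage(sam_paths[0], annotation,
                               U=cov_cfg["U"], D=cov_cfg["D"], B=cov_cfg["B"],
                               aggregate=True)
    cov_rows = (
        [("upstream", i + 1, v) for i, v in enumerate(profile.upstream)]
        + [("cds_bin", i + 1, v) for i, v in enumerate(profile.cds_binned)]
        + [("downstream", i + 1, v) for i, v in enumerate(profile.downstream)]
    )
    pd.DataFrame(cov_rows, columns=["segment", "index", "depth"]) \
        .to_csv(results / "coverage.tsv", sep="\t", index=False)

    # 5. ORF prediction on the genome
    orf_rows = []
    for rec in SeqIO.parse(str(workdir / cfg["genome"]), "fasta"):
        for orf in pred_orf(str(rec.seq), strand="both",
                            min_length=cfg["orf_min_length"], seq_id=rec.id):
            orf_rows.append((orf.seq_id, orf.start, orf.end, orf.strand,
                             orf.frame, orf.length_nt, orf.rank))
    pd.DataFrame(orf_rows, columns=["seqid", "start", "end", "strand",
                                    "frame", "length_nt", "rank"]) \
        .to_csv(results / "orfs.tsv", sep="\t", index=False)

    # 6. DEG filtering + Venn overlap of up-regulated sets
    deg_table = pd.read_csv(workdir / cfg["deg_table"], sep="\t",
                            index_col=0)
    degs = filter_degs(deg_table, lfc_min=cfg["lfc_min"],
                       fdr_max=cfg["fdr_max"])
    degs.summary.to_csv(results / "deg_summary.tsv", sep="\t", index=False)
    venn = overlapper({comp: degs.up[comp] for comp in degs.up})
    venn_fig = venn_counts_plot(venn, results / "venn_up.png")
    venn_df = pd.DataFrame(
        [(" & ".join(k), v) for k, v in sorted(venn.all_counts().items())],
        columns=["region", "count"])
    venn_df.to_csv(results / "venn_up_counts.tsv", sep="\t", index=False)

    # 7. report
    targets_df = pd.DataFrame(
        [(r.sample_name, r.factor, Path(r.file1).name) for r in targets.rows],
        columns=["sample", "factor", "file"])
    context = {
        "targets_table": targets_df,
        "fastq_tsv": fastq_tsv,
        "fastq_figure": fastq_fig,
        "status_table": status_df,
        "align_stats_table": stats,
        "featuretype_table": ft_total,
        "lfc_min": cfg["lfc_min"],
        "fdr_max": cfg["fdr_max"],
        "deg_summary_table": degs.summary,
        "venn_counts_table": venn_df,
        "venn_figure": venn_fig,
    }
    return build_report(context, workdir / cfg["report_template"],
                        results / "report.md",
                        report_date=cfg.get("report_date", "unset"))
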