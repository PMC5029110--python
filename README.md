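# ngsflow

A sample-sheet driven workflow engine and analysis toolkit for
next-generation sequencing (NGS) experiments — RNA-Seq, Ribo-Seq, ChIP-Seq
and similar applications whose analyses chain external command-line tools
(read preprocessors, aligners, callers) with downstream statistics.

The problem it addresses: NGS analyses are multi-step pipelines over many
samples, mixing external executables with in-library statistics. Running
them by hand is error-prone (mismatched file names, silently missing
samples, non-restartable half-finished runs) and hard to reproduce. ngsflow
makes the *sample sheet* the single source of truth and every workflow step
a declarative, restartable object.

## Design

Two small TSV formats define a workflow:

- **targets file** — the sample sheet: per-sample input paths, sample names,
  condition factors, and named comparison (contrast) sets declared in
  `# <CMP> CMPset1: A-B, A-C` header lines.
- **param file** — a command template for one external tool: the executable,
  ordered argument slots, and placeholder tokens
  (`<FileName1> <FileName2> <SampleName> <OutFile> <Reference>`)
  substituted per sample.

A `SysArgs` step object renders one argument vector per sample, registers
every input and expected output, and chains: the next step's targets table
is derived automatically from the current step's outputs, so sample names
and contrasts propagate through the whole workflow. The runner executes
steps serially or on a local process pool with per-job logs and an
append-only JSONL status registry; completed samples (all expected outputs
exist non-empty) are skipped on rerun, so restarting after a crash runs
exactly the missing samples. Commands are executed as argument vectors,
never through a shell.

Around the engine sit the analysis operators NGS workflows share:

- streamed FASTQ preprocessing (adaptor/quality trimming, length and
  mean-quality filters) and an eight-panel quality/diversity summary
  (per-cycle quality percentiles, base proportions, mean-quality / length /
  duplication / GC histograms, distinct k-mer diversity, N proportion);
- alignment statistics and strand-specific read counting across **all**
  annotation feature types at once (a read counts once per feature type it
  overlaps by ≥ 1 bp, split by read strand);
- metagene coverage: nucleotide-resolution depth upstream/downstream of
  start and stop codons with the spliced CDS compressed into B bins of mean
  depth, all in 5′→3′ transcript orientation;
- ORF prediction on both strands (maximal ATG→stop runs per frame, internal
  ATGs suppressed, N-codons inert);
- n-way Venn intersects (disjoint occupancy regions for 2–20 sets, 2–5-way
  diagrams) and DEG-table filtering (`logFC`/`FDR` columns per comparison;
  positive logFC of `A-B` means higher in `A`);
- Markdown report generation from `{{field}}` templates, byte-reproducible
  given a fixed report date;
- a synthetic-data module (random genome, planted gene annotations, read
  simulation with ground-truth SAM) so everything is testable offline.

## Worked example

Generate and run the self-contained demo workflow (synthetic genome, 20
genes, 6 samples × 250 reads in three condition groups; the external
alignment step copies the simulator's ground-truth SAM files so the demo
needs no aligner installed):

```
$ ngsflow workenv rnaseq-mini demo
workflow environment created: demo
$ ngsflow run demo
report written: demo/results/report.md
$ ngsflow status demo align
A1      done (exit 0)
A2      done (exit 0)
B1      done (exit 0)
B2      done (exit 0)
C1      done (exit 0)
C2      done (exit 0)
```

Rerunning `ngsflow run demo` launches zero processes (every sample reports
`skipped`). The results directory holds the QC figure and TSVs; for example
`align_stats.tsv` shows every sample fully aligned, as expected for
ground-truth alignments:

```
label   total_reads  aligned  align_pct  secondary
A1      250          250      100.0      0
A2      250          250      100.0      0
...
```

and `deg_summary.tsv` / `venn_up_counts.tsv` enumerate the differentially
expressed genes per contrast and their overlap (synthetic DE table, cutoffs
|logFC| ≥ 1, FDR ≤ 0.05):

```
comparison  n_up  n_down  n_total          region       count
A-B         1     1       2                A-B          1
A-C         1     2       3                A-B & A-C    0
                                           A-C          1
```

`results/orfs.tsv` lists the 192 ORFs (≥ 60 nt) found on both strands of the
demo genome, longest first — the top entries are the planted gene CDSs.

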