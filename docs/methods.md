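# Methods

This note documents the models, conventions and numerical choices behind
ngsflow, and what the synthetic-data generator does and does not emulate.

## Workflow model

A workflow is a chain of steps. Each step is instantiated from a sample
sheet (*targets* table) and a command template (*param* file) into a
`SysArgs` object holding, per sample, a fully substituted argument vector
and the registered input/expected output paths. Chaining replaces each
sample's `FileName1` with the step's first (canonical) output while
preserving sample names, factors, extra columns and comparison sets, so the
initial sample sheet is the only hand-written input.

Conventions chosen where the formats were open:

- Targets/param files are TSV. Comparison sets are declared in comment
  lines with the literal sentinel `# <CMP>`, as `SETNAME: A-B, A-C`
  (hyphen-separated factor pairs). This is the smallest grammar that can
  express named multi-contrast sets in a plain-text header.
- Sample names are restricted to `[A-Za-z0-9_.-]`, factors to
  `[A-Za-z0-9_.]` (no `-`, which separates the factors of a pair). The
  restriction keeps labels safe inside file names and contrast syntax and,
  together with the fixed five-token placeholder vocabulary, means data
  files cannot inject arbitrary shell text.
- Commands are rendered as argument vectors and executed without a shell.
  Display strings are a plain join of the tokens.
- *Completed* means: every expected output exists with size > 0. Zero-byte
  files are treated as failures because crashed tools routinely leave empty
  outputs behind. Partial outputs of failed jobs are renamed with a
  `.failed` suffix so they can never satisfy the completion check.
- The status registry is an append-only JSONL file per step. Each record is
  written with a single `O_APPEND` write, which is atomic for short lines,
  so concurrent pool workers can share one registry. The last record per
  sample wins.
- No automatic retries: restart semantics make reruns cheap and explicit,
  and silent retries would mask systematic tool failures.
- The parallel backend is a local process pool with per-sample
  independence; the parallel-map contract (same results as serial, row
  order restored) is the extension point for cluster schedulers, which are
  out of scope here.

## FASTQ statistics

Quality encoding is fixed to Phred+33 and treated as a declared input
property; characters below `!` raise an error rather than triggering
auto-detection, which is unreliable on short or high-quality files.

The summary is a single streaming pass over batches of at most
`batch_size` reads. Per-cycle statistics accumulate into per-cycle
histograms over the 94 possible quality values, from which exact
min/Q1/median/Q3/max/mean are derived at the end (percentiles use the same
linear-interpolation definition as `numpy.percentile`), so results are
bit-identical for any batch size. The duplication histogram counts exact
full-sequence multiplicities and the k-mer diversity panel counts distinct
k-mers ending at each cycle; both keep one entry per *distinct*
sequence/k-mer, so memory is bounded by library diversity rather than file
size — the right trade-off at QC scale, documented rather than hidden.
GC fractions are binned into 50 fixed-width bins. Subsampling uses
reservoir sampling with an explicit seed.

Adaptor trimming removes the longest read suffix that exactly matches a
prefix of the adaptor, with a minimum overlap; mismatch-tolerant trimming
is deliberately out of scope (dedicated trimmers do it better, and the
exact rule is easy to reason about in tests).

## Counting and coverage

Coordinates are 1-based inclusive everywhere externally (GFF3/SAM native);
0-based indexing exists only inside depth arrays. Reference blocks are
derived from CIGAR strings with M/=/X/D extending the current block and
only N (skipped region, i.e. intron) splitting it; I/S/H/P consume no
reference.

Feature-type counting is type-level: a read counts once per feature *type*
it overlaps (≥ 1 bp, any block), not once per feature, because the
intended readout is the distribution of reads over annotation categories.
Only primary alignments count; each mate counts independently. Features
with strand `.` match any read strand in sense/antisense modes. An
interval tree per chromosome makes the scan near-linear; a quadratic
all-pairs oracle in the tests pins the semantics.

Metagene coverage locates the start codon at the first 3 nt and the stop
codon at the last 3 nt of the spliced CDS in transcript orientation (stop
assumed included in the CDS span). Upstream/downstream flanks are reported
5′→3′; positions off the chromosome contribute depth 0. The spliced CDS of
length L is cut into B contiguous bins with boundaries ⌊iL/B⌋ (the last
bin absorbs the remainder); each bin reports mean per-nt depth. Transcripts
without CDS records, or with spliced CDS shorter than B (or than the 6 nt
needed for both codons), are skipped with a warning. Aggregation sums
vectors across transcripts.

## ORF prediction

Per frame and strand, scanning walks codons left to right: the first ATG
after the previous stop opens an ORF, the next in-frame stop closes it
(stop included), and scanning resumes beyond that stop — so internal ATGs
sharing a stop are suppressed in favour of the maximal ORF. Codons
containing N are inert: they never match start or stop and never terminate
scanning. Minus-strand ORFs are found on the reverse complement and mapped
back with start′ = L − end + 1. Results sort by descending length, then
ascending forward start, then `+` before `−`; `longest_disjoint` greedily
keeps top-ranked ORFs that do not overlap already kept ones. ORFs running
off the sequence end are reported (truncated to the last complete codon)
only when `require_stop` is off.

## Venn intersects and DEG filtering

`overlapper` assigns every element of the union to exactly one region — the
subset of sets containing it — so region counts always sum to |union|.
Full-region mode is capped at 20 sets (2^n − 1 regions). Diagrams for 2–5
sets use circle/ellipse layouts; region label positions are located
numerically by rasterizing the shapes and taking, for each occupancy
region, the region point nearest its centroid. This guarantees every label
sits inside its region for any layout, without hand-tuned coordinates.

DEG filtering consumes tables with `<comparison>_logFC` and
`<comparison>_FDR` column pairs. A gene is up in `c` iff logFC ≥ lfc_min
and FDR ≤ fdr_max, down iff logFC ≤ −lfc_min and FDR ≤ fdr_max; missing
values never pass. Sign convention: positive logFC of comparison `A-B`
means higher abundance in `A`. At the degenerate cutoff lfc_min = 0 a
logFC of exactly 0 is assigned to *up* so the two lists stay disjoint. FDR
is consumed, never computed — multiple-testing correction belongs to the
upstream differential-expression tool.

## Reports

Reports are data-driven Markdown: `{{field}}` placeholders resolve from a
context of strings, tables (rendered as Markdown tables) and file paths
(verified to exist). Rendering is deterministic given the context and a
fixed report date, so regeneration is byte-identical; rendered sections are
cached next to the report keyed by a digest of their input value. Literate
code-chunk evaluation and PDF output are out of scope: the reproducibility
contract (regenerable, state-driven reports) is preserved without
embedding a document-language runtime.

## Synthetic data

`make_genome` draws i.i.d. bases with P(G) = P(C) = gc/2. `make_annotation`
plants non-overlapping genes: each CDS is written into the genome as an
in-frame guard stop, ATG, sense codons, stop — so every CDS is exactly one
maximal ORF on its strand, giving ORF prediction and coverage tools exact
ground truth. `simulate_reads` draws read starts uniformly within genes
(fraction `transcript_frac`, on the gene's strand) or uniformly on the
genome, applies i.i.d. substitution errors, writes Phred+33 qualities from
a per-cycle decay model Q(c) = clip(40 − 0.15c + N(0, 3), 2, 40), and emits
the true alignments as SAM (all-match CIGAR, MAPQ 60).

What the generator does **not** emulate: spliced reads (gene models are
effectively single-exon at the CDS level, so CIGARs contain no N), indels,
paired-end fragments, coverage biases (GC, positional), duplicated reads
from PCR, quality-dependent error profiles, and adapter read-through.
Passing tests therefore demonstrate correctness of the counting, coverage,
ORF and workflow logic under clean conditions — not robustness to the
artefacts of real libraries, which enter through the external tools a real
workflow would invoke.

## Problem sizes

The default test and acceptance runs use desk-scale instances chosen to
exercise every code path with exact oracles: 15–40 kb genomes, 10–40 genes,
400–1000 reads of 50 nt, 6–8-sample workflows, 100-instance oracle suites
(2-kb sequences for ORFs, ≤ 6 sets × ≤ 500 elements for Venn). The
streaming design is what makes larger inputs a matter of waiting, not of
memory.
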