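# chemoseq

A desk-scale, fully tested pipeline for tissue-enhancement profiling from
single-end short-read RNA-seq of paired tissue/body samples in two sexes
(e.g. chemosensory appendages vs whole bodies):

1. **simulate** — synthetic gene-level transcriptome (with optional
   near-identical paralog pairs), six tissue/sex-structured abundance
   profiles with designated enhanced gene sets at controlled fold changes,
   and FASTQ read libraries with full ground truth.
2. **mapping** — uniform 5'/3' end trimming (4 / 12 nt defaults), then
   mismatch-tolerant mapping (≤ 3 mismatches by default) to a
   gene-condensed transcriptome via a k-mer seed index with pigeonhole
   guarantees; all placements on both strands are reported, isoform hits
   collapse to gene membership.
3. **quantify** — unique and weighted read counts (equal 1/k split across
   ambiguous genes, or a rescue scheme proportional to unique evidence) and
   RPKM = 1e9 · C / (L · N) expression values, plus per-sample summaries.
4. **enhance** — per-gene two-sided Fisher's exact test on weighted counts
   (gene reads vs remaining mapped reads per sample), Bonferroni
   family-wise control, a 2-fold RPKM ratio filter with a 0.10 pseudo-value
   for zero RPKMs, and volcano-plot tables.
5. **comparative** — Venn overlaps of enhanced gene sets, ranked PfamA
   tallies, family RPKM profile matrices, sensilla-count / co-receptor
   normalization factors, and recovery scoring against simulated truth.

## CLI

```sh
chemoseq simulate --config examples/sim.yaml --outdir out --seed 1
chemoseq map --transcriptome out/transcriptome.fasta --fastq out/FA.fastq --out hits.tsv
chemoseq compare --counts out/expression_table.tsv --a FA --b FB --ntests 500
chemoseq profile --counts out/expression_table.tsv --annotation out/annotation.tsv --family Or
chemoseq evaluate --records out/comparison_FA_vs_FB.tsv \
    --truth-labels out/truth_labels.tsv --comparison FA_vs_FB
chemoseq run-all --config examples/sim.yaml --outdir out --seed 1
```

A config YAML takes either a `simulate:` block (synthetic run with ground
truth and recovery metrics) or an `inputs:` block pointing at a
transcriptome FASTA (`GENE|isoformN` headers), an annotation TSV
(`gene_id`, `length`, optional `family`/`pfam`) and one FASTQ per sample
label (FB, FA, FP, MB, MA, MP). See `examples/sim.yaml`.

Expression tables use a six-sample TSV dialect (gene ID, transcript length,
RPKM / unique hits / total weighted hits per sample) that the `compare`
and `profile` subcommands can re-ingest directly; `read_counts_table`
accepts externally produced tables in the same dialect, with an optional
per-sample mapped-total override.

## Conventions

- Coordinates 0-based half-open internally; 1-based only in prose.
- Weighted counts are rounded half-up before the exact test.
- p-values floored at 1e-300; volcano −log10 p capped at 300.
- Reported factors round to one decimal, percentages to integers; machine
  outputs always retain full precision.
- All randomness derives from one master seed; reruns are byte-identical.
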