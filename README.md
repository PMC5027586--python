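# groseqtk

Integrative analysis of nascent transcription (GRO-seq) and ChIP-seq,
re-implemented as a tested, reusable pipeline:

* **de novo nascent-transcript detection** from stranded, binned coverage —
  initiation when the 200-bp window density rises 3-fold over the previous
  window, transcript splits when the "bodyFold" change exceeds 3-fold, with
  explicit closure and trimming semantics;
* **promoter-proximal pausing index** (PPI) per gene, with Kruskal–Wallis /
  Dunn group comparisons;
* **differential transcription** via a negative-binomial exact test
  (method-of-moments common dispersion, conditional on the pooled sum) with
  Benjamini–Hochberg FDR and the gene gates RPKM ≥ 0.5, FDR ≤ 0.01,
  |log2FC| ≥ 0.585 (enhancer gates: FDR ≤ 0.05, |log2FC| ≥ 1);
* **eRNA enhancer calling** — intergenic enhancers are two opposing
  transcripts within 1 kb of each other, > 3 kb from every gene TTS and
  outside genes; intragenic enhancers are short (150–500 bp) transcripts
  antisense to their host gene overlapping an H3K4me2 interval, quantified
  on the antisense strand only;
* **ChIP-seq integration** — 4-fold-enrichment peak calling on signal
  normalized to 10⁷ mapped tags with a normalized-tag ≥ 10 gate and
  replicate consensus, genomic categories, three-timepoint Venn categories,
  peak-to-gene association within ±50 kb of the TSS, and the pairwise
  min-set ("maximal overlap percentage") co-occurrence matrix with
  Euclidean average-linkage clustering;
* **synthetic-data generator** — genomes, gene annotations, stranded
  GRO-seq coverage, ChIP coverage and a serialized ground truth, so every
  stage is testable offline against planted features.

## CLI

One entry point with a sub-group per stage:

```bash
# synthetic fixtures (bedGraph + GFF3/BED12 + truth TSVs + manifest)
groseqtk sim generate --config sim.yaml --out fixtures/ --seed 1

# transcript detection from per-strand bedGraph
groseqtk transcripts detect --plus f_plus.bedgraph --minus f_minus.bedgraph \
    --chrom-sizes fixtures/chrom.sizes --out transcripts.bed

# differential transcription (counts + design TSVs)
groseqtk diff run --counts counts.tsv --design design.tsv --gates genes --out diff.tsv

# enhancer calling
groseqtk enhancers call --transcripts transcripts.bed --genes genes.gff3 \
    --h3k4me2 h3k4me2.bed --out enhancers.tsv

# ChIP peak calling and integration
groseqtk chip call --treatment fixtures/chip_AR_t2_rep1 --control fixtures/input_AR_t2_rep1 --out peaks.bed
groseqtk chip consensus --rep1 p1.bed --rep2 p2.bed --out consensus.bed
groseqtk chip venn --a t05.bed --b t2.bed --c t4.bed --out venn.tsv
groseqtk chip associate --peaks peaks.bed --genes genes.gff3 --diff diff.tsv --out assoc.tsv
groseqtk chip cooccur --bed AR peaks_ar.bed --bed ERG peaks_erg.bed --out matrix.tsv

# full pipeline: simulate -> detect -> quantify -> classify -> integrate
groseqtk pipeline run --config run.yaml --out run/ --seed 1
groseqtk pipeline eval --run-dir run/
```

`pipeline run` writes every stage output plus `eval_report.json` (recovery
and false-call rates against the planted truth) and a checksummed
`manifest.json`; reruns with the same configuration and seed are
byte-identical.

## Conventions

bedGraph/BED are 0-based half-open; GFF3 is 1-based closed and converted on
read. Coverage is binned (default 50 bp); interval overlap is ≥ 1 bp on
half-open intervals throughout. All randomness flows from one seeded
generator — there is no global random state.

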