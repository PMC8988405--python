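# trnakit

Toolkit for bulk tRNA-seq expression analysis in genomes with highly
redundant tRNA gene complements, built around a bovine two-tissue
(skeletal muscle, liver), three-treatment study design.

## The problem

Mammalian genomes carry hundreds to over a thousand predicted tRNA genes,
many of which are exact sequence duplicates of one another.  A sequencing
read from a mature tRNA therefore cannot be attributed to a single locus.
`trnakit` resolves this by collapsing loci into **sequence groups** —
equivalence classes of genes with byte-identical mature (intron-spliced,
CCA-less) sequences — and carrying out all expression analysis at that
level, reporting every member locus alongside each result.

On top of that core it provides:

- **Quantification** — CPM normalization, a presence filter (a feature is
  expressed in a tissue when it has nonzero counts in ≥ 2 distinct
  individuals), anticodon-level aggregation, and per-anticodon
  expressed-copy proportions.
- **Differential expression** — an edgeR-style count pipeline authored here:
  TMM normalization factors, a pooled method-of-moments negative-binomial
  dispersion φ (Var = μ + φμ²), a two-sided exact test on the conditional
  distribution of the group-A count sum given the total, Benjamini–Hochberg
  FDR, and calls requiring both p ≤ 0.05 and FDR ≤ 0.05.  Features enter
  testing only if CPM ≥ 5 in all control samples, or all ART-normal
  samples, or at least two ART-LOS samples.
- **Codon usage** — per-gene codon frequencies from CDS FASTA, RSCU
  (observed count over the family-uniform expectation, so ΣRSCU = family
  size) and RAC (count over the family maximum), restricted to genes with
  ≥ 1 TPM in ≥ 2 replicates, plus wobble decoding rules
  (G34→{C,U}, U34→{A,G}, C34→{G}, A34→{U} or {U,C,A} with inosine) and
  anticodon–codon concordance per amino-acid family.
- **Correlations and partitions** — tRNA abundance vs gene copy number,
  family-percentage RSCU vs anticodon expression paired through
  Watson–Crick decoding, and shared/unique expressed-sequence partitions
  across tissues and treatments.
- **DMR proximity** — tRNA genes within an inclusive 5 kb window of
  differentially methylated regions, each pair annotated with the number of
  loci sharing the gene's exact sequence.
- **Synthetic data** — fully seeded generators (annotation with controlled
  duplication, NB counts with spikes and silencing, CDS sets with codon
  bias, planted DMRs) that record their ground truth, so every stage is
  testable without any download.

## Worked example

```bash
trnakit simulate --seed 11 --outdir fixture/
trnakit run-all \
    --gff fixture/trna.gff3 --fasta fixture/genome.fa \
    --counts fixture/counts.tsv --samples fixture/samples.tsv \
    --cds fixture/cds.fa --tpm fixture/tpm.tsv \
    --rna-samples fixture/rna_samples.tsv \
    --dmrs fixture/dmrs.bed --outdir out/
```

prints

```
{
 "stages": [
  "annotation",
  "codonusage",
  "correlate",
  "detest",
  "dmr",
  "quantify"
 ]
}
```

and `out/` then holds, among others, `groups.tsv` (the locus→sequence-group
partition), `de_muscle_control_vs_los.tsv` (per-group mean CPMs, log2 fold
change, p, FDR, call and direction for that contrast), `concordance.tsv`
(whether each amino-acid family's top-expressed anticodon Watson–Crick
pairs its most frequent codon), `dmr_trna_pairs.tsv` (DMR–gene distances
with identical-locus counts) and `manifest.json` (parameters plus input and
output checksums — rerunning with the same inputs reproduces every checksum
exactly).

The same functionality is available as a library:

```python
from trnakit.annotation import parse_trna_annotation, collapse_identical_sequences
genes = parse_trna_annotation("trna.gff3", "genome.fa", mito_contig="MT")
groups = collapse_identical_sequences(genes)   # loci -> unique sequences
```

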