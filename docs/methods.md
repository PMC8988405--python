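# Methods

## Sequence-group model

The unit of analysis is the *sequence group*: the set of annotated tRNA loci
whose mature sequences are byte-identical after intron removal and
reverse-complementation to the coding orientation, in the RNA alphabet and
without the post-transcriptionally added 3' CCA.  Grouping is an exact
string partition — no mismatch tolerance, no clustering — because a read
that matches several identical loci carries literally no information about
its locus of origin, while a single-base difference already separates
isodecoders.  Two consequences drive the rest of the design:

- locus-level expression flags are inherited from the group (a locus is
  called expressed iff any locus with the same sequence shows reads), and
- every group-level result lists all member loci, so downstream users can
  see when locus attribution is masked (the DMR report carries this count
  explicitly).

Identical sequences annotated with conflicting anticodons are treated as a
hard annotation error rather than silently merged.

Coordinates are 1-based inclusive internally (the GFF3 convention); BED
input is converted from 0-based half-open on read and back on write.
Anticodons are kept in the RNA alphabet and codons in DNA; the two meet only
at the reverse-complement pairing boundary.

## Expression filtering

A feature is *expressed* in a tissue when its raw count is > 0 in at least
`min_individuals = 2` distinct individuals of that tissue, identified by the
sample sheet's `individual` column so technical replicates never satisfy the
rule alone.  "Present" is deliberately raw-count-nonzero rather than a CPM
threshold: the CPM ≥ 5 rule belongs to the differential-expression
prefilter, which keeps a feature iff CPM ≥ 5 (inclusive) in *all* control
samples, or *all* ART-normal samples, or ≥ 2 ART-LOS samples.  The looser
LOS clause reflects the expectation that the syndrome group is the most
heterogeneous.  log2 CPM uses a pseudocount of 1 so zeros map to zero.
Unassigned reads are excluded from library sizes, matching a
count-on-annotated-features workflow.

## Differential expression

The DE engine re-creates the classic exact-test pipeline for small-n count
data:

- **TMM factors.** The reference sample is the column whose upper quartile
  of scaled counts is closest to the mean upper quartile (lowest index on
  ties).  Log ratios M are trimmed 30% on each side, absolute intensities A
  5% on each side, and the surviving M values are averaged with
  delta-method precision weights; factors are rescaled to geometric mean 1.
- **Dispersion.** One common φ across features, by method of moments on
  counts rescaled to a common effective library size: within each group,
  E[s² − μ̄] = φμ̄², so φ̂ is the ratio of pooled (degrees-of-freedom
  weighted) sums, floored at 0.  Moment estimation was chosen over
  conditional maximum likelihood deliberately: it is transparent, fast, and
  its accuracy requirements here are set by the test's calibration, which
  the suite verifies directly (type-I error within 0.05 ± 0.02 at
  φ ∈ {0, 0.1, 0.4}).  Numerical agreement with any external tool is
  explicitly not a goal.
- **Exact test.** Counts are rescaled to a common TMM-adjusted library size
  with deterministic rounding (`numpy.rint`).  Conditional on the total
  y_A + y_B, the group-A sum is distributed as the normalized product of
  NB(n_A μ, φ/n_A) and NB(n_B μ, φ/n_B) masses, with μ the pooled per-sample
  mean; at φ = 0 this is the binomial split.  The two-sided p-value sums the
  probabilities of all outcomes no more likely than the observed one (with
  a 1e-10 log-tolerance for ties), which makes the test exactly symmetric
  under swapping groups.  All-zero features get p = 1.
- **Calling.** BH step-up FDR (via statsmodels) and the conjunctive rule
  p ≤ α AND FDR ≤ α, both inclusive, α = 0.05.  Fold changes are computed on
  mean CPM with a 0.5 pseudocount to avoid infinities.

Unwanted-variation correction (RUV-style factors) is not implemented; the
study's negative-control genes are not enumerable here.  The pipeline can be
run with externally computed normalization factors instead of TMM.

## Codon usage

RSCU follows the classical definition: observed codon count divided by the
family-uniform expectation (family total / family size), so family RSCUs sum
to the family size.  RAC divides by the family maximum.  Terminal stop
codons are excluded from counting; ambiguous codons are skipped
individually; a CDS length not divisible by 3 skips the gene with a QC
entry; internal stops are counted but flagged.  Per-group profiles average
per-gene RSCU/RAC unweighted over expressed genes, excluding genes where a
family is entirely absent (counting them as zero would bias short genes);
a pooled-counts mode is available for comparison.  Stop codons and
selenocysteine recoding are out of scope; SeC and iMet annotations are
carried as distinct labels and excluded from the 20-family analyses.

Wobble decoding at anticodon position 34 (first base 5'→3'): G34 reads
codon-third-position C/U, U34 reads A/G, C34 reads G only, and A34 reads U —
or U/C/A when A34 is assumed deaminated to inosine (the default, as in
mammalian cytosolic tRNAs).  Concordance asks, per amino-acid family,
whether the top-expressed anticodon's Watson–Crick codon equals the
family's most frequent codon; families with no expressed anticodon are
excluded from the denominator and listed.

## Correlations and partitions

Expression entering correlations is per-anticodon (or per-group) mean CPM
across the relevant samples, not log-transformed by default, since CPM is
the working unit throughout; a log2 option exists.  For usage–expression
correlation, per-family percentages (values scaled to sum 100 within each
amino-acid family) are computed first and anticodons are paired with their
Watson–Crick codons; anticodons absent from the annotation are excluded
rather than zero-filled — they are unannotated, not unexpressed.
Shared/unique partitions enumerate all nonempty membership patterns of 2–3
expressed-sequence sets with the union as the percentage base.  Pearson r
uses the two-sided t-test with n − 2 degrees of freedom (scipy); constant
vectors are an error rather than NaN.

## DMR proximity

Distances are gaps between closest interval ends, 0 on overlap; the window
is inclusive ("within 5 kb" admits a gap of exactly 5,000 bp, and the
boundary is unit-tested on both sides).  A DMR intersecting the gene span is
reported as `overlap_gene_body`.  Strand is ignored.  Inputs must share an
assembly; no liftover is attempted.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their parameters and a seed, and
return the planted truth alongside the data.  Defaults mirror the study
shape: two tissues × three treatments with 13 animals per tissue (5 control,
4 + 4 treated; per-treatment sizes are not fixed by the study description
and are configurable), the same individuals sampled in both tissues,
library sizes log-uniform over 0.5–2 × 10⁶ so CPM and TMM are exercised
nontrivially, and NB counts with configurable φ (default 0.1, a typical
bulk-RNA replicate dispersion).  tRNA bodies are random 72–90 nt sequences
carrying the anticodon at positions 34–36, with a controllable fraction of
exact duplicates per anticodon; the copy-number/expression relation can be
set to `proportional` (every locus contributes the same base rate) or
`independent` (group rates drawn regardless of copy number).

Deliberately not emulated: reverse-transcription stalls at modified
nucleosides and the resulting truncation/misincorporation patterns, adapter
artefacts, alignment ambiguity beyond exact sequence identity, and
tissue-specific codon bias in the CDS generator.  Passing tests therefore
demonstrate correctness of the statistical and combinatorial machinery
under the stated generative model, not robustness to those measurement
artefacts in real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale problem sizes
chosen to give the statistical checks adequate resolution: 1,000 features
for type-I calibration (binomial SE ≈ 0.007 at the 0.05 level), 300
features × 20 seeds for spike recovery, ~500 loci / ~280 groups for
correlation recovery, 500 genes for RSCU law-of-large-numbers checks.
Ties in TMM reference selection and in preferred-codon argmax break
deterministically (lowest index / lexicographic).  All rounding in the
exact test is `numpy.rint` (half to even).  Pipeline outputs contain no
timestamps, so reruns with identical inputs and seed are byte-identical;
the manifest records parameters and SHA-256 checksums of all inputs and
outputs.

## Known limitations

- A single common dispersion is shared by all features; strongly
  feature-specific overdispersion will inflate calls for the noisiest
  features (tagwise shrinkage is out of scope).
- The exact test conditions on totals after deterministic rescaling and
  rounding; for very large counts the discreteness correction is
  negligible, but for libraries differing by more than ~4-fold the
  rescaling approximation dominates the test's accuracy.
- Expression flags at locus level are group-inherited and therefore
  systematically optimistic for duplicated loci — by construction, this is
  the honest representation of what the data can support.
- The GFF parser targets the tRNAscan-SE/GtRNAdb dialect (name tokens
  `tRNA-<AA>-<anticodon>-<n>-<m>`, optional exon children, pseudogene /
  secondary-filtered markers); other dialects need explicit
  `amino_acid`/`anticodon` attributes.
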