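# Methods

This note documents the models, parameter choices and numerical conventions
behind `rnapile`, and what the synthetic benchmark does and does not show.

## Coordinates and formats

All genomic intervals are 0-based, half-open internally. GFF3 emission
converts to 1-based inclusive; BED-family outputs stay 0-based half-open.
FASTQ qualities are Sanger/Phred+33 with a flat profile (base-quality
realism is out of scope). SAM output encodes bridged reads as split
alignments with an `N` CIGAR operation across the intron.

## Synthetic study model

The generator emulates a two-condition short-read transcriptome experiment
(an unstressed baseline versus an acute stress time point, e.g. salinity
shock) at desk scale. Defaults, which are the conditions used by the test
suite and the acceptance script:

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 50 kb | large enough for ~50 non-overlapping genes, small enough for the exhaustive alignment oracle |
| planted repeat | one duplicated 300-bp segment | guarantees exact-duplicate 36-mers so the "multiple" class occurs |
| genes | 50, exons 2–5 × 120–300 bp, introns 60–200 bp | compact gene models; every exon exceeds the 100-bp fragment retention filter so discovery sensitivity is not confounded by fragment-length censoring |
| hidden fraction | 0.16 (floor → 8 genes) | withheld from the emitted GFF3; ground truth for unannotated-transcript discovery |
| reads | 36 bp, 60,000 per condition, unstranded | short-read era design; desk-scale depth |
| errors | 0.004 substitutions/base, 0.001 indels/read (1–3 bp) | typical early-platform error scale |
| contaminants | adapter 1.29%, foreign 0.96%, rRNA 0.81%, random 8.65% of reads | ≈11.7% unmapped in total, split in the proportions reported for unmapped-read categories in this kind of experiment (26.1% identifiable: adapter 11.0 / foreign 8.2 / rRNA 6.9 of unmapped; the rest mutually dissimilar random sequence) |
| abundance | log-normal, σ = 0.7 | smooth dynamic range at a depth where every expressed gene is well covered |
| fold changes | 6% of genes ×4 up, 8% ×4 down | see below |

Reads are drawn with expected count proportional to abundance × exon-model
length, with uniform start positions along the spliced transcript — the
simplest fragmentation model consistent with RPKM's length normalisation.
Each read's truth record stores its origin, planted errors, and its class:
*junction-spanning* (the error-free window crosses an exon boundary with ≥ 1
base on each side), *repeat* (the window's 36-mer occurs ≥ 2 times in the
genome by exhaustive canonical k-mer census), *genome-unique*, or
*contaminant*. Junction records also carry a `contiguous_match` flag: true
when the read's sequence additionally occurs contiguously in the genome
(then a 0-mismatch genomic alignment exists and the mapper's
genome-precedence rule deliberately reports `UNIQUE_GENOME`).

### Pool-conserving fold changes

A sequencing library samples a fixed number of reads from the mRNA pool, so
only relative concentrations are observable. If planted regulation changed
the total transcript mass appreciably, every unchanged gene would appear
spuriously regulated and RPKM ratios would be biased by the global mass
factor — acute at desk scale, where 50 genes make single-gene mass shares
percent-level. Stress responses of the kind emulated are roughly balanced
between induction and repression, and the generator plants them that way:
up-regulated genes are drawn from the 50th–85th abundance percentile
(measurable without dominating the pool), and down-regulated genes are then
chosen among the most abundant remaining genes such that the mass they
release best offsets the mass gained. Very extreme regulation (≥ 32×)
affects ~0.2% of genes in studies of this type — below the resolution of a
50-gene benchmark — and is therefore not in the defaults, though
`fold_change_spec` accepts any ratio and explicit gene lists. A small
residual composition bias (typically ≤ 2–3%) remains and is part of what
the fold-change-recovery checks absorb.

### CHASTITY filter

Per-cycle purity = highest channel intensity / (highest + second highest); a
read passes only if **every** cycle is ≥ 0.6 (threshold inclusive; a cycle
with all four channels zero is uncallable and fails). The all-cycles scope is
the strictest consistent reading of the filter's definition and is
configurable. The pipeline's simulated reads are all emitted as
filter-passed; `chastity_filter`/`simulate_intensities` expose the mechanism
itself.

## Mapper

Seed-and-extend with 12-mer exact seeds in three partitions (pigeonhole: a
≤ 2-mismatch alignment of a 36-bp read leaves one partition exact). Indel
placements (one contiguous 1–3 bp gap, zero mismatches — mismatches and
indels never combine) are found by additionally anchoring the first or last
12-mer, which by a second pigeonhole argument covers every gap position.
Alignments are ranked by stratum `(mismatches, indel length)`,
lexicographically, so a clean 1-bp-indel placement outranks a 1-mismatch
placement; this is a documented convention, and the exhaustive scorer in the
test suite — which tries every offset, strand and split point — is the
arbiter of the whole contract.

Conventions where multiple readings were possible:

- **Genome precedence.** Within the best stratum a genomic hit beats an SEJ
  hit; an SEJ hit that does not cross its junction is always redundant with
  the genome (flanks are genome substrings) and is dropped outright.
- **Bridged criterion.** ≥ 1 base on each side of the junction offset — the
  weakest criterion that makes "bridged" meaningful; configurable.
- **SEJ hits are mismatch-only.** An indel across a junction record has no
  unambiguous two-block genomic projection, and junction+indel reads are
  vanishingly rare at the modelled error rates; indel search therefore runs
  against the genome only.
- **Duplicate junctions** shared by transcripts at a locus are deduplicated
  by flank-interval pairs at SEJ construction, and bridged hits projecting
  to identical genomic blocks collapse to one hit at classification.
- Unstranded reads: both strands are always searched; the reported strand is
  the match strand. Exons shorter than the 40-bp flank truncate the flank;
  flanks never extend into the intron.

Unmapped reads are screened against adapter, foreign and rRNA references by
ungapped full-read identity ≥ 0.90 on either strand, assigned in priority
order adapter → foreign → rRNA, else "other".

## Quantification

- Library size `N` = unique-genome + unique-bridged reads of the sample.
- A genome-unique read counts for a gene when its alignment overlaps the
  gene's exons by ≥ 18 of 36 bases (majority rule; configurable); a bridged
  read counts for its junction's transcript's gene; reads qualifying for
  ≥ 2 genes are discarded (logged) — the simplest rule consistent with
  "uniquely mapped". The same rule, with fragment blocks as the exon model,
  prices fragment RPKM.
- Saturation analysis stratifies genes by final RPKM into [0,3), [3,30),
  [30,300), [300,∞) (left-closed; the two interior classes follow the
  conventional enumeration) and reports, per cumulative read prefix, the
  fraction of each stratum within ±5% of its final RPKM; genes with final
  RPKM 0 are excluded. At desk-scale N (~10⁵) these absolute RPKM strata
  degenerate (any covered gene is far above 300), so the saturation
  benchmark in the acceptance script runs the operation on a count-level
  simulation at published-library scale (9 increments × 3M uniquely mapped
  reads, 20,000 genes); the alignment-level wrapper is exercised on the
  pipeline fixture.

## Differential expression

G-test on the 2×2 {gene, rest-of-library} × {condition} table — the
standard two-library test for unreplicated count data; counts, not RPKM, are
tested (the only statistically coherent choice). The statistic is computed
cell-wise as `2 Σ O ln(O/E)` in the expected-frequency form `E = row·col/n`:
the algebraically equivalent margin-entropy form cancels catastrophically at
N ~ 10⁷. Zero cells contribute zero. No Williams/continuity correction by
default (a Williams flag exists). Genes with zero counts in both conditions
are excluded from testing and from the number of hypotheses. FDR control is
Benjamini–Hochberg step-up (via statsmodels; the step-up definition is
re-derived independently in the test suite). Reported ratios are
RPKM₁/RPKM₀ rounded to one decimal, "-" when RPKM₀ = 0; up/down is by ratio
≥ 1 / < 1. Without biological replicates the test measures sampling, not
biological, variability.

## Discovery and ORF triage

Pile-up depth uses genome hits plus both blocks of bridged reads (never the
intron between). Islands are maximal runs of depth ≥ 1 — raw depth is not
the retention criterion, the RPKM ≥ 2 filter is. Islands are joined when
≥ 1 bridged read overlaps both (transitively, via union–find); retention
requires pooled-condition RPKM ≥ 2 *and* length ≥ 100 bp (both inclusive).
A fragment is *annotated-locus* if any block overlaps any annotated gene's
extent — first to last exon, introns included, strand-agnostic (reads are
unstranded) — by ≥ 1 bp; else *unannotated*. Discovery pools both
conditions for the pile-up and reports expression per condition plus pooled.

ORFs are ATG-to-stop in any of six frames; the stop is required (ORFs
hanging off fragment edges do not count — conservative) and is excluded from
the amino-acid length; codons containing non-ACGT bases are untranslatable
barriers. Ties break by frame number then leftmost start. The translated
search aligns each six-frame translation locally (match +1, mismatch −1,
gap −2) against the supplied protein set; a hit needs identity ≥ 0.40 over
≥ 30 aligned residue pairs. Category precedence: similarity-hit, else ORF
≥ 20 aa, else neither. The pipeline's protein reference is generated from
half of the hidden genes' own ORFs plus random decoys, so all three
categories occur and the partition identity is testable end to end.

## What passing tests do and do not show

The synthetic genome is i.i.d. random apart from one planted duplication:
real genomes have repeat families, paralogy, GC structure and alternative
splicing, none of which are modelled. Hidden-gene junctions are absent from
the SEJ library by construction, so hidden multi-exon genes are recovered as
per-exon fragments — the expected behaviour of annotation-based junction
libraries, and the reason junction-recall checks condition on junctions the
library contains. Uniform fragmentation ignores coverage bias; the error
model is homogeneous; there are no biological replicates. Passing therefore
demonstrates algorithmic correctness of mapping, accounting identities,
calibration of the test statistic, and recovery of planted signal under the
stated model — not performance on real libraries.

## Problem sizes

Test-suite and acceptance problem sizes (50–60k reads per condition against
100 kb; a 30-kb single-chromosome study for the exhaustive-oracle and
per-module tests; 20 replicates × 2,000 genes for calibration; 20,000 genes
× 9 increments for saturation) were chosen so each check has clear
statistical resolution while the whole suite remains a desk-scale
computation. All randomness flows from explicit seeds; identical configs
give byte-identical outputs.
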