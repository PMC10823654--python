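# Methods

## The question and the two arms

Clinically classified germline variants in the mismatch-repair genes are
traced to two candidate origins.  The *phylogenetic arm* asks whether a
human variant's alternate allele is the aligned (wild-type) state of
other vertebrates in a multiple whole-genome alignment: widespread
sharing, especially in species close to humans, would indicate
cross-species conservation.  The *archeological arm* asks whether the
same variants are present in ancient human sequencing data once
postmortem damage has been controlled for: sharing concentrated in
recent millennia indicates an origin inside human history.  Both arms
consume one normalized catalog, and one statistical layer compares their
outputs.

## Variant catalog

ClinVar-style significance strings collapse to three working classes —
PV (Pathogenic, Likely pathogenic, Pathogenic/Likely pathogenic),
BV (Benign, Likely benign, Benign/Likely benign), VUS (Uncertain
significance).  Records with conflicting interpretations never enter the
analysis; the drop count is logged.  Genomic coordinates are 1-based
VCF-convention throughout the package; the MAF boundary converts
explicitly to 0-based half-open.  Indels are VCF-style anchored on the
base before the event.

HGVS c. conversion supports the grammar the analysis needs:
substitutions, del/ins/dup with explicit spans, and intronic ±M offsets.
`c.1` is the first base of the translation start; intronic offsets count
from the nearest exon boundary, switching from `+M` to `−M` at the
intron midpoint (ties go to `+`).  On minus-strand transcripts alleles
are reverse-complemented to the genome forward strand.  The converter
guarantees `genomic_to_cds(cds_to_genomic(x)) = x` for substitutions and
plain del/ins names; `dup` input is accepted and canonicalized to an
anchored insertion.  Offsets beyond half the intron are not validated —
the catalog's variants never exercise that regime.

Effect classification is deliberately minimal: splice means within 2 bp
of an exon/intron boundary on the intron side; CDS indels are
frameshift iff the length change is not a multiple of 3; CDS SNVs are
classified by translating the affected codon (synonymous / missense /
stopgain / stoploss).  One transcript model per gene is assumed.  A
reference-allele mismatch at the variant position is a hard error, since
it almost always means a coordinate-system bug rather than bad data.

## Cross-species sharing

MAF blocks are parsed preserving score, strand and srcSize (e/i/q lines
are skipped).  For each variant, the footprint is the ref-allele span —
one column for a SNV, the deleted span for a deletion, the anchor column
(plus any following reference-gap columns) for an insertion.  A species
is *shared* iff its observed footprint equals the alternate-allele
footprint, case-insensitively; a base matching neither allele is
not-shared (no third category is defined); gaps and unaligned spans are
missing data.  Design choices made where the convention was genuinely
open:

- Overlapping blocks: the highest-scoring covering block wins, ties by
  file order; a lower-scoring block never rescues a missing call.
- Soft-masked (lowercase) bases are compared case-insensitively but
  flagged `masked` in the output, preserving auditability of
  repeat-masked columns without discarding them.
- Deletions count as shared when the species shows the post-deletion
  haplotype (anchor retained, deleted columns gapped); an entirely
  gapped footprint is missing, not shared.
- Sharing is evaluated on genomic alignment columns for all variants,
  including splice-region ones.

Aggregation attaches each species' clade and its patristic distance to
the reference leaf, emits species in tree display order (the
reference-containing side of every split first, written child order
otherwise, no ladderization or re-rooting), and produces per-clade
groups of per-species shared-PV counts for the Kruskal–Wallis
comparison.  Domain overlap uses half-open BED intervals (start inside,
end outside); overlapping intervals are merged with a warning.

## Ancient-DNA arm

Postmortem cytosine deamination in single-stranded overhangs reads as
C→T near the molecule 5′ end and G→A near the 3′ end.  All offsets are
computed in original-molecule orientation: for a reverse-strand
alignment the molecule 5′ end is the rightmost reference position.  This
matters twice — a forward C>T call supported by a reverse-aligned read
is a molecule G>A event, so its damage-relevant end is the molecule 3′.

- **Profile**: `ct5[o]` = fraction of reference-C positions at molecule
  5′ offset `o` read as T (symmetrically `ga3`).  Offsets with zero
  opportunities are undefined (missing), never zero.  A weighted
  least-squares fit of `d0·exp(−λ·o)` over both ends summarizes the
  profile.
- **Rescaling**: a candidate damage product (T-over-C near 5′,
  A-over-G near 3′) has its quality capped at `round(−10·log10 p)` where
  `p` is the profiled rate at that offset (rate 0.5 → Q3).  Other bases
  never change.  True-variant reads at terminal offsets are capped too —
  the rescaler cannot distinguish them; the caller's depth does.
- **Calling**: mpileup-style presence/absence per position over mapped,
  non-duplicate reads with base quality ≥ 1 (the minimum the source
  protocol used); any non-reference allele with ≥ `min_alt` (default 1)
  qualifying reads is emitted, so allele counts sum to depth.  No
  diploid genotype likelihoods — sharing is presence-based.
- **Filter**: "within 2 bp" means offsets 0 and 1.  Alt-supporting reads
  at terminal offsets are discounted for C>T/G>A calls; a call with no
  surviving support is `DAMAGE`, with fewer than `min_alt` survivors
  `LOWSUPPORT`, otherwise `PASS` with the surviving count.  The per-read
  discount is the reproducible formalization of what is otherwise done
  by visual assembly inspection.
- **Matching and chronology**: exact (chrom, pos, ref, alt) matches of
  PASS calls against the catalog, per class; an optional reference
  checksum guards against build mismatches.  Date ranges resolve to
  midpoints; a midpoint exactly at the cutoff (default 10,000 BP) counts
  as within.  Carrier-level fractions are over sharing modern-human
  samples; PV-level fractions date each PV by the *oldest* midpoint
  among its modern-human carriers.  Archaic hominins (Neanderthal,
  Denisovan, hybrid) are tabulated separately and never enter
  modern-human time bins.  The genomic intervals of the four human MMR
  genes on hg19 ship as `MMR_GENE_REGIONS_HG19` for real-data windowing.

## Statistics

Kruskal–Wallis H on mid-ranks with the tie correction
`1 − Σ(t³−t)/(N³−N)`; P from the chi-squared approximation with k−1 df;
a pooled sample of identical values yields H = 0, P = 1; a single group
is refused.  Benjamini–Hochberg is the standard step-up.  Chi-squared is
Pearson's without continuity correction (a Yates flag exists).
Percentages are rounded half-away-from-zero to one decimal.  BH families
are the minimal faithful grouping: the four per-gene class comparisons
form one family; the clade comparison is its own.  At N ≤ 10 the
chi-squared approximation to the KW null deviates from the exact
permutation distribution by up to ~0.1 in P — the property test asserts
tracking within an absolute band, not exactness.

## Synthetic data: what it emulates, and what it does not

The generator is the package's study bench.  Defaults: 20 species in 8
clades (reference species first), an 8 kb reference carrying four
three-exon gene models on alternating strands, 14 PV + 14 BV + 14 VUS +
4 conflicting catalog records cycling through the effect categories, 20
ancient individuals spanning six continent-level regions and 45,045–100
years BP including two archaic hominins, coverage 30×, read length 60,
and damage `d0 = 0.3`, `λ = 0.3`.  The damage magnitudes are synthetic
conventions in the range damage-profiling tools report for genuinely
ancient libraries, not values taken from any particular dataset; they
are deliberately high enough to exercise every filter.  Read length and
reference size are desk-scale choices that keep a full run in seconds
while leaving >50 read starts per position-of-interest.

Planted structure: sharing probability per (variant, species) is a
class base rate (PV 0.12, BV 0.55, VUS 0.30) scaled by clade distance,
reproducing the qualitative gradients of interest — benign variants
widely shared, pathogenic variants shared mostly by distal clades; 5%
of non-shared cells are planted missing.  The damage model is
single-stranded-overhang style: independent per-base Bernoulli flips
with exponentially decaying probability from each molecule end.  Reads
are uniform with fixed length, constant Phred 37 qualities (artifacts
keep the emitted quality — distinguishing them is the rescaler's job),
and alignment blocks are cut every ~40 reference bases but never through
a variant footprint, since the lookup treats a footprint split across
blocks as uncovered.

Not emulated: sequencing error, indel error, contamination,
fragment-length and GC bias, alignment error, multi-transcript genes,
population allele frequencies.  Passing tests therefore demonstrate the
*logic* of the pipeline — coordinate handling, strand handling, the
filters, the planted-truth bookkeeping — not robustness to every noise
mode of real archives.

One property of the damage model is worth stating plainly: with
`λ = 0.3` the exponential tail places C→T artifacts at interior read
offsets often enough that, at 30× and presence-based calling with one
supporting read, artifact calls at catalog C>T/G>A positions are
expected in any cohort.  The terminal-2-bp rule removes terminal-only
artifact calls — all of them, which the truth set verifies — but interior
artifacts are indistinguishable from genuine low-dosage alleles at the
single-read level, exactly the regime in which the source protocol fell
back on visual inspection.  The planted-recovery checks therefore assert
full sensitivity (every planted carrier recovered), complete removal of
terminal-artifact-only calls, and that every remaining false match is
fully explained by logged artifacts.

## Numerical and degenerate-input conventions

Equal simulator seeds reproduce byte-identical MAF/TSV/SAM/FASTA/JSON
outputs.  Zero-opportunity profile offsets are missing; a zero or
undefined damage rate never caps a quality.  Pileup depth counts only
bases that passed the quality threshold.  KW refuses < 2 groups or
empty groups; chi-squared refuses zero margins; proportions refuse zero
denominators.  Newick trees are consumed as written (no re-rooting);
duplicate leaf names and negative branch lengths are rejected.

## Problem sizes used by the checks

The acceptance run uses 10 species × 50 variants for sharing recovery,
the default 20-sample cohort at 30× for carrier recovery, and 50,000
reads for damage-parameter recovery (d0 within 3 binomial SE, λ within
20%) — sizes at which every stochastic bound in the checks is
comfortably stable while a full run stays under half a minute.
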