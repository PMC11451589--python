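# Methods

## Model

A KIR gene is represented by a `GeneDefinition`: a designated per-gene
**wildtype allele** (the coordinate frame for everything downstream), an
ordered table of coding exons on wildtype coordinates (0-based half-open
internally; all user-facing output is 1-based inclusive), an optional CDS
phase for the first coding exon, a set of intervals flagged as
expression-relevant UTR, and a pseudogene flag. Every other allele of the
gene is expressed as a set of variants against the wildtype, split into
**core** (protein- or expression-changing: missense, nonsense, frameshift,
start-loss, functional-UTR) and **silent** (synonymous, intronic, other
UTR).

Which allele is "wildtype" is a database convention, not a biological fact:
the fixture dialect names it explicitly per gene; for EMBL/IMGT-style
releases the lowest-numbered genomic allele within 5% of the longest
genomic sequence is chosen, which is deterministic and follows nomenclature
convention. Whether a UTR interval is expression-relevant is likewise an
explicit database annotation, not an inference.

### cDNA-only alleles

Alleles known only from their transcript are given a genomic sequence by
choosing the genomic allele whose spliced exon sequence is nearest to the
cDNA by edit distance (ties: lowest allele number), then replacing that
backbone's exonic bases with the cDNA's, keeping introns unchanged. A cDNA
that cannot be reconciled with the backbone's exon structure (edit distance
or length discrepancy above 20% of the spliced length) is flagged and
excluded from the mapping set with a warning rather than aborting the load.

### Variant calling

The wildtype is aligned to the extracted assembly sequence by semi-global
affine-gap alignment: terminal gaps in the *target* (the extraction, which
may overshoot the gene) are free, while every wildtype base is accounted
for — an unaligned wildtype head or tail surfaces as a penalized terminal
deletion. This asymmetry is deliberate: truncations must appear as variants
so the clipping-repair stage can see them. Scoring defaults are match +1,
mismatch −4, gap open 6, gap extend 1 (a gap of length L costs 6 + L);
these are standard variant-calling-grade parameters favouring contiguous
indels, and they are configurable. The dynamic programming is delegated to
Biopython's `PairwiseAligner` (exact Gotoh recurrences in C); the package
owns the scoring convention, the end-gap configuration and the op-run
(CIGAR) extraction, and the test suite checks score equality against an
independently written brute-force DP on hundreds of random pairs.

Indels are left-aligned at extraction (shifted to the smallest wildtype
position preserving the sequence, never across a preceding variant).
Consequences are assigned by applying each variant **independently** to the
wildtype, lifting the exon table through the edit, re-splicing, translating
with the standard code, and comparing proteins. A premature stop is one
that appears before the final codon of the *mutated* CDS — so an in-frame
deletion that merely shortens the protein is missense, not nonsense.
Variants downstream of the wildtype stop are synonymous by definition.
Pseudogenes produce no protein, so their exonic variants are silent unless
they touch a functional-UTR interval. Independent per-variant application
means compound effects (two frameshifts restoring frame) are not modelled;
this is a known limitation.

### Locus discovery

All (unflagged) allele sequences are mapped onto the assembly. The default
backend is a builtin deterministic k-mer seed-and-extend mapper (k = 21,
exact seeds, diagonal-band clustering with 100 bp indel tolerance): it has
no binary dependency, is reproducible bit-for-bit, and is exact on the
fixture scale where spacers are guaranteed to share no 21-mer with any
allele. A minimap2 adapter (PAF parsing) is available for real assemblies;
when the executable is absent the pipeline falls back to the builtin mapper
with a warning. Secondary and heavily clipped mappings are retained —
copies with large deletions or truncations are found through them.

Same-contig, same-strand mappings overlapping by ≥1 bp are merged
transitively into candidate regions (gap-merge threshold 0 by default);
strands never merge. Regions backed by fewer than 2 mappings or shorter
than 500 bp are dropped as spurious fragments. Each region is assigned the
gene with the highest mapping count ("prevalence" is interpreted as
mapping count; ties broken by summed score, then name — coverage weighting
would be a config alternative).

### Boundary refinement and clipping repair

The assigned gene's wildtype is aligned against the region padded by a
1 kb flank; the aligned target span becomes the gene bounds. One numerical
subtlety: when a copy is genuinely truncated, forcing the penalized
wildtype end into unrelated flanking sequence can out-score a single clean
terminal deletion by cherry-picking chance matches. Terminal alignment
segments whose cumulative score drops below −30 (≈ seven clustered
mismatches — deeper than any realistic variant cluster at this scale) are
therefore recognized as artifacts and trimmed from the bounds, letting the
missing wildtype end re-surface as one clean terminal deletion at
variant-calling time. A region whose wildtype alignment matches fewer than
30% of wildtype bases is dropped as unmappable.

When variant calling produces a deletion whose footprint includes the
first or last wildtype base, the copy is re-extracted with bounds pushed
outward by the net terminal indel length (prefix-deletion length minus any
insertion anchored at position 0, symmetrically for the suffix, clamped to
the contig), and variants are re-called. The copy keeps whichever variant
set is less complex — lexicographically by (variant count, total edited
bases) — with ties keeping the original for stability. Refinement is a
single round: the repair either succeeds immediately (erroneous clipping:
the true head was present in the assembly) or re-finds the same truncation
(the head genuinely is not there), and a single pass guarantees
termination and idempotence.

### Allele calling

See the README for the scoring formula. Implementation details: the
nucleotide "state" at an index position is the wildtype base unless the
variant set substitutes it, deletes it (each deleted base independently),
or anchors an insertion there (the state then carries the inserted bases).
`h/|P|` is defined as 0 when the index is empty, which keeps
pseudogene-like genes with no core variation well defined. The final
tie-break after (core score, silent Jaccard) is the numeric allele suffix,
for determinism. Reports: a TSV summary (one row per copy, forward-strand
1-based inclusive coordinates, sorted by contig then start) and a YAML
detail file with the full classified variant list and score breakdowns for
the top 5 closest alleles; variants whose observed bases contain N are
marked low-confidence. The pipeline contains no randomness: identical
inputs give byte-identical outputs.

## Synthetic data

The fixture generator emulates the structure of the real allele database at
toy scale: genes of ~2 kb with 3 coding exons (150–300 bp each, CDS forced
to a whole number of codons with a proper start and stop and no internal
stop), 300–500 bp introns, 300 bp UTRs with a 30 bp expression-relevant
interval at positions 100–130, and per-gene allele series whose planted
variants cycle through the consequence classes. Every planted variant is
certified by the package's own classifier before emission, so the declared
core/silent partition is ground truth by construction; a generation seed
controls all randomness and output files are byte-reproducible. Assemblies
are built by concatenating planted allele copies (optionally
reverse-complemented, head/tail-truncated, or carrying certified novel
variants placed off the core index) with ≥2 kb intergenic spacers
rejection-sampled to share no 21-mer with any allele.

What the toy data does **not** emulate: real KIR paralog similarity (toy
genes are unrelated random sequences, so cross-gene mapping ambiguity is
absent), assembly base errors, tandem or overlapping gene copies, and
realistic intron/exon counts or lengths. Passing tests therefore
demonstrate the correctness of the algorithmic machinery — mapping
consolidation, alignment, consequence classification, scoring, repair —
not recall under paralog confusion, which only full-scale assemblies can
probe.

## Problem sizes used in the automated checks

The test suite and acceptance script run entirely on generated fixtures:
2-gene × 3-allele databases (~2 kb genes), assemblies of ~25 kb with six
planted copies, 500 random alignment pairs up to 200 bp for the DP
cross-check, and 1,000 randomized scoring triples on an 800 bp frame.
These sizes make every check exact and fast while exercising each code
path, including minus-strand copies, truncations, cDNA-only alleles and
novel core variants.
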