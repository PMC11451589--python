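"""Gene-copy extraction and boundary refinement.

``refine_with_wildtype`` turns a consolidated candidate region into a
:class:`GeneCopy` by aligning the assigned gene's wildtype against the
region (padded by a flank) and taking the aligned span as the gene bounds.

``refine`` implements the clipping-repair stage: when variant calling has
produced prefix or suffix deletions (deletions removing the head or tail of
the wildtype), the copy is re-extracted with its bounds pushed outward by
the net terminal indel length and variants re-called; the less complex of
the two variant sets wins (ties keep the original, for stability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

from Bio.Seq import reverse_complement

from .alignment import PairwiseAlignment, ScoringScheme, semiglobal_align
from .database import GeneDefinition
from .mapping import CandidateRegion
from .variants import Variant, call_variants

log = logging.getLogger(__name__)


@dataclass
class GeneCopy:
    region: CandidateRegion
    gene: str
    refined_start: int
    refined_end: int
    extracted_seq: str  # oriented to the wildtype strand
    variants: list[Variant] = field(default_factory=list)
    alignment: PairwiseAlignment | None = None
    allele_call: str | None = None
    score_table: list = field(default_factory=list)
    n_novel_silent: int = 0  # copy silent variants absent from the called allele

    @property
    def contig(self) -> str:
        return self.region.contig

    @property
    def strand(self) -> str:
        return self.region.strand

    @property
    def core_variants(self) -> list[Variant]:
        return [v for v in self.variants if v.core]

    @property
    def silent_variants(self) -> list[Variant]:
        return [v for v in self.variants if not v.core]


def extract_oriented(contig_seq: str, start: int, end: int, strand: str) -> str:
    seq = contig_seq[start:end]
    return seq if strand == "+" else reverse_complement(seq)


def _run_score(op: str, length: int, scoring: ScoringScheme) -> int:
    if op == "=":
        return scoring.match * length
    if op == "X":
        return scoring.mismatch * length
    return -scoring.gap_cost(length)


def _junk_trim(
    ops: list[tuple[str, int]], scoring: ScoringScheme, threshold: int
) -> tuple[int, int]:
    """Target bases to trim from each end of an alignment.

    When a gene copy is truncated, forcing the (penalized) wildtype end into
    the unrelated flanking sequence can out-score a single clean terminal
    deletion by cherry-picking chance matches.  Such artifact segments are
    recognizable as a terminal stretch whose cumulative score drops below
    ``-threshold``; they are trimmed here so that the missing wildtype end
    re-surfaces as one terminal deletion at variant-calling time.
    """

    def scan(runs: list[tuple[str, int]]) -> int:
        cum = 0
        cum_min = 0
        target_bases = 0
        trim = 0
        for op, length in runs:
            cum += _run_score(op, length, scoring)
            if op in ("=", "X", "I"):
                target_bases += length
            if cum < cum_min:
                cum_min = cum
                if cum_min <= -threshold:
                    trim = target_bases
        return trim

    return scan(ops), scan(ops[::-1])


def refine_with_wildtype(
    region: CandidateRegion,
    gene: GeneDefinition,
    contigs: dict[str, str],
    flank_bp: int = 1000,
    scoring: ScoringScheme | None = None,
    min_identity: float = 0.3,
    junk_threshold: int = 30,
) -> GeneCopy | None:
    """Set preliminary gene bounds by mapping the wildtype back to the region.

    The region is padded by ``flank_bp`` on each side and the wildtype
    aligned semi-globally against it (padding overhangs are free); the
    aligned target span, less any low-quality terminal artifact segments,
    becomes the refined bounds.  Returns ``None`` when the wildtype
    effectively fails to map (matched fraction < ``min_identity``).
    """
    contig_seq = contigs[region.contig]
    pad_start = max(0, region.start - flank_bp)
    pad_end = min(len(contig_seq), region.end + flank_bp)
    window = extract_oriented(contig_seq, pad_start, pad_end, region.strand)

    aln = semiglobal_align(gene.wildtype_seq, window, scoring)
    if aln.matched_bases < min_identity * len(gene.wildtype_seq):
        log.warning(
            "wildtype of %s failed to map in %s:[%d,%d); region dropped",
            gene.name,
            region.contig,
            region.start,
            region.end,
        )
        return None

    ts, te = aln.target_span
    trim_left, trim_right = _junk_trim(aln.ops, scoring or ScoringScheme(), junk_threshold)
    ts, te = ts + trim_left, te - trim_right
    if te <= ts:
        return None
    if region.strand == "+":
        refined_start, refined_end = pad_start + ts, pad_start + te
    else:
        refined_start = pad_start + (len(window) - te)
        refined_end = pad_start + (len(window) - ts)
    return GeneCopy(
        region=region,
        gene=gene.name,
        refined_start=refined_start,
        refined_end=refined_end,
        extracted_seq=extract_oriented(contig_seq, refined_start, refined_end, region.strand),
    )


# ---------------------------------------------------------------------------
# clipping repair


def needs_refinement(variants: list[Variant], wildtype_len: int) -> bool:
    """True iff a deletion's footprint includes the first or last wildtype base."""
    for v in variants:
        if v.kind != "del":
            continue
        if v.pos == 0 or v.end == wildtype_len:
            return True
    return False


def complexity(variants: list[Variant]) -> tuple[int, int]:
    """Lexicographic complexity: (variant count, total edited bases)."""
    return (len(variants), sum(max(len(v.ref), len(v.alt)) for v in variants))


def _terminal_adjustments(variants: list[Variant], wildtype_len: int) -> tuple[int, int]:
    """Outward bound shifts implied by terminal indels: prefix-deletion length
    minus prefix-insertion length, and symmetrically for the suffix."""
    prefix = suffix = 0
    for v in variants:
        if v.kind == "del":
            if v.pos == 0:
                prefix += len(v.ref)
            if v.end == wildtype_len:
                suffix += len(v.ref)
        elif v.kind == "ins":
            if v.pos == 0:
                prefix -= len(v.alt)
            if v.pos == wildtype_len - 1:
                suffix -= len(v.alt)
    return prefix, suffix


def refine(
    copy: GeneCopy,
    gene: GeneDefinition,
    contigs: dict[str, str],
    scoring: ScoringScheme | None = None,
) -> GeneCopy:
    """Single-round clipping repair; returns the copy unchanged when no
    terminal deletions were called."""
    wl = len(gene.wildtype_seq)
    if not needs_refinement(copy.variants, wl):
        return copy

    prefix, suffix = _terminal_adjustments(copy.variants, wl)
    contig_seq = contigs[copy.contig]
    if copy.strand == "+":
        new_start = copy.refined_start - prefix
        new_end = copy.refined_end + suffix
    else:
        new_start = copy.refined_start - suffix
        new_end = copy.refined_end + prefix
    clamped_start = max(0, new_start)
    clamped_end = min(len(contig_seq), new_end)
    if (clamped_start, clamped_end) != (new_start, new_end):
        log.warning(
            "re-extraction of %s at %s clamped to contig bounds", copy.gene, copy.contig
        )
    if clamped_start >= clamped_end:
        return copy

    new_seq = extract_oriented(contig_seq, clamped_start, clamped_end, copy.strand)
    new_variants, new_aln = call_variants(gene.wildtype_seq, new_seq, gene, scoring)

    if complexity(new_variants) < complexity(copy.variants):
        return dc_replace(
            copy,
            refined_start=clamped_start,
            refined_end=clamped_end,
            extracted_seq=new_seq,
            variants=new_variants,
            alignment=new_aln,
        )
    return copy
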