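"""Allele calling by the core-variant-first distance scheme.

For each gene a *core-position index* collects every wildtype position
touched by any allele's core variants (each base of a deletion counts
independently; an insertion counts through its anchor).  A candidate allele
is scored against an assembly gene copy as

    core_score = h / |index| + n

where ``h`` is the Hamming distance between the nucleotide states implied by
the allele's and the copy's variant sets over the index positions, and ``n``
is the number of *novel* core variants — copy core variants whose footprint
lies entirely outside the index.  Ties in core_score are broken by the
Jaccard distance between the silent-variant sets, then by the numeric allele
suffix.  The scheme deliberately prefers agreement at functionally relevant
positions over global edit distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .database import AlleleDatabase, AlleleRecord, CorePositionIndex, allele_number
from .regions import GeneCopy
from .variants import Variant


@dataclass
class AlleleScore:
    allele_name: str
    core_score: float
    silent_jaccard: float
    missing_core: list[str] = field(default_factory=list)
    novel_core: list[str] = field(default_factory=list)


def _state_maps(variants: list[Variant]) -> tuple[dict[int, str], dict[int, str]]:
    """Per-position nucleotide state implied by a variant set.

    Substituted positions carry the alt base, deleted positions a gap mark,
    and an insertion annotates its anchor position.  Positions not covered
    default to the wildtype base at comparison time.
    """
    subst: dict[int, str] = {}
    inserted: dict[int, str] = {}
    for v in variants:
        if v.kind == "snp":
            subst[v.pos] = v.alt
        elif v.kind == "del":
            for p in v.footprint():
                subst[p] = "-"
        else:
            inserted[v.pos] = v.alt
    return subst, inserted


def _state_at(
    pos: int, wildtype: str, subst: dict[int, str], inserted: dict[int, str]
) -> str:
    base = subst.get(pos, wildtype[pos])
    ins = inserted.get(pos)
    return base + "+" + ins if ins else base


def core_score(
    copy: GeneCopy,
    allele: AlleleRecord,
    index: CorePositionIndex,
    wildtype_seq: str,
) -> AlleleScore:
    """Score one candidate allele against the copy's called variants."""
    if allele.gene != copy.gene:
        raise ValueError(
            f"gene mismatch: copy is {copy.gene}, allele is {allele.gene}"
        )
    allele_subst, allele_ins = _state_maps(allele.core_variants)
    copy_subst, copy_ins = _state_maps(copy.core_variants)

    h = sum(
        1
        for pos in index.positions
        if _state_at(pos, wildtype_seq, allele_subst, allele_ins)
        != _state_at(pos, wildtype_seq, copy_subst, copy_ins)
    )

    index_set = set(index.positions)
    copy_core_keys = {v.key() for v in copy.core_variants}
    novel = [
        v
        for v in copy.core_variants
        if all(p not in index_set for p in v.footprint())
    ]
    missing = [
        v
        for v in allele.core_variants
        if v.key() not in copy_core_keys
    ]

    score = (h / len(index) if len(index) else 0.0) + len(novel)
    return AlleleScore(
        allele_name=allele.allele_name,
        core_score=score,
        silent_jaccard=silent_jaccard(copy.silent_variants, allele.silent_variants),
        missing_core=[v.render() for v in missing],
        novel_core=[v.render() for v in novel],
    )


def silent_jaccard(copy_silent: list[Variant], allele_silent: list[Variant]) -> float:
    """Jaccard distance on exact variant identity; two empty sets → 0.0."""
    a = {v.key() for v in copy_silent}
    b = {v.key() for v in allele_silent}
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def call_allele(
    copy: GeneCopy,
    alleles: list[AlleleRecord],
    index: CorePositionIndex,
    wildtype_seq: str,
    top_n: int = 5,
) -> tuple[str, list[AlleleScore]]:
    """Rank candidate alleles and return (call, top-N score table)."""
    if not alleles:
        raise ValueError(f"no alleles available for gene {copy.gene}")
    scores = [core_score(copy, a, index, wildtype_seq) for a in alleles]
    scores.sort(
        key=lambda s: (s.core_score, s.silent_jaccard, allele_number(s.allele_name))
    )
    return scores[0].allele_name, scores[:top_n]


def annotate_copy(copy: GeneCopy, db: AlleleDatabase) -> GeneCopy:
    """Attach the allele call and score table to a gene copy in place."""
    gene = db.genes[copy.gene]
    alleles = [a for a in db.gene_alleles(copy.gene) if not a.flagged]
    call, table = call_allele(
        copy, alleles, db.core_index[copy.gene], gene.wildtype_seq
    )
    copy.allele_call = call
    copy.score_table = table
    called_silent = {v.key() for v in db.alleles[call].silent_variants}
    copy.n_novel_silent = sum(
        1 for v in copy.silent_variants if v.key() not in called_silent
    )
    return copy
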