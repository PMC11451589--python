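"""Variants against a gene wildtype, and their functional classification.

A :class:`Variant` is expressed in wildtype coordinates (0-based internally;
rendered 1-based for humans).  Classification follows the mutate–splice–
translate recipe: each variant is applied *independently* to the wildtype,
the CDS is re-spliced from the (coordinate-shifted) exon table, translated
with the standard genetic code, and the protein compared with the wildtype
protein.  Variants that change the protein or its expression (missense,
nonsense, frameshift, start-loss, functionally-relevant UTR changes) are
"core"; synonymous, intronic and other-UTR variants are "silent".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio.Seq import Seq

from .alignment import PairwiseAlignment

if TYPE_CHECKING:  # pragma: no cover
    from .database import GeneDefinition

CORE_EFFECTS = frozenset(
    {"missense", "nonsense", "frameshift", "start_loss", "utr_functional"}
)
SILENT_EFFECTS = frozenset({"synonymous", "intronic", "utr_silent"})


@dataclass(frozen=True)
class Variant:
    """One difference vs. the gene wildtype.

    ``pos`` is a 0-based wildtype coordinate.  For an insertion, ``ref`` is
    empty and ``pos`` is the *anchor*: the inserted bases sit immediately
    after wildtype position ``pos``.  For a deletion, ``alt`` is empty and
    the footprint is ``[pos, pos + len(ref))``.
    """

    pos: int
    ref: str
    alt: str
    kind: str  # snp | ins | del
    effect: str | None = None
    core: bool | None = None

    def __post_init__(self) -> None:
        if self.kind == "snp":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("snp requires |ref| = |alt| = 1")
        elif self.kind == "ins":
            if self.ref != "" or not self.alt:
                raise ValueError("ins requires empty ref, non-empty alt")
        elif self.kind == "del":
            if self.alt != "" or not self.ref:
                raise ValueError("del requires empty alt, non-empty ref")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    def footprint(self) -> range:
        """Wildtype positions touched: each deleted base independently, the
        anchor for an insertion, the single base for a SNP."""
        if self.kind == "ins":
            return range(self.pos, self.pos + 1)
        return range(self.pos, self.pos + len(self.ref))

    @property
    def end(self) -> int:
        """End (exclusive) of the replaced wildtype interval."""
        return self.pos + len(self.ref)

    def net_length(self) -> int:
        return len(self.alt) - len(self.ref)

    def render(self) -> str:
        """Human-readable 1-based ``pos REF>ALT`` form."""
        if self.kind == "snp":
            return f"{self.pos + 1} {self.ref}>{self.alt}"
        if self.kind == "del":
            return f"{self.pos + 1} {self.ref}>-"
        return f"{self.pos + 1} ->{self.alt}"

    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def _variant_sort_key(v: Variant) -> tuple[int, int]:
    return (v.pos, 0 if v.kind == "ins" else 1)


def apply_variants(wildtype: str, variants: Iterable[Variant]) -> str:
    """Reconstruct the sequence implied by ``variants`` on ``wildtype``.

    Variants must be non-overlapping; insertions at position p are placed
    immediately after wildtype base p.
    """
    out: list[str] = []
    cursor = 0
    for v in sorted(variants, key=_variant_sort_key):
        if v.kind == "ins":
            if v.pos + 1 < cursor:
                raise ValueError(f"overlapping variants at {v.pos}")
            out.append(wildtype[cursor : v.pos + 1])
            out.append(v.alt)
            cursor = v.pos + 1
        else:
            if v.pos < cursor:
                raise ValueError(f"overlapping variants at {v.pos}")
            if wildtype[v.pos : v.end] != v.ref:
                raise ValueError(
                    f"ref mismatch at {v.pos}: expected {v.ref!r}, "
                    f"wildtype has {wildtype[v.pos:v.end]!r}"
                )
            out.append(wildtype[cursor : v.pos])
            out.append(v.alt)
            cursor = v.end
    out.append(wildtype[cursor:])
    return "".join(out)


def _lift(pos: int, v: Variant) -> int:
    """Map a wildtype coordinate through a single applied variant."""
    if v.kind == "ins":
        return pos if pos <= v.pos else pos + len(v.alt)
    if pos <= v.pos:
        return pos
    if pos < v.end:  # inside a deleted/replaced interval: clamp to its start
        return v.pos + min(pos - v.pos, len(v.alt))
    return pos + v.net_length()


def extract_variants(
    aln: PairwiseAlignment, wildtype: str, target: str
) -> list[Variant]:
    """Turn an alignment into variants (effects unset).

    Mismatch columns become SNPs; each insertion/deletion run becomes a
    single variant.  Indels are left-aligned: shifted to the smallest
    wildtype position that preserves the resulting sequence, without
    crossing a preceding variant.
    """
    variants: list[Variant] = []
    i = aln.wildtype_span[0]
    j = aln.target_span[0]
    for op, length in aln.ops:
        if op == "=":
            i += length
            j += length
        elif op == "X":
            for k in range(length):
                variants.append(
                    Variant(pos=i + k, ref=wildtype[i + k], alt=target[j + k], kind="snp")
                )
            i += length
            j += length
        elif op == "D":
            variants.append(
                Variant(pos=i, ref=wildtype[i : i + length], alt="", kind="del")
            )
            i += length
        elif op == "I":
            variants.append(
                Variant(pos=i - 1, ref="", alt=target[j : j + length], kind="ins")
            )
            j += length
    return _left_align(variants, wildtype)


def _left_align(variants: list[Variant], wildtype: str) -> list[Variant]:
    out: list[Variant] = []
    prev_end = 0
    for v in variants:
        if v.kind == "del":
            pos, ref = v.pos, v.ref
            while pos > prev_end and wildtype[pos - 1] == ref[-1]:
                pos -= 1
                ref = wildtype[pos] + ref[1:]
            v = replace(v, pos=pos, ref=ref)
        elif v.kind == "ins":
            pos, alt = v.pos, v.alt
            # insertion after pos can move to after pos-1 if its last base
            # equals wildtype[pos] (rotate right)
            while pos > prev_end and pos >= 0 and alt[-1] == wildtype[pos]:
                alt = wildtype[pos] + alt[:-1]
                pos -= 1
            v = replace(v, pos=pos, alt=alt)
        out.append(v)
        prev_end = v.pos + 1 if v.kind == "ins" else v.end
    return out


# ---------------------------------------------------------------------------
# effect classification


def _spliced_cds(seq: str, exons: Sequence[tuple[int, int]], phase: int) -> str:
    cds = "".join(seq[s:e] for s, e in exons)
    return cds[phase:]


def _translate(cds: str) -> str:
    """Translate up to and including the first stop codon."""
    cds = cds[: len(cds) - len(cds) % 3]
    protein = str(Seq(cds).translate())
    stop = protein.find("*")
    return protein if stop == -1 else protein[: stop + 1]


def _region_of(pos: int, gene: "GeneDefinition") -> str:
    for s, e in gene.exons:
        if s <= pos < e:
            return "exon"
    if not gene.exons:
        return "utr"
    if pos < gene.exons[0][0] or pos >= gene.exons[-1][1]:
        return "utr"
    return "intron"


def _is_exonic(v: Variant, gene: "GeneDefinition") -> bool:
    if v.kind == "ins":
        # an insertion sits between pos and pos+1; it is exonic only when both
        # flanking bases belong to the same exon
        return any(s <= v.pos and v.pos + 1 < e for s, e in gene.exons)
    return any(_region_of(p, gene) == "exon" for p in v.footprint())


def classify_effect(v: Variant, gene: "GeneDefinition") -> Variant:
    """Return ``v`` with ``effect`` and ``core`` set.

    Each variant is evaluated independently: applied to the wildtype, the CDS
    re-spliced from the shifted exon table and translated.  Compound effects
    of co-occurring variants (e.g. two frameshifts restoring the frame) are
    deliberately not modelled.
    """
    n = len(gene.wildtype_seq)
    if not (0 <= v.pos < n) or v.end > n:
        raise ValueError(f"variant {v.render()} outside wildtype [0, {n})")

    in_functional_utr = any(
        any(s <= p < e for s, e in gene.functional_utr) for p in v.footprint()
    )

    if not _is_exonic(v, gene):
        if in_functional_utr:
            return replace(v, effect="utr_functional", core=True)
        region = _region_of(v.pos, gene)
        effect = "intronic" if region == "intron" else "utr_silent"
        return replace(v, effect=effect, core=False)

    if gene.pseudogene:
        # no protein product: exonic changes cannot alter one
        effect = "utr_functional" if in_functional_utr else "synonymous"
        return replace(v, effect=effect, core=(effect == "utr_functional"))

    mutated = apply_variants(gene.wildtype_seq, [v])
    new_exons = [(_lift(s, v), _lift(e, v)) for s, e in gene.exons]
    wt_cds = _spliced_cds(gene.wildtype_seq, gene.exons, gene.cds_phase)
    mut_cds = _spliced_cds(mutated, new_exons, gene.cds_phase)

    if v.kind in ("ins", "del") and abs(v.net_length()) % 3 != 0:
        return replace(v, effect="frameshift", core=True)

    wt_protein = _translate(wt_cds)
    mut_protein = _translate(mut_cds)

    if wt_cds[:3] == "ATG" and mut_cds[:3] != "ATG":
        return replace(v, effect="start_loss", core=True)
    if mut_protein == wt_protein:
        effect = "utr_functional" if in_functional_utr else "synonymous"
        return replace(v, effect=effect, core=(effect == "utr_functional"))
    # a stop before the final codon of the mutated CDS is a premature stop;
    # an in-frame indel that merely shortens the protein is not
    premature = mut_protein.endswith("*") and len(mut_protein) < len(mut_cds) // 3
    if premature and len(mut_protein) < len(wt_protein):
        return replace(v, effect="nonsense", core=True)
    return replace(v, effect="missense", core=True)


def classify_all(variants: Iterable[Variant], gene: "GeneDefinition") -> list[Variant]:
    return [classify_effect(v, gene) for v in variants]


def call_variants(
    wildtype: str, target: str, gene: "GeneDefinition | None" = None, scoring=None
) -> tuple[list[Variant], PairwiseAlignment]:
    """Align ``target`` to ``wildtype``, extract and (optionally) classify."""
    from .alignment import semiglobal_align

    aln = semiglobal_align(wildtype, target, scoring)
    variants = extract_variants(aln, wildtype, target)
    if gene is not None:
        variants = classify_all(variants, gene)
    return variants, aln
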