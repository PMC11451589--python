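"""Independent brute-force oracles used to verify the implementation.

Everything here is written from first principles — plain-Python dynamic
programming, literal set arithmetic, direct splice-and-translate — and
deliberately shares no code with the package internals it checks.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def semiglobal_score_oracle(
    wildtype: str,
    target: str,
    match: int = 1,
    mismatch: int = -4,
    gap_open: int = 6,
    gap_extend: int = 1,
) -> float:
    """Gotoh affine-gap DP, free end gaps on the target only.

    A gap of length L costs ``gap_open + L * gap_extend``.  Returns the
    optimal score; O(nm) time, O(nm) memory, pure Python.
    """
    n, m = len(wildtype), len(target)
    open_cost = gap_open + gap_extend

    # best[i][j]: best score of any alignment consuming wildtype[:i], target[:j]
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in target (wildtype deleted)
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in wildtype (insertion)

    M[0][0] = 0
    for j in range(1, m + 1):
        Iy[0][j] = 0  # leading target overhang is free
    for i in range(1, n + 1):
        Ix[i][0] = -(gap_open + i * gap_extend)

    for i in range(1, n + 1):
        wi = wildtype[i - 1]
        for j in range(1, m + 1):
            s = match if (wi == target[j - 1] and wi != "N") else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(
                M[i - 1][j] - open_cost,
                Ix[i - 1][j] - gap_extend,
                Iy[i - 1][j] - open_cost,
            )
            Iy[i][j] = max(
                M[i][j - 1] - open_cost,
                Iy[i][j - 1] - gap_extend,
                Ix[i][j - 1] - open_cost,
            )

    # trailing target overhang is free: take the best over the last row
    return max(max(M[n][j], Ix[n][j], Iy[n][j]) for j in range(m + 1))


def core_score_oracle(
    wildtype: str,
    index_positions: list[int],
    allele_variants: list[tuple[int, str, str]],
    copy_variants: list[tuple[int, str, str]],
) -> float:
    """Literal position-by-position enumeration of the allele scoring formula.

    Variants are (pos, ref, alt) triples of *core* variants; each deleted
    base counts as its own position, an insertion annotates its anchor.
    """

    def states(variants):
        st = {}
        ins = {}
        for pos, ref, alt in variants:
            if ref and alt:  # substitution
                for k in range(len(ref)):
                    st[pos + k] = alt[k]
            elif ref:  # deletion
                for k in range(len(ref)):
                    st[pos + k] = "-"
            else:  # insertion
                ins[pos] = alt
        return st, ins

    a_st, a_ins = states(allele_variants)
    c_st, c_ins = states(copy_variants)

    h = 0
    for p in index_positions:
        va = (a_st.get(p, wildtype[p]), a_ins.get(p, ""))
        vc = (c_st.get(p, wildtype[p]), c_ins.get(p, ""))
        if va != vc:
            h += 1

    idx = set(index_positions)
    novel = 0
    for pos, ref, alt in copy_variants:
        footprint = [pos] if not ref else list(range(pos, pos + len(ref)))
        if all(p not in idx for p in footprint):
            novel += 1

    return (h / len(index_positions) if index_positions else 0.0) + novel


def union_sweep_oracle(
    intervals: list[tuple[str, str, int, int]]
) -> list[tuple[str, str, int, int]]:
    """Transitive interval union, partitioned by (contig, strand)."""
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for contig, strand, s, e in intervals:
        groups.setdefault((contig, strand), []).append((s, e))
    out = []
    for (contig, strand), ivs in sorted(groups.items()):
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend((contig, strand, s, e) for s, e in merged)
    return out


_CODON_TABLE = {}


def _codon_table():
    global _CODON_TABLE
    if not _CODON_TABLE:
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        _CODON_TABLE = {
            a + b + c: aas[16 * i + 4 * j + k]
            for i, a in enumerate(bases)
            for j, b in enumerate(bases)
            for k, c in enumerate(bases)
        }
    return _CODON_TABLE


def translate_oracle(cds: str) -> str:
    """Standard-code translation up to and including the first stop."""
    table = _codon_table()
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = table[cds[i : i + 3]]
        protein.append(aa)
        if aa == "*":
            break
    return "".join(protein)


def effect_oracle(
    wildtype: str,
    exons: list[tuple[int, int]],
    pos: int,
    ref: str,
    alt: str,
    functional_utr: list[tuple[int, int]] = (),
) -> str:
    """Mutate–splice–translate comparison, written independently.

    Handles the variant shapes the toy fixtures plant: SNPs anywhere and
    indels confined to a single exon or intron.
    """
    footprint = [pos] if not ref else list(range(pos, pos + len(ref)))
    in_exon = any(any(s <= p < e for p in footprint) for s, e in exons)
    if not ref:  # insertion after pos: exonic when strictly inside one exon
        in_exon = any(s <= pos and pos + 1 < e for s, e in exons)
    if not in_exon:
        if any(any(s <= p < e for p in footprint) for s, e in functional_utr):
            return "utr_functional"
        if pos < exons[0][0] or pos >= exons[-1][1]:
            return "utr_silent"
        return "intronic"

    if ref:
        mutated = wildtype[:pos] + alt + wildtype[pos + len(ref) :]
    else:
        mutated = wildtype[: pos + 1] + alt + wildtype[pos + 1 :]
    shift = len(alt) - len(ref)
    new_exons = []
    for s, e in exons:
        new_exons.append(
            (s if s <= pos else s + shift, e if e <= pos else e + shift)
        )
    wt_cds = "".join(wildtype[s:e] for s, e in exons)
    mut_cds = "".join(mutated[s:e] for s, e in new_exons)

    if abs(shift) % 3 != 0:
        return "frameshift"
    wt_protein = translate_oracle(wt_cds)
    mut_protein = translate_oracle(mut_cds)
    if mut_cds[:3] != "ATG":
        return "start_loss"
    if mut_protein == wt_protein:
        return "synonymous"
    if (
        mut_protein.endswith("*")
        and len(mut_protein) < len(mut_cds) // 3
        and len(mut_protein) < len(wt_protein)
    ):
        return "nonsense"
    return "missense"


def splice_substitute_oracle(
    backbone: str, exons: list[tuple[int, int]], cdna: str
) -> str:
    """Coordinate-lift reconstruction of a genomic sequence from a cDNA of
    identical spliced length: exon bases come from the cDNA, introns from
    the backbone."""
    spliced_len = sum(e - s for s, e in exons)
    assert len(cdna) == spliced_len, "oracle only handles length-preserving cDNA"
    out = []
    cursor = 0
    offset = 0
    for s, e in exons:
        out.append(backbone[cursor:s])
        out.append(cdna[offset : offset + (e - s)])
        offset += e - s
        cursor = e
    out.append(backbone[cursor:])
    return "".join(out)


def apply_variants_oracle(
    wildtype: str, variants: list[tuple[int, str, str]]
) -> str:
    """Right-to-left literal application of (pos, ref, alt) edits."""
    seq = wildtype
    for pos, ref, alt in sorted(variants, reverse=True):
        if ref:
            assert seq[pos : pos + len(ref)] == ref
            seq = seq[:pos] + alt + seq[pos + len(ref) :]
        else:
            seq = seq[: pos + 1] + alt + seq[pos + 1 :]
    return seq
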