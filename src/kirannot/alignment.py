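"""Semi-global pairwise alignment of a gene wildtype against an extracted
assembly sequence.

The alignment is "semi-global" in the fit sense: every base of the wildtype
must be accounted for (unaligned wildtype head/tail shows up as penalized
terminal deletion runs), while overhangs of the *target* — the sequence
extracted from the assembly, which may overshoot the gene on either side —
are free.  This asymmetry is deliberate: truncations of the gene in the
assembly must surface as prefix/suffix deletion variants so that the
downstream region-refinement stage can detect and repair erroneous clipping,
whereas extra flanking assembly sequence is not a variant at all.

The dynamic programming itself is delegated to :class:`Bio.Align.PairwiseAligner`
(affine gaps, full Gotoh recurrences in C); this module owns the scoring
convention, the free-end-gap configuration and the conversion of the
alignment path into CIGAR-style operation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

VALID_ALPHABET = frozenset("ACGTN")

#: CIGAR-style opcodes: '=' match, 'X' mismatch, 'I' insertion in the target
#: (bases absent from the wildtype), 'D' deletion from the wildtype.
OPS = ("=", "X", "I", "D")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring.  A gap of length L costs ``gap_open + L * gap_extend``
    (both stored as positive costs).  Defaults are standard variant-calling-grade
    parameters that favour contiguous indels over scattered mismatches.
    """

    match: int = 1
    mismatch: int = -4
    gap_open: int = 6
    gap_extend: int = 1

    def gap_cost(self, length: int) -> int:
        return self.gap_open + length * self.gap_extend


@dataclass
class PairwiseAlignment:
    """Result of :func:`semiglobal_align`.

    ``ops`` covers the full wildtype and the aligned span of the target;
    free target overhangs are excluded from the ops and reported only through
    ``target_span``.
    """

    ops: list[tuple[str, int]]
    score: int
    wildtype_span: tuple[int, int]
    target_span: tuple[int, int]

    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)

    @property
    def matched_bases(self) -> int:
        return sum(n for op, n in self.ops if op == "=")


def _validate(name: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(
            f"{name} sequence contains non-IUPAC characters: {sorted(bad)!r}"
        )


@lru_cache(maxsize=8)
def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    # N never matches, not even N vs N: an ambiguous base carries no evidence.
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            matrix[a, b] = scheme.match if (a == b and a != "N") else scheme.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # Biopython charges open on the first gap base; our convention charges
    # open + extend for a length-1 gap.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    # Free end gaps on the *target* only.  In Biopython's vocabulary a
    # "deletion" is a gap in the query row, i.e. unaligned target bases.
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


def semiglobal_align(
    wildtype: str, target: str, scoring: ScoringScheme | None = None
) -> PairwiseAlignment:
    """Align ``wildtype`` against ``target`` with free target end gaps.

    Returns the optimal-score alignment under ``scoring``; among co-optimal
    alignments Biopython's leftmost path is taken and indel placement is
    normalized later, at variant extraction.
    """
    scoring = scoring or ScoringScheme()
    _validate("wildtype", wildtype)
    _validate("target", target)

    aligner = _make_aligner(scoring)
    result = aligner.align(target, wildtype)
    best = result[0]
    score = int(result.score)

    n, m = len(wildtype), len(target)
    coords = best.coordinates  # row 0: target, row 1: wildtype
    ops: list[tuple[str, int]] = []
    tstart: int | None = None
    tend = 0

    def push(op: str, length: int) -> None:
        if length == 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    segments = list(zip(coords[0], coords[1], coords[0][1:], coords[1][1:]))
    for idx, (t0, q0, t1, q1) in enumerate(segments):
        dt, dq = int(t1 - t0), int(q1 - q0)
        if dq == 0:
            # target-only segment: a free overhang at either boundary of the
            # wildtype, otherwise a genuine insertion
            if (idx == 0 and q0 == 0) or (idx == len(segments) - 1 and int(q0) == n):
                continue
            push("I", dt)
        elif dt == 0:
            push("D", dq)
        else:
            for k in range(dt):
                ti, qi = int(t0) + k, int(q0) + k
                push("=" if target[ti] == wildtype[qi] and wildtype[qi] != "N" else "X", 1)
        if tstart is None:
            tstart = int(t0)
        tend = int(t1)

    if tstart is None:  # degenerate: nothing aligned (cannot happen for ACGT inputs)
        tstart = 0
    return PairwiseAlignment(
        ops=ops, score=score, wildtype_span=(0, n), target_span=(tstart, tend)
    )
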