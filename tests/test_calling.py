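import numpy as np
import pytest

from kirannot.calling import call_allele, core_score, silent_jaccard
from kirannot.database import AlleleRecord, CorePositionIndex
from kirannot.mapping import CandidateRegion
from kirannot.regions import GeneCopy
from kirannot.variants import Variant

from oracles import core_score_oracle

WT = "ACGGTCATTGCAAGGCTAGTCCAGTACGATTGCCGATGAC" * 20  # 800 bp scratch wildtype


def _copy(gene="G1", variants=()):
    region = CandidateRegion("c1", 0, len(WT), "+", {gene: [1, 10]})
    return GeneCopy(
        region=region,
        gene=gene,
        refined_start=0,
        refined_end=len(WT),
        extracted_seq=WT,
        variants=list(variants),
    )


def _allele(name, variants=()):
    return AlleleRecord(name, WT, "genomic", genomic_seq=WT, variants=list(variants))


def _core_snp(pos, alt=None):
    ref = WT[pos]
    alt = alt or "ACGT"[("ACGT".index(ref) + 1) % 4]
    return Variant(pos=pos, ref=ref, alt=alt, kind="snp", effect="missense", core=True)


def _silent_snp(pos):
    ref = WT[pos]
    alt = "ACGT"[("ACGT".index(ref) + 2) % 4]
    return Variant(pos=pos, ref=ref, alt=alt, kind="snp", effect="intronic", core=False)


def _core_del(pos, length):
    return Variant(
        pos=pos, ref=WT[pos : pos + length], alt="", kind="del", effect="frameshift", core=True
    )


def _index(positions, gene="G1"):
    return CorePositionIndex(gene=gene, positions=tuple(sorted(positions)))


class TestCoreScore:
    def test_full_core_agreement_scores_zero(self):
        shared = [_core_snp(100), _core_snp(200)]
        allele = _allele("G1*002", shared)
        copy = _copy(variants=shared)
        s = core_score(copy, allele, _index([100, 200]), WT)
        assert s.core_score == 0.0
        assert s.missing_core == [] and s.novel_core == []

    def test_one_mismatch_over_four_positions(self):
        allele = _allele("G1*002", [_core_snp(10)])
        copy = _copy(variants=[_core_snp(10), _core_snp(20)])
        s = core_score(copy, allele, _index([10, 20, 30, 40]), WT)
        assert s.core_score == pytest.approx(0.25)

    def test_novel_core_variants_add_whole_units(self):
        allele = _allele("G1*002", [_core_snp(10)])
        copy = _copy(variants=[_core_snp(10), _core_snp(300), _core_snp(400)])
        s = core_score(copy, allele, _index([10, 20, 30, 40]), WT)
        assert s.core_score == pytest.approx(2.0)
        assert len(s.novel_core) == 2

    def test_indel_positions_counted_independently(self):
        allele = _allele("G1*002", [_core_del(100, 3)])
        copy = _copy(variants=[])
        s = core_score(copy, allele, _index([100, 101, 102, 200, 201, 202]), WT)
        assert s.core_score == pytest.approx(3 / 6)

    def test_empty_index_convention(self):
        s = core_score(_copy(), _allele("G1*001"), _index([]), WT)
        assert s.core_score == 0.0

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError):
            core_score(_copy(gene="G1"), _allele("G2*001"), _index([], gene="G2"), WT)

    def test_matches_position_enumeration_oracle(self, rng):
        """1:1 agreement with a literal per-position enumeration on random
        (index, allele, copy) triples including multi-base deletions."""
        for _ in range(300):
            positions = sorted(rng.choice(600, size=int(rng.integers(0, 12)), replace=False))
            def random_variants():
                out = []
                for _ in range(int(rng.integers(0, 5))):
                    pos = int(rng.integers(0, 600))
                    kind = ["snp", "del", "ins"][int(rng.integers(0, 3))]
                    if kind == "snp":
                        out.append(_core_snp(pos))
                    elif kind == "del":
                        out.append(_core_del(pos, int(rng.integers(1, 5))))
                    else:
                        out.append(Variant(pos=pos, ref="", alt="TT", kind="ins",
                                           effect="frameshift", core=True))
                # drop overlapping footprints to keep the state well defined
                seen: set[int] = set()
                kept = []
                for v in sorted(out, key=lambda v: v.pos):
                    fp = set(v.footprint())
                    if not (fp & seen):
                        kept.append(v)
                        seen |= fp
                return kept

            av, cv = random_variants(), random_variants()
            s = core_score(
                _copy(variants=cv), _allele("G1*002", av), _index(positions), WT
            )
            expected = core_score_oracle(
                WT,
                list(positions),
                [(v.pos, v.ref, v.alt) for v in av],
                [(v.pos, v.ref, v.alt) for v in cv],
            )
            assert s.core_score == pytest.approx(expected)
            assert s.core_score >= 0.0


class TestSilentJaccard:
    def test_identical_sets(self):
        vs = [_silent_snp(5), _silent_snp(50)]
        assert silent_jaccard(vs, list(vs)) == 0.0

    def test_disjoint_sets(self):
        assert silent_jaccard([_silent_snp(5)], [_silent_snp(50)]) == 1.0

    def test_half_overlap(self):
        a = [_silent_snp(5), _silent_snp(50), _silent_snp(100)]
        b = [_silent_snp(5), _silent_snp(50), _silent_snp(200)]
        # |A ∩ B| = 2, |A ∪ B| = 4
        assert silent_jaccard(a, b) == pytest.approx(0.5)

    def test_both_empty(self):
        assert silent_jaccard([], []) == 0.0

    def test_bounds(self, rng):
        for _ in range(50):
            a = [_silent_snp(int(p)) for p in rng.choice(400, size=int(rng.integers(0, 6)), replace=False)]
            b = [_silent_snp(int(p)) for p in rng.choice(400, size=int(rng.integers(0, 6)), replace=False)]
            assert 0.0 <= silent_jaccard(a, b) <= 1.0


class TestCallAllele:
    def test_core_agreement_beats_silent_difference(self):
        shared_core = [_core_snp(100)]
        a2 = _allele("G1*002", shared_core + [_silent_snp(300)])
        a3 = _allele("G1*003", [_silent_snp(300)])
        copy = _copy(variants=shared_core)
        call, table = call_allele(copy, [a2, a3], _index([100]), WT)
        assert call == "G1*002"
        # a3 agrees on zero silent variants AND mismatches the core position
        assert table[0].core_score < table[1].core_score

    def test_silent_jaccard_breaks_core_ties(self):
        core = [_core_snp(100)]
        a2 = _allele("G1*002", core + [_silent_snp(300)])
        a3 = _allele("G1*003", core + [_silent_snp(300), _silent_snp(400)])
        copy = _copy(variants=core + [_silent_snp(300)])
        call, table = call_allele(copy, [a3, a2], _index([100]), WT)
        assert call == "G1*002"
        assert table[0].core_score == table[1].core_score

    def test_numeric_suffix_breaks_exact_ties(self):
        a10 = _allele("G1*010")
        a2 = _allele("G1*002")
        call, _ = call_allele(_copy(), [a10, a2], _index([]), WT)
        assert call == "G1*002"

    def test_single_allele_gene(self):
        call, table = call_allele(
            _copy(variants=[_core_snp(100)]), [_allele("G1*001")], _index([100]), WT
        )
        assert call == "G1*001"
        assert len(table) == 1

    def test_top5_retained(self):
        alleles = [_allele(f"G1*{n:03d}") for n in range(1, 9)]
        _, table = call_allele(_copy(), alleles, _index([]), WT)
        assert len(table) == 5

    def test_core_first_dominance(self, rng):
        """An allele with strictly smaller core score always outranks one with
        a smaller silent Jaccard but a larger core score."""
        core = [_core_snp(100)]
        good_core = _allele("G1*007", core + [_silent_snp(300), _silent_snp(400)])
        good_silent = _allele("G1*005", [_silent_snp(200)])
        copy = _copy(variants=core + [_silent_snp(200)])
        call, table = call_allele(copy, [good_silent, good_core], _index([100]), WT)
        assert call == "G1*007"
        scores = [(s.core_score, s.silent_jaccard) for s in table]
        assert scores == sorted(scores)
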