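import pytest

from kirannot.database import (
    AlleleRecord,
    DatabaseError,
    allele_number,
    build_core_index,
    infer_genomic_sequence,
    load_database,
    save_database,
)
from kirannot.variants import Variant, apply_variants

from oracles import splice_substitute_oracle


def _write_fixture(tmp_path, fasta_records, gene_rows):
    fasta = tmp_path / "db.fa"
    with open(fasta, "w") as fh:
        for header, seq in fasta_records:
            fh.write(f">{header}\n{seq}\n")
    with open(tmp_path / "db.genes.tsv", "w") as fh:
        for row in gene_rows:
            fh.write("\t".join(row) + "\n")
    return fasta


class TestLoading:
    def test_counts_preserved(self, toy_db):
        assert len(toy_db.genes) == 2
        assert len(toy_db.alleles) == 6
        for gene in toy_db.genes.values():
            assert gene.wildtype_allele in toy_db.alleles

    def test_wildtype_allele_has_no_variants(self, toy_db):
        for gene in toy_db.genes.values():
            assert toy_db.alleles[gene.wildtype_allele].variants == []

    def test_alleles_identical_to_wildtype_have_empty_variant_lists(self, tmp_path, mini_gene):
        seq = mini_gene.wildtype_seq
        fasta = _write_fixture(
            tmp_path,
            [("KIRMINI*001 kind=genomic", seq), ("KIRMINI*002 kind=genomic", seq)],
            [("KIRMINI", "KIRMINI*001", "21-32;53-64", "3-6", "0", "0")],
        )
        db = load_database(fasta)
        assert all(a.variants == [] for a in db.alleles.values())
        assert len(db.core_index["KIRMINI"]) == 0

    def test_core_silent_partition_matches_generator_truth(self, toy_fixture):
        """The load-time mutate-splice-translate partition reproduces the
        certified partition planted by the fixture generator."""
        for name, truth in toy_fixture.truth_partition.items():
            allele = toy_fixture.db.alleles[name]
            assert sorted(v.render() for v in allele.core_variants) == sorted(truth["core"])
            assert sorted(v.render() for v in allele.silent_variants) == sorted(truth["silent"])

    def test_variants_reconstruct_genomic_seq(self, toy_db):
        for allele in toy_db.alleles.values():
            gene = toy_db.genes[allele.gene]
            assert apply_variants(gene.wildtype_seq, allele.variants) == allele.genomic_seq

    def test_roundtrip_preserves_variants_and_index(self, toy_db, tmp_path):
        save_database(toy_db, tmp_path / "dump.fa")
        reloaded = load_database(tmp_path / "dump.fa")
        for name, allele in toy_db.alleles.items():
            assert [v.key() for v in reloaded.alleles[name].variants] == [
                v.key() for v in allele.variants
            ]
        for gene in toy_db.genes:
            assert reloaded.core_index[gene].positions == toy_db.core_index[gene].positions

    @pytest.mark.parametrize(
        "records,rows,message",
        [
            ([("BADHEADER", "ACGT")], [], "malformed"),
            (
                [("G1*001 kind=cdna", "ACGTACGT")],
                [("G1", "G1*001", "1-8", ".", "0", "1")],
                "no genomic",
            ),
            (
                [("G1*001 kind=genomic", "ACGTACGT")],
                [("G1", "G1*001", "1-8", ".", "0", "1"), ("BAD",)],
                "columns",
            ),
        ],
    )
    def test_malformed_inputs_raise(self, tmp_path, records, rows, message):
        fasta = _write_fixture(tmp_path, records, rows)
        with pytest.raises(DatabaseError, match=message):
            load_database(fasta)


class TestCdnaInference:
    def test_cdna_equal_to_wildtype_exons_reconstructs_wildtype(self, mini_gene):
        wt_allele = AlleleRecord("KIRMINI*001", mini_gene.wildtype_seq, "genomic",
                                 genomic_seq=mini_gene.wildtype_seq)
        cdna = AlleleRecord("KIRMINI*005", mini_gene.spliced(), "cdna")
        assert infer_genomic_sequence(cdna, mini_gene, [wt_allele]) == mini_gene.wildtype_seq

    def test_single_exonic_substitution_lifted_to_genomic_coordinate(self, mini_gene):
        spliced = mini_gene.spliced()
        mutated = spliced[:5] + "T" + spliced[6:]  # exon1 offset 5 -> genomic 25
        assert mutated != spliced
        wt_allele = AlleleRecord("KIRMINI*001", mini_gene.wildtype_seq, "genomic",
                                 genomic_seq=mini_gene.wildtype_seq)
        cdna = AlleleRecord("KIRMINI*005", mutated, "cdna")
        result = infer_genomic_sequence(cdna, mini_gene, [wt_allele])
        assert result == splice_substitute_oracle(
            mini_gene.wildtype_seq, mini_gene.exons, mutated
        )
        assert result[25] == "T"

    def test_genomic_seq_differs_from_backbone_only_inside_exons(self, toy_db):
        for allele in toy_db.alleles.values():
            if allele.seq_kind != "cdna":
                continue
            gene = toy_db.genes[allele.gene]
            backbone = gene.wildtype_seq  # toy cDNA alleles sit on the wildtype
            diffs = [
                i for i, (a, b) in enumerate(zip(allele.genomic_seq, backbone)) if a != b
            ]
            assert diffs, "cDNA allele should differ from wildtype"
            for pos in diffs:
                assert any(s <= pos < e for s, e in gene.exons)

    def test_nearest_backbone_chosen_by_spliced_edit_distance(self, mini_gene):
        spliced = mini_gene.spliced()
        # backbone B: five exonic substitutions vs. wildtype
        b_spliced = list(spliced)
        for off in (4, 7, 10, 13, 16):
            b_spliced[off] = "A" if spliced[off] != "A" else "C"
        b_genomic = splice_substitute_oracle(
            mini_gene.wildtype_seq, mini_gene.exons, "".join(b_spliced)
        )
        wt_allele = AlleleRecord("KIRMINI*001", mini_gene.wildtype_seq, "genomic",
                                 genomic_seq=mini_gene.wildtype_seq)
        # give backbone B SNP-only variants so its exon table lifts unchanged
        b_allele = AlleleRecord("KIRMINI*002", b_genomic, "genomic", genomic_seq=b_genomic)
        # cDNA = backbone B's exons with one further substitution: 1 edit from B, ~5 from wildtype
        cdna_seq = "".join(b_spliced)
        cdna_seq = cdna_seq[:20] + ("G" if cdna_seq[20] != "G" else "T") + cdna_seq[21:]
        cdna = AlleleRecord("KIRMINI*005", cdna_seq, "cdna")
        result = infer_genomic_sequence(cdna, mini_gene, [wt_allele, b_allele])
        # introns must come from backbone B (identical to wildtype introns here),
        # exons from the cDNA
        assert result == splice_substitute_oracle(
            mini_gene.wildtype_seq, mini_gene.exons, cdna_seq
        )

    def test_irreconcilable_cdna_is_rejected(self, mini_gene):
        wt_allele = AlleleRecord("KIRMINI*001", mini_gene.wildtype_seq, "genomic",
                                 genomic_seq=mini_gene.wildtype_seq)
        cdna = AlleleRecord("KIRMINI*005", "ACGT", "cdna")
        with pytest.raises(DatabaseError):
            infer_genomic_sequence(cdna, mini_gene, [wt_allele])


class TestCoreIndex:
    def _allele(self, name, variants):
        return AlleleRecord(name, "", "genomic", variants=variants)

    def test_silent_only_alleles_give_empty_index(self, mini_gene):
        a = self._allele(
            "KIRMINI*002",
            [Variant(pos=35, ref="G", alt="A", kind="snp", effect="intronic", core=False)],
        )
        assert build_core_index(mini_gene, [a]).positions == ()

    def test_indel_positions_counted_independently(self, mini_gene):
        a = self._allele(
            "KIRMINI*002",
            [Variant(pos=120, ref="A", alt="G", kind="snp", effect="missense", core=True)],
        )
        b = self._allele(
            "KIRMINI*003",
            [
                Variant(pos=120, ref="A", alt="G", kind="snp", effect="missense", core=True),
                Variant(pos=10520, ref="CAT", alt="", kind="del", effect="frameshift", core=True),
            ],
        )
        index = build_core_index(mini_gene, [a, b])
        assert index.positions == (120, 10520, 10521, 10522)

    def test_shared_core_snp_deduplicated(self, mini_gene):
        v = Variant(pos=120, ref="A", alt="G", kind="snp", effect="missense", core=True)
        index = build_core_index(
            mini_gene, [self._allele("KIRMINI*002", [v]), self._allele("KIRMINI*003", [v])]
        )
        assert len(index) == 1

    def test_index_monotone_under_added_alleles(self, toy_db):
        for gene_name, gene in toy_db.genes.items():
            alleles = toy_db.gene_alleles(gene_name)
            seen: set[int] = set()
            for k in range(len(alleles) + 1):
                positions = set(build_core_index(gene, alleles[:k]).positions)
                assert seen <= positions
                seen = positions

    def test_empty_allele_list_gives_empty_index(self, mini_gene):
        assert len(build_core_index(mini_gene, [])) == 0


def test_allele_number_parsing():
    assert allele_number("KIR2DL4*0050101") == 50101
    assert allele_number("KIRTOY1*002") == 2


class TestIpdFlatfileAdapter:
    @staticmethod
    def _record(entry_id, name, seq, exon_lines):
        def sq_lines(s):
            out = []
            for i in range(0, len(s), 60):
                chunk = s[i : i + 60]
                groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
                out.append(f"     {groups:<66}{min(i + 60, len(s)):>9}")
            return "\n".join(out)

        ft = "\n".join(f"FT   exon            {s}..{e}" for s, e in exon_lines)
        return (
            f"ID   {entry_id}; SV 1; linear; genomic DNA; HTC; HUM; {len(seq)} BP.\n"
            "XX\n"
            f"DE   {name}, Human Killer-cell Immunoglobulin-like Receptor\n"
            "XX\n"
            "FH   Key             Location/Qualifiers\n"
            "FH\n"
            f"FT   source          1..{len(seq)}\n"
            f"{ft}\n"
            "XX\n"
            f"SQ   Sequence {len(seq)} BP;\n"
            f"{sq_lines(seq)}\n"
            "//\n"
        )

    def test_embl_style_release_loads(self, mini_gene, tmp_path):
        """A synthetic EMBL/IMGT-style flat file (genomic wildtype plus a
        cDNA-form allele) loads through the flat-file adapter."""
        genomic = mini_gene.wildtype_seq.lower()
        spliced = mini_gene.spliced().lower()
        # cDNA allele with one exonic substitution at spliced offset 7
        cdna = spliced[:7] + ("a" if spliced[7] != "a" else "g") + spliced[8:]
        flat = tmp_path / "release.dat"
        flat.write_text(
            self._record("KIR00001", "KIRMINI*001", genomic,
                         [(s + 1, e) for s, e in mini_gene.exons])
            + self._record("KIR00002", "KIRMINI*002", cdna, [(1, len(cdna))])
        )
        db = load_database(flat, dialect="ipd_flatfile")
        assert set(db.alleles) == {"KIRMINI*001", "KIRMINI*002"}
        assert db.alleles["KIRMINI*001"].seq_kind == "genomic"
        assert db.alleles["KIRMINI*002"].seq_kind == "cdna"
        gene = db.genes["KIRMINI"]
        assert gene.wildtype_allele == "KIRMINI*001"
        assert gene.exons == mini_gene.exons
        (v,) = db.alleles["KIRMINI*002"].variants
        assert v.pos == mini_gene.exons[0][0] + 7  # lifted to genomic coordinates
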