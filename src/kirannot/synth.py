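"""Deterministic generator of toy KIR-like allele databases and synthetic
assemblies with known ground truth.

The generated databases mimic the structure of the real allele database —
multi-exon genes with UTRs and introns, genomic and cDNA-form alleles,
alleles differing from the wildtype by planted variants of known functional
class — at a scale where every pipeline stage can be verified exactly.
Every planted variant is certified by the package's own mutate–splice–
translate classifier before emission, so the declared core/silent partition
is ground truth by construction.

Intergenic spacers are rejection-sampled to share no k-mer with any database
allele, so the builtin mapper cannot produce spurious candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import reverse_complement

from .database import AlleleDatabase, AlleleRecord, GeneDefinition, load_database
from .variants import Variant, apply_variants, classify_effect

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
)


class GenerationError(RuntimeError):
    pass


@dataclass
class PlantSpec:
    """One gene copy to plant into a synthetic assembly."""

    allele: str
    strand: str = "+"
    truncate_head: int = 0
    truncate_tail: int = 0
    novel_effects: tuple[str, ...] = ()


@dataclass
class PlantedCopy:
    contig: str
    start: int
    end: int
    strand: str
    gene: str
    allele: str
    novel_variants: list[Variant] = field(default_factory=list)
    truncate_head: int = 0
    truncate_tail: int = 0


@dataclass
class TruthTable:
    copies: list[PlantedCopy]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# contig\tstart\tend\tstrand\tgene\tallele\t"
                "novel_variants\ttruncate_head\ttruncate_tail\n"
            )
            for c in self.copies:
                novel = ";".join(v.render() for v in c.novel_variants) or "."
                fh.write(
                    f"{c.contig}\t{c.start + 1}\t{c.end}\t{c.strand}\t{c.gene}\t"
                    f"{c.allele}\t{novel}\t{c.truncate_head}\t{c.truncate_tail}\n"
                )


# ---------------------------------------------------------------------------
# gene and variant synthesis


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _make_gene(
    rng: np.random.Generator,
    name: str,
    n_exons: int = 3,
    utr_len: int = 300,
    exon_len_range: tuple[int, int] = (150, 300),
    intron_len_range: tuple[int, int] = (300, 500),
) -> GeneDefinition:
    exon_lens = [int(rng.integers(*exon_len_range)) for _ in range(n_exons)]
    total = sum(exon_lens)
    exon_lens[-1] += (3 - total % 3) % 3  # CDS length a multiple of 3
    intron_lens = [int(rng.integers(*intron_len_range)) for _ in range(n_exons - 1)]

    n_codons = sum(exon_lens) // 3
    codons = ["ATG"]
    codons += [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)]
    codons.append(_STOPS[int(rng.integers(0, 3))])
    cds = "".join(codons)

    pieces = [_random_seq(rng, utr_len)]
    exons: list[tuple[int, int]] = []
    offset = 0
    pos = utr_len
    for i, el in enumerate(exon_lens):
        pieces.append(cds[offset : offset + el])
        exons.append((pos, pos + el))
        offset += el
        pos += el
        if i < n_exons - 1:
            pieces.append(_random_seq(rng, intron_lens[i]))
            pos += intron_lens[i]
    pieces.append(_random_seq(rng, utr_len))
    seq = "".join(pieces)

    gene = GeneDefinition(
        name=name,
        wildtype_allele=f"{name}*001",
        wildtype_seq=seq,
        exons=exons,
        functional_utr=[(100, 130)],
    )
    gene.validate()
    return gene


def _plant_variant(
    gene: GeneDefinition,
    rng: np.random.Generator,
    effect: str,
    occupied: set[int],
    edge_margin: int = 30,
    max_tries: int = 500,
) -> Variant:
    """Draw a random variant of the requested functional class, certified by
    the effect classifier; avoids previously used footprints."""
    wt = gene.wildtype_seq
    n = len(wt)
    exon_positions = [p for s, e in gene.exons for p in range(s + 3, e - 3)]
    first_exon_start = gene.exons[0][0]
    intron_positions = [
        p
        for i in range(len(gene.exons) - 1)
        for p in range(gene.exons[i][1] + 5, gene.exons[i + 1][0] - 5)
    ]
    functional = [p for s, e in gene.functional_utr for p in range(s, e)]
    utr_silent_pos = [
        p
        for p in list(range(edge_margin, first_exon_start - 5))
        + list(range(gene.exons[-1][1] + 5, n - edge_margin))
        if not any(s <= p < e for s, e in gene.functional_utr)
    ]

    for _ in range(max_tries):
        if effect in ("missense", "synonymous", "nonsense"):
            pos = exon_positions[int(rng.integers(0, len(exon_positions)))]
            alt = _BASES[int(rng.integers(0, 4))]
            if alt == wt[pos]:
                continue
            candidate = Variant(pos=pos, ref=wt[pos], alt=alt, kind="snp")
        elif effect == "frameshift":
            pos = exon_positions[int(rng.integers(0, len(exon_positions)))]
            candidate = Variant(pos=pos, ref=wt[pos], alt="", kind="del")
        elif effect == "inframe_del":
            pos = exon_positions[int(rng.integers(0, len(exon_positions) - 3))]
            if pos + 3 > gene.exons[-1][1]:
                continue
            candidate = Variant(pos=pos, ref=wt[pos : pos + 3], alt="", kind="del")
        elif effect == "intronic":
            pos = intron_positions[int(rng.integers(0, len(intron_positions)))]
            alt = _BASES[int(rng.integers(0, 4))]
            if alt == wt[pos]:
                continue
            candidate = Variant(pos=pos, ref=wt[pos], alt=alt, kind="snp")
        elif effect == "start_loss":
            pos = first_exon_start + int(rng.integers(0, 3))
            alt = _BASES[int(rng.integers(0, 4))]
            if alt == wt[pos]:
                continue
            candidate = Variant(pos=pos, ref=wt[pos], alt=alt, kind="snp")
        elif effect == "utr_functional":
            pos = functional[int(rng.integers(0, len(functional)))]
            alt = _BASES[int(rng.integers(0, 4))]
            if alt == wt[pos]:
                continue
            candidate = Variant(pos=pos, ref=wt[pos], alt=alt, kind="snp")
        elif effect == "utr_silent":
            pos = utr_silent_pos[int(rng.integers(0, len(utr_silent_pos)))]
            alt = _BASES[int(rng.integers(0, 4))]
            if alt == wt[pos]:
                continue
            candidate = Variant(pos=pos, ref=wt[pos], alt=alt, kind="snp")
        else:
            raise GenerationError(f"unknown effect class {effect!r}")

        # keep footprints well apart so alignment recovers each independently
        footprint = set(range(candidate.pos - 8, candidate.end + 8))
        if footprint & occupied:
            continue
        classified = classify_effect(candidate, gene)
        want = "missense" if effect == "inframe_del" else effect
        if classified.effect != want:
            continue
        occupied.update(footprint)
        return classified
    raise GenerationError(f"could not plant a {effect} variant in {gene.name}")


# default variant-class menus cycled over non-wildtype alleles
_ALLELE_MENUS = (
    ("missense", "synonymous"),
    ("missense", "intronic", "synonymous"),
    ("nonsense", "intronic"),
    ("frameshift", "utr_silent"),
    ("missense", "missense", "intronic"),
)


@dataclass
class ToyFixture:
    db_fasta: Path
    db: AlleleDatabase
    # allele name -> {"core": [...], "silent": [...]} rendered variant strings
    truth_partition: dict[str, dict[str, list[str]]]


def make_toy_database(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 2,
    alleles_per_gene: int = 3,
    include_cdna: bool = False,
    allele_menus: tuple[tuple[str, ...], ...] = _ALLELE_MENUS,
) -> ToyFixture:
    """Generate a fixture database (FASTA + gene sidecar) and load it back.

    Deterministic for a given seed.  When ``include_cdna`` is set, the last
    allele of each gene is emitted in cDNA (spliced) form only.
    """
    if n_genes < 1 or alleles_per_gene < 1:
        raise GenerationError("counts must be positive")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes: list[GeneDefinition] = []
    records: list[tuple[str, str, str]] = []  # (name, kind, seq)
    truth: dict[str, dict[str, list[str]]] = {}

    for g in range(n_genes):
        gene = _make_gene(rng, f"KIRTOY{g + 1}")
        genes.append(gene)
        records.append((gene.wildtype_allele, "genomic", gene.wildtype_seq))
        truth[gene.wildtype_allele] = {"core": [], "silent": []}
        for a in range(1, alleles_per_gene):
            name = f"{gene.name}*{a + 1:03d}"
            is_cdna = include_cdna and a == alleles_per_gene - 1
            # a cDNA-form allele carries only exonic SNPs: its transcript has
            # no introns/UTRs, and SNPs keep wildtype exon coordinates valid
            menu = (
                ("missense", "synonymous")
                if is_cdna
                else allele_menus[(a - 1) % len(allele_menus)]
            )
            occupied: set[int] = set()
            planted = [_plant_variant(gene, rng, eff, occupied) for eff in menu]
            planted.sort(key=lambda v: v.pos)
            seq = apply_variants(gene.wildtype_seq, planted)
            if is_cdna:
                records.append((name, "cdna", gene.spliced(seq)))
            else:
                records.append((name, "genomic", seq))
            truth[name] = {
                "core": [v.render() for v in planted if v.core],
                "silent": [v.render() for v in planted if not v.core],
            }

    fasta = out_dir / "toy_db.fa"
    sidecar = out_dir / "toy_db.genes.tsv"
    with open(fasta, "w") as fh:
        for name, kind, seq in records:
            fh.write(f">{name} kind={kind}\n{seq}\n")
    with open(sidecar, "w") as fh:
        fh.write("# gene\twildtype\texons\tfunctional_utr\tcds_phase\tpseudogene\n")
        for gene in genes:
            exons = ";".join(f"{s + 1}-{e}" for s, e in gene.exons)
            utr = ";".join(f"{s + 1}-{e}" for s, e in gene.functional_utr)
            fh.write(f"{gene.name}\t{gene.wildtype_allele}\t{exons}\t{utr}\t0\t0\n")

    db = load_database(fasta, dialect="fixture")
    return ToyFixture(db_fasta=fasta, db=db, truth_partition=truth)


# ---------------------------------------------------------------------------
# synthetic assemblies


def _kmer_set(seqs: list[str], k: int) -> set[str]:
    kmers: set[str] = set()
    for seq in seqs:
        for s in (seq, reverse_complement(seq)):
            for i in range(len(s) - k + 1):
                kmers.add(s[i : i + k])
    return kmers


def _clean_spacer(
    rng: np.random.Generator, length: int, forbidden: set[str], k: int, max_tries: int = 50
) -> str:
    for _ in range(max_tries):
        spacer = _random_seq(rng, length)
        if not any(spacer[i : i + k] in forbidden for i in range(len(spacer) - k + 1)):
            return spacer
    raise GenerationError("could not sample an allele-free spacer")


def _plant_novel(
    db: AlleleDatabase,
    gene: GeneDefinition,
    allele: AlleleRecord,
    rng: np.random.Generator,
    effect: str,
) -> Variant:
    """A novel variant: certified effect class, absent from every allele of
    the gene, and (for core classes) with a footprint outside the gene's
    core-position index so it is counted as novel rather than as a
    core-position mismatch."""
    index = set(db.core_index[gene.name].positions)
    known = {
        v.key() for a in db.gene_alleles(gene.name) for v in a.variants
    }
    occupied: set[int] = set()
    for a in db.gene_alleles(gene.name):
        for v in a.variants:
            occupied.update(range(v.pos - 8, v.end + 8))
    for _ in range(200):
        trial_occupied = set(occupied)
        v = _plant_variant(gene, rng, effect, trial_occupied)
        if v.key() in known:
            continue
        if v.core and any(p in index for p in v.footprint()):
            continue
        return v
    raise GenerationError(f"could not plant novel {effect} variant in {gene.name}")


def make_synthetic_assembly(
    db: AlleleDatabase,
    plants: list[PlantSpec],
    seed: int = 0,
    out_dir: str | Path | None = None,
    spacer_len: int = 2000,
    kmer_size: int = 21,
    contig_name: str = "contig_1",
) -> tuple[dict[str, str], TruthTable]:
    """Build a synthetic assembly containing the requested gene copies,
    separated by allele-free intergenic spacers.  Deterministic per seed.
    Returns the contigs and a truth table; writes FASTA + truth TSV when
    ``out_dir`` is given.
    """
    rng = np.random.default_rng(seed)
    forbidden = _kmer_set(
        [a.genomic_seq for a in db.mappable_alleles()], kmer_size
    )

    pieces: list[str] = [_clean_spacer(rng, spacer_len, forbidden, kmer_size)]
    pos = len(pieces[0])
    copies: list[PlantedCopy] = []
    for plant in plants:
        allele = db.alleles[plant.allele]
        gene = db.genes[allele.gene]
        novel: list[Variant] = []
        if plant.novel_effects:
            for eff in plant.novel_effects:
                novel.append(_plant_novel(db, gene, allele, rng, eff))
            seq = apply_variants(
                gene.wildtype_seq,
                sorted(allele.variants + novel, key=lambda v: v.pos),
            )
        else:
            seq = allele.genomic_seq
        if plant.truncate_head or plant.truncate_tail:
            seq = seq[plant.truncate_head : len(seq) - plant.truncate_tail or None]
        if not seq:
            raise GenerationError("plant truncated to nothing")
        oriented = seq if plant.strand == "+" else reverse_complement(seq)
        copies.append(
            PlantedCopy(
                contig=contig_name,
                start=pos,
                end=pos + len(oriented),
                strand=plant.strand,
                gene=gene.name,
                allele=plant.allele,
                novel_variants=novel,
                truncate_head=plant.truncate_head,
                truncate_tail=plant.truncate_tail,
            )
        )
        pieces.append(oriented)
        pos += len(oriented)
        spacer = _clean_spacer(rng, spacer_len, forbidden, kmer_size)
        pieces.append(spacer)
        pos += len(spacer)

    contigs = {contig_name: "".join(pieces)}
    truth = TruthTable(copies=copies)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "assembly.fa", "w") as fh:
            for name in sorted(contigs):
                fh.write(f">{name}\n{contigs[name]}\n")
        truth.write(out_dir / "truth.tsv")
    return contigs, truth
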