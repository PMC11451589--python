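"""The allele-database layer: gene definitions, allele records, and the
per-gene core-position index.

Two on-disk dialects are supported:

* ``fixture`` — a FASTA of allele sequences (headers ``GENE*NNN kind=genomic``
  or ``kind=cdna``) plus a tab-separated sidecar (``<stem>.genes.tsv``)
  giving, per gene: the wildtype allele, exon intervals, functionally-relevant
  UTR intervals, CDS phase and pseudogene flag.  Intervals in the sidecar are
  1-based inclusive; everything in memory is 0-based half-open.
* ``ipd_flatfile`` — a best-effort adapter for EMBL/IMGT-style flat files as
  released by IPD-KIR, parsed with Biopython's ``imgt`` reader.

On load every allele is given a genomic sequence (cDNA-only alleles are
spliced onto the nearest genomic backbone), its variant set vs. the gene
wildtype is computed by semi-global alignment and classified into core and
silent, and the gene's core-position index is built.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
from Bio import SeqIO

from .alignment import ScoringScheme
from .variants import Variant, call_variants

log = logging.getLogger(__name__)

_HEADER_RE = re.compile(r"^(?P<name>[A-Za-z0-9_.-]+\*\d+)(\s+kind=(?P<kind>genomic|cdna))?")


class DatabaseError(ValueError):
    pass


def allele_number(name: str) -> int:
    """Numeric suffix of ``GENE*NNNNN`` (used for deterministic tie-breaks)."""
    return int(name.split("*", 1)[1])


def gene_of(name: str) -> str:
    return name.split("*", 1)[0]


@dataclass
class GeneDefinition:
    name: str
    wildtype_allele: str
    wildtype_seq: str
    exons: list[tuple[int, int]]
    cds_phase: int = 0
    functional_utr: list[tuple[int, int]] = field(default_factory=list)
    pseudogene: bool = False

    def validate(self) -> None:
        n = len(self.wildtype_seq)
        prev = 0
        for s, e in self.exons:
            if not (0 <= s < e <= n):
                raise DatabaseError(f"{self.name}: exon [{s},{e}) outside [0,{n})")
            if s < prev:
                raise DatabaseError(f"{self.name}: exons overlap or unsorted")
            prev = e
        if not self.pseudogene and self.exons:
            cds_len = sum(e - s for s, e in self.exons) - self.cds_phase
            if cds_len % 3 != 0:
                raise DatabaseError(
                    f"{self.name}: CDS length {cds_len} not a multiple of 3"
                )

    def spliced(self, seq: str | None = None) -> str:
        seq = seq if seq is not None else self.wildtype_seq
        return "".join(seq[s:e] for s, e in self.exons)


@dataclass
class AlleleRecord:
    allele_name: str
    seq: str
    seq_kind: str  # genomic | cdna
    genomic_seq: str = ""
    variants: list[Variant] = field(default_factory=list)
    flagged: bool = False  # cDNA incompatible with backbone; excluded from mapping

    @property
    def gene(self) -> str:
        return gene_of(self.allele_name)

    @property
    def core_variants(self) -> list[Variant]:
        return [v for v in self.variants if v.core]

    @property
    def silent_variants(self) -> list[Variant]:
        return [v for v in self.variants if not v.core]


@dataclass
class CorePositionIndex:
    gene: str
    positions: tuple[int, ...]  # sorted, deduplicated wildtype coordinates

    def __len__(self) -> int:
        return len(self.positions)

    def __contains__(self, pos: int) -> bool:
        return pos in set(self.positions)


@dataclass
class AlleleDatabase:
    genes: dict[str, GeneDefinition]
    alleles: dict[str, AlleleRecord]
    core_index: dict[str, CorePositionIndex]

    def gene_alleles(self, gene: str) -> list[AlleleRecord]:
        return sorted(
            (a for a in self.alleles.values() if a.gene == gene),
            key=lambda a: allele_number(a.allele_name),
        )

    def mappable_alleles(self) -> list[AlleleRecord]:
        return sorted(
            (a for a in self.alleles.values() if not a.flagged),
            key=lambda a: a.allele_name,
        )


# ---------------------------------------------------------------------------
# core index


def build_core_index(gene: GeneDefinition, alleles: list[AlleleRecord]) -> CorePositionIndex:
    """Union of wildtype positions touched by any allele's core variants.

    Every position of a multi-base deletion contributes independently; an
    insertion contributes its anchor position.
    """
    positions: set[int] = set()
    for allele in alleles:
        for v in allele.core_variants:
            positions.update(v.footprint())
    return CorePositionIndex(gene=gene.name, positions=tuple(sorted(positions)))


# ---------------------------------------------------------------------------
# cDNA -> genomic inference


def infer_genomic_sequence(
    cdna_allele: AlleleRecord,
    gene: GeneDefinition,
    genomic_alleles: list[AlleleRecord],
) -> str:
    """Give a cDNA-only allele a genomic sequence.

    The backbone is the genomic allele whose spliced exon sequence is nearest
    to the cDNA by edit distance (ties: lowest allele number); its exonic
    bases are replaced by the cDNA's, introns are kept unchanged.

    Raises :class:`DatabaseError` when the cDNA cannot be reconciled with the
    backbone exon structure (caller flags the allele rather than aborting).
    """
    if not genomic_alleles:
        raise DatabaseError(f"{gene.name}: no genomic allele to anchor {cdna_allele.allele_name}")

    cdna = cdna_allele.seq
    best: tuple[int, int, AlleleRecord] | None = None
    for backbone in genomic_alleles:
        spliced = _spliced_on_backbone(gene, backbone)
        dist = edlib.align(cdna, spliced, task="distance")["editDistance"]
        key = (dist, allele_number(backbone.allele_name))
        if best is None or key < (best[0], best[1]):
            best = (dist, key[1], backbone)
    dist, _, backbone = best

    spliced = _spliced_on_backbone(gene, backbone)
    if dist > 0.2 * len(spliced) or abs(len(cdna) - len(spliced)) > 0.2 * len(spliced):
        raise DatabaseError(
            f"{cdna_allele.allele_name}: cDNA irreconcilable with backbone "
            f"{backbone.allele_name} (edit distance {dist}, lengths "
            f"{len(cdna)} vs {len(spliced)})"
        )

    # map spliced-backbone coordinates to cDNA coordinates via the edlib path
    aln = edlib.align(cdna, spliced, task="path", mode="NW")
    lift = _cigar_lift(aln["cigar"], len(spliced))

    exons = _backbone_exons(gene, backbone)
    pieces: list[str] = []
    cursor = 0
    offset = 0  # spliced coordinate of current exon start
    bseq = backbone.genomic_seq or backbone.seq
    for s, e in exons:
        pieces.append(bseq[cursor:s])
        pieces.append(cdna[lift[offset] : lift[offset + (e - s)]])
        offset += e - s
        cursor = e
    pieces.append(bseq[cursor:])
    return "".join(pieces)


def _spliced_on_backbone(gene: GeneDefinition, backbone: AlleleRecord) -> str:
    seq = backbone.genomic_seq or backbone.seq
    return "".join(seq[s:e] for s, e in _backbone_exons(gene, backbone))


def _backbone_exons(gene: GeneDefinition, backbone: AlleleRecord) -> list[tuple[int, int]]:
    """Wildtype exon intervals lifted through the backbone's variant list."""
    if backbone.allele_name == gene.wildtype_allele or not backbone.variants:
        return list(gene.exons)
    from .variants import _lift

    exons = list(gene.exons)
    for v in sorted(backbone.variants, key=lambda v: v.pos, reverse=True):
        exons = [(_lift(s, v), _lift(e, v)) for s, e in exons]
    return exons


def _cigar_lift(cigar: str, ref_len: int) -> list[int]:
    """From an edlib NW cigar of query-vs-ref, map each ref coordinate
    (0..ref_len inclusive) to the corresponding query coordinate."""
    lift = [0] * (ref_len + 1)
    q = r = 0
    for length, op in re.findall(r"(\d+)([=XIDM])", cigar):
        length = int(length)
        if op in "=XM":
            for k in range(length):
                lift[r + k] = q + k
            q += length
            r += length
        elif op == "I":  # in query, absent from ref
            q += length
        else:  # D: in ref, absent from query
            for k in range(length):
                lift[r + k] = q
            r += length
    lift[ref_len] = q
    return lift


# ---------------------------------------------------------------------------
# loading


def load_database(
    path: str | Path,
    dialect: str = "fixture",
    scoring: ScoringScheme | None = None,
) -> AlleleDatabase:
    path = Path(path)
    if dialect == "fixture":
        genes, alleles = _read_fixture(path)
    elif dialect == "ipd_flatfile":
        genes, alleles = _read_ipd_flatfile(path)
    else:
        raise DatabaseError(f"unknown dialect {dialect!r}")
    return _finalize(genes, alleles, scoring)


def _finalize(
    genes: dict[str, GeneDefinition],
    alleles: dict[str, AlleleRecord],
    scoring: ScoringScheme | None,
) -> AlleleDatabase:
    for gene in genes.values():
        gene.validate()
        if gene.wildtype_allele not in alleles:
            raise DatabaseError(f"{gene.name}: wildtype allele {gene.wildtype_allele} absent")

    # genomic sequences for cDNA-only alleles
    for gene_name, gene in genes.items():
        genomic = [
            a for a in alleles.values() if a.gene == gene_name and a.seq_kind == "genomic"
        ]
        if not genomic:
            raise DatabaseError(f"{gene_name}: no genomic allele at all")
        for a in genomic:
            a.genomic_seq = a.seq
        # wildtype variants must be computed before backbone exon lifting
        for a in sorted(genomic, key=lambda a: allele_number(a.allele_name)):
            a.variants = _call_allele_variants(gene, a.genomic_seq, scoring)
        for a in alleles.values():
            if a.gene != gene_name or a.seq_kind != "cdna":
                continue
            try:
                a.genomic_seq = infer_genomic_sequence(a, gene, genomic)
            except DatabaseError as exc:
                log.warning("excluding allele from mapping set: %s", exc)
                a.flagged = True
                a.genomic_seq = a.seq
                continue
            a.variants = _call_allele_variants(gene, a.genomic_seq, scoring)

    index = {
        name: build_core_index(gene, [a for a in alleles.values() if a.gene == name and not a.flagged])
        for name, gene in genes.items()
    }
    return AlleleDatabase(genes=genes, alleles=alleles, core_index=index)


def _call_allele_variants(
    gene: GeneDefinition, genomic_seq: str, scoring: ScoringScheme | None
) -> list[Variant]:
    if genomic_seq == gene.wildtype_seq:
        return []
    variants, _ = call_variants(gene.wildtype_seq, genomic_seq, gene, scoring)
    return variants


# -- fixture dialect --------------------------------------------------------


def _parse_intervals(text: str) -> list[tuple[int, int]]:
    """``"10-309;700-999"`` (1-based inclusive) -> 0-based half-open."""
    if not text or text == ".":
        return []
    out = []
    for chunk in text.split(";"):
        s, e = chunk.split("-")
        out.append((int(s) - 1, int(e)))
    return out


def _format_intervals(intervals: list[tuple[int, int]]) -> str:
    if not intervals:
        return "."
    return ";".join(f"{s + 1}-{e}" for s, e in intervals)


def _read_fixture(path: Path) -> tuple[dict[str, GeneDefinition], dict[str, AlleleRecord]]:
    fasta = path
    sidecar = Path(str(path).rsplit(".", 1)[0] + ".genes.tsv")
    if not fasta.exists():
        raise DatabaseError(f"database FASTA not found: {fasta}")
    if not sidecar.exists():
        raise DatabaseError(f"gene sidecar not found: {sidecar}")

    alleles: dict[str, AlleleRecord] = {}
    for record in SeqIO.parse(str(fasta), "fasta"):
        m = _HEADER_RE.match(record.description)
        if not m:
            raise DatabaseError(f"{fasta}: malformed allele header {record.description!r}")
        name = m.group("name")
        kind = m.group("kind") or "genomic"
        if name in alleles:
            raise DatabaseError(f"{fasta}: duplicate allele {name}")
        alleles[name] = AlleleRecord(allele_name=name, seq=str(record.seq).upper(), seq_kind=kind)

    genes: dict[str, GeneDefinition] = {}
    with open(sidecar) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise DatabaseError(f"{sidecar}:{lineno}: expected 6 columns, got {len(fields)}")
            name, wildtype, exons, utr, phase, pseudo = fields
            if wildtype not in alleles:
                raise DatabaseError(f"{sidecar}:{lineno}: wildtype {wildtype} not in FASTA")
            genes[name] = GeneDefinition(
                name=name,
                wildtype_allele=wildtype,
                wildtype_seq=alleles[wildtype].seq,
                exons=_parse_intervals(exons),
                functional_utr=_parse_intervals(utr),
                cds_phase=int(phase),
                pseudogene=pseudo.lower() in ("1", "true", "yes"),
            )

    for name, allele in alleles.items():
        if allele.gene not in genes:
            raise DatabaseError(f"allele {name}: gene {allele.gene} not in sidecar")
    return genes, alleles


def save_database(db: AlleleDatabase, fasta_path: str | Path) -> None:
    """Dump a database back to the fixture dialect (FASTA + sidecar)."""
    fasta_path = Path(fasta_path)
    sidecar = Path(str(fasta_path).rsplit(".", 1)[0] + ".genes.tsv")
    with open(fasta_path, "w") as fh:
        for name in sorted(db.alleles):
            a = db.alleles[name]
            fh.write(f">{a.allele_name} kind={a.seq_kind}\n{a.seq}\n")
    with open(sidecar, "w") as fh:
        fh.write("# gene\twildtype\texons\tfunctional_utr\tcds_phase\tpseudogene\n")
        for name in sorted(db.genes):
            g = db.genes[name]
            fh.write(
                "\t".join(
                    [
                        g.name,
                        g.wildtype_allele,
                        _format_intervals(g.exons),
                        _format_intervals(g.functional_utr),
                        str(g.cds_phase),
                        "1" if g.pseudogene else "0",
                    ]
                )
                + "\n"
            )


# -- IPD-KIR flat-file adapter ----------------------------------------------

_KNOWN_PSEUDOGENES = {"KIR2DP1", "KIR3DP1"}


def _read_ipd_flatfile(path: Path) -> tuple[dict[str, GeneDefinition], dict[str, AlleleRecord]]:
    """Best-effort adapter for EMBL/IMGT-style releases (``KIR.dat``).

    Allele names are taken from the description line, exon features from the
    feature table.  A record is genomic when its exon features do not tile
    the sequence contiguously (i.e. introns are present).  The wildtype is
    the lowest-numbered genomic allele within 5% of the longest genomic
    sequence for the gene.
    """
    alleles: dict[str, AlleleRecord] = {}
    exon_tables: dict[str, list[tuple[int, int]]] = {}
    for record in SeqIO.parse(str(path), "imgt"):
        m = re.search(r"([A-Za-z0-9_.-]+\*\d+)", record.description or record.id)
        if not m:
            raise DatabaseError(f"{path}: cannot find allele name in record {record.id!r}")
        name = m.group(1)
        exons = sorted(
            (int(f.location.start), int(f.location.end))
            for f in record.features
            if f.type.lower() == "exon"
        )
        seq = str(record.seq).upper()
        spliced_len = sum(e - s for s, e in exons)
        contiguous = bool(exons) and spliced_len == exons[-1][1] - exons[0][0]
        kind = "cdna" if (not exons or contiguous) and spliced_len >= len(seq) else "genomic"
        if exons and (exons[0][0] > 0 or exons[-1][1] < len(seq)):
            kind = "genomic"  # flanking UTR sequence present
        alleles[name] = AlleleRecord(allele_name=name, seq=seq, seq_kind=kind)
        exon_tables[name] = exons

    genes: dict[str, GeneDefinition] = {}
    by_gene: dict[str, list[str]] = {}
    for name in alleles:
        by_gene.setdefault(gene_of(name), []).append(name)
    for gene_name, names in by_gene.items():
        genomic = [n for n in names if alleles[n].seq_kind == "genomic"]
        if not genomic:
            raise DatabaseError(f"{gene_name}: no genomic allele in flat file")
        max_len = max(len(alleles[n].seq) for n in genomic)
        full_length = [n for n in genomic if len(alleles[n].seq) >= 0.95 * max_len]
        wildtype = min(full_length, key=allele_number)
        genes[gene_name] = GeneDefinition(
            name=gene_name,
            wildtype_allele=wildtype,
            wildtype_seq=alleles[wildtype].seq,
            exons=exon_tables[wildtype],
            pseudogene=gene_name in _KNOWN_PSEUDOGENES,
        )
    return genes, alleles
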