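"""Locus discovery: map the allele set onto the assembly and consolidate
overlapping mappings into candidate gene regions.

Two mapper backends satisfy the same PAF-like contract:

* the builtin deterministic k-mer seed-and-extend mapper (default in tests
  and the fallback when no external mapper is available), and
* an adapter that shells out to ``minimap2`` and parses its PAF output.

Secondary and heavily clipped mappings are deliberately retained: a gene
copy carrying a large deletion or truncation is discovered precisely through
clipped partial mappings.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import reverse_complement

from .database import AlleleDatabase, gene_of

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MappingRecord:
    """One allele-to-contig mapping (PAF-like; 0-based half-open)."""

    allele_name: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    score: int
    clip5: int = 0
    clip3: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("mapping requires start < end")
        if self.clip5 < 0 or self.clip3 < 0:
            raise ValueError("clip lengths must be non-negative")

    @property
    def gene(self) -> str:
        return gene_of(self.allele_name)


@dataclass
class CandidateRegion:
    contig: str
    start: int
    end: int
    strand: str
    # gene symbol -> [mapping count, summed score]
    support: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_mappings(self) -> int:
        return sum(c for c, _ in self.support.values())


# ---------------------------------------------------------------------------
# builtin mapper


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _cluster_hits(
    hits: list[tuple[int, int]], k: int, band: int, max_gap: int
) -> list[tuple[int, int, int, int, int]]:
    """Cluster (qpos, tpos) seed hits into mappings.

    Hits are grouped when their diagonals agree within ``band`` (tolerating
    small indels) and they are not separated by more than ``max_gap`` on the
    target.  Returns (qstart, qend, tstart, tend, covered_query_bases).
    """
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h[1] - h[0], h[1]))
    clusters: list[list[tuple[int, int]]] = []
    for q, t in hits:
        placed = False
        for cluster in clusters:
            lq, lt = cluster[-1]
            if abs((t - q) - (lt - lq)) <= band and abs(t - lt) <= max_gap:
                cluster.append((q, t))
                placed = True
                break
        if not placed:
            clusters.append([(q, t)])
    out = []
    for cluster in clusters:
        qs = [q for q, _ in cluster]
        ts = [t for _, t in cluster]
        # covered query bases: union of the k-length seed intervals
        covered = 0
        prev_end = -1
        for q in sorted(set(qs)):
            covered += min(k, q + k - max(q, prev_end)) if q + k > prev_end else 0
            prev_end = max(prev_end, q + k)
        out.append((min(qs), max(qs) + k, min(ts), max(ts) + k, covered))
    return out


def builtin_map(
    db: AlleleDatabase,
    contigs: dict[str, str],
    kmer_size: int = 21,
    band: int = 100,
    max_gap: int = 2000,
    min_seeds: int = 2,
) -> list[MappingRecord]:
    """Deterministic exact-k-mer seed + extension mapper."""
    records: list[MappingRecord] = []
    k = kmer_size
    for contig_name in sorted(contigs):
        index = _kmer_index(contigs[contig_name].upper(), k)
        for allele in db.mappable_alleles():
            qlen = len(allele.genomic_seq)
            for strand in "+-":
                q = allele.genomic_seq if strand == "+" else reverse_complement(allele.genomic_seq)
                hits = [
                    (i, t)
                    for i in range(qlen - k + 1)
                    for t in index.get(q[i : i + k], ())
                ]
                for qs, qe, ts, te, covered in _cluster_hits(hits, k, band, max_gap):
                    if covered < min_seeds * k:
                        continue
                    records.append(
                        MappingRecord(
                            allele_name=allele.allele_name,
                            contig=contig_name,
                            start=ts,
                            end=te,
                            strand=strand,
                            score=covered,
                            clip5=qs,
                            clip3=qlen - qe,
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# minimap2 adapter


def minimap2_available() -> bool:
    return shutil.which("minimap2") is not None


def minimap2_map(db: AlleleDatabase, contigs: dict[str, str]) -> list[MappingRecord]:
    """Map alleles with the minimap2 executable and parse its PAF output."""
    with tempfile.TemporaryDirectory() as tmp:
        ref = Path(tmp) / "assembly.fa"
        qry = Path(tmp) / "alleles.fa"
        with open(ref, "w") as fh:
            for name in sorted(contigs):
                fh.write(f">{name}\n{contigs[name]}\n")
        with open(qry, "w") as fh:
            for allele in db.mappable_alleles():
                fh.write(f">{allele.allele_name}\n{allele.genomic_seq}\n")
        proc = subprocess.run(
            ["minimap2", "-N", "50", "-p", "0.1", str(ref), str(qry)],
            capture_output=True,
            text=True,
            check=True,
        )
    return parse_paf(proc.stdout.splitlines())


def parse_paf(lines: list[str]) -> list[MappingRecord]:
    records = []
    for line in lines:
        if not line.strip():
            continue
        f = line.split("\t")
        qname, qlen, qstart, qend = f[0], int(f[1]), int(f[2]), int(f[3])
        strand, tname, tstart, tend = f[4], f[5], int(f[7]), int(f[8])
        score = int(f[9])  # residue matches
        clip5 = qstart if strand == "+" else qlen - qend
        clip3 = qlen - qend if strand == "+" else qstart
        records.append(
            MappingRecord(
                allele_name=qname,
                contig=tname,
                start=tstart,
                end=tend,
                strand=strand,
                score=score,
                clip5=clip5,
                clip3=clip3,
            )
        )
    return records


def get_mapper(name: str):
    """Resolve a mapper backend; falls back to the builtin with a warning."""
    if name == "builtin":
        return builtin_map
    if name == "minimap2":
        if minimap2_available():
            return minimap2_map
        log.warning("minimap2 not found on PATH; falling back to builtin mapper")
        return builtin_map
    raise ValueError(f"unknown mapper {name!r}")


# ---------------------------------------------------------------------------
# consolidation and gene assignment


def consolidate(
    mappings: list[MappingRecord], gap_merge: int = 0
) -> list[CandidateRegion]:
    """Merge overlapping same-contig, same-strand mappings transitively.

    The region interval is the union span; support is aggregated per gene.
    Mappings separated by more than ``gap_merge`` bases are never merged
    (default: any positive gap keeps them apart).
    """
    by_group: dict[tuple[str, str], list[MappingRecord]] = {}
    for m in mappings:
        by_group.setdefault((m.contig, m.strand), []).append(m)

    regions: list[CandidateRegion] = []
    for (contig, strand) in sorted(by_group):
        group = sorted(by_group[(contig, strand)], key=lambda m: (m.start, m.end))
        current: CandidateRegion | None = None
        for m in group:
            if current is not None and m.start <= current.end + gap_merge:
                current.end = max(current.end, m.end)
                entry = current.support.setdefault(m.gene, [0, 0])
                entry[0] += 1
                entry[1] += m.score
            else:
                current = CandidateRegion(
                    contig=contig,
                    start=m.start,
                    end=m.end,
                    strand=strand,
                    support={m.gene: [1, m.score]},
                )
                regions.append(current)
    regions.sort(key=lambda r: (r.contig, r.start, r.strand))
    return regions


def assign_gene(region: CandidateRegion) -> str:
    """Most prevalent gene in the region: highest mapping count, ties broken
    by larger summed score, then lexicographic gene name."""
    if not region.support:
        raise ValueError("region has no support")
    return min(
        region.support,
        key=lambda g: (-region.support[g][0], -region.support[g][1], g),
    )


def filter_regions(
    regions: list[CandidateRegion], min_support: int = 2, min_len: int = 500
) -> list[CandidateRegion]:
    """Drop weakly supported or short regions (spurious pseudogene fragments)."""
    return [
        r
        for r in regions
        if r.n_mappings >= min_support and (r.end - r.start) >= min_len
    ]
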