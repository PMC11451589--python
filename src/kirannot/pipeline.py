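"""End-to-end driver and report writers.

The pipeline is fully deterministic given its inputs and configuration:
locus discovery → gene assignment → wildtype boundary refinement → variant
calling → clipping repair → allele calling, then a TSV summary and an
in-depth YAML report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from .alignment import ScoringScheme
from .calling import annotate_copy
from .database import AlleleDatabase, load_database
from .mapping import assign_gene, consolidate, filter_regions, get_mapper
from .regions import GeneCopy, refine, refine_with_wildtype
from .variants import call_variants

log = logging.getLogger(__name__)

TSV_COLUMNS = [
    "contig",
    "gene",
    "allele_call",
    "start",
    "end",
    "strand",
    "core_score",
    "n_missing_core",
    "n_novel_core",
    "n_novel_silent",
]


@dataclass(frozen=True)
class PipelineConfig:
    mapper: str = "builtin"
    flank_bp: int = 1000
    min_region_support: int = 2
    min_region_len: int = 500
    kmer_size: int = 21
    gap_merge: int = 0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)


def read_assembly(path: str | Path) -> dict[str, str]:
    return {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }


def annotate_assembly(
    contigs: dict[str, str],
    db: AlleleDatabase,
    config: PipelineConfig | None = None,
) -> list[GeneCopy]:
    """Annotate every KIR gene copy found in ``contigs``."""
    config = config or PipelineConfig()
    mapper = get_mapper(config.mapper)
    if mapper.__name__ == "builtin_map":
        mappings = mapper(db, contigs, kmer_size=config.kmer_size)
    else:
        mappings = mapper(db, contigs)
    log.info("mapped %d allele hits", len(mappings))

    regions = filter_regions(
        consolidate(mappings, gap_merge=config.gap_merge),
        min_support=config.min_region_support,
        min_len=config.min_region_len,
    )
    log.info("consolidated into %d candidate regions", len(regions))

    copies: list[GeneCopy] = []
    for region in regions:
        gene = db.genes[assign_gene(region)]
        copy = refine_with_wildtype(
            region, gene, contigs, flank_bp=config.flank_bp, scoring=config.scoring
        )
        if copy is None:
            continue
        copy.variants, copy.alignment = call_variants(
            gene.wildtype_seq, copy.extracted_seq, gene, config.scoring
        )
        copy = refine(copy, gene, contigs, config.scoring)
        annotate_copy(copy, db)
        copies.append(copy)

    copies.sort(key=lambda c: (c.contig, c.refined_start, c.refined_end))
    if not copies:
        log.info("no gene copies found")
    return copies


def run_pipeline(
    assembly_path: str | Path,
    database_path: str | Path,
    out_prefix: str | Path,
    config: PipelineConfig | None = None,
    dialect: str = "fixture",
) -> list[GeneCopy]:
    """Annotate an assembly FASTA and write ``<prefix>.tsv`` / ``<prefix>.yaml``."""
    db = load_database(database_path, dialect=dialect)
    contigs = read_assembly(assembly_path)
    copies = annotate_assembly(contigs, db, config)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    write_tsv(copies, Path(f"{out_prefix}.tsv"))
    write_yaml(copies, Path(f"{out_prefix}.yaml"))
    return copies


# ---------------------------------------------------------------------------
# reports


def _call_score(copy: GeneCopy):
    for s in copy.score_table:
        if s.allele_name == copy.allele_call:
            return s
    raise ValueError("copy has no score for its own allele call")


def write_tsv(copies: list[GeneCopy], path: str | Path) -> None:
    """Gene-by-gene summary: one row per copy, coordinates 1-based inclusive
    on the forward strand, sorted by contig then start."""
    rows = []
    for copy in sorted(copies, key=lambda c: (c.contig, c.refined_start)):
        score = _call_score(copy)
        rows.append(
            [
                copy.contig,
                copy.gene,
                copy.allele_call,
                str(copy.refined_start + 1),
                str(copy.refined_end),
                copy.strand,
                f"{score.core_score:.6g}",
                str(len(score.missing_core)),
                str(len(score.novel_core)),
                str(copy.n_novel_silent),
            ]
        )
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_yaml(copies: list[GeneCopy], path: str | Path) -> None:
    """In-depth report: full variant list and the top-5 closest alleles."""
    entries = []
    for copy in sorted(copies, key=lambda c: (c.contig, c.refined_start)):
        entries.append(
            {
                "region": {
                    "contig": copy.contig,
                    "start": copy.refined_start + 1,
                    "end": copy.refined_end,
                    "strand": copy.strand,
                },
                "gene": copy.gene,
                "allele_call": copy.allele_call,
                "variants": [
                    {
                        "variant": v.render(),
                        "kind": v.kind,
                        "effect": v.effect,
                        "core": bool(v.core),
                        **({"low_confidence": True} if "N" in v.alt else {}),
                    }
                    for v in copy.variants
                ],
                "closest_alleles": [
                    {
                        "allele": s.allele_name,
                        "core_score": round(s.core_score, 6),
                        "silent_jaccard": round(s.silent_jaccard, 6),
                        "missing_core": list(s.missing_core),
                        "novel_core": list(s.novel_core),
                    }
                    for s in copy.score_table
                ],
                "cigar": copy.alignment.cigar() if copy.alignment else None,
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"gene_copies": entries}, fh, default_flow_style=False, sort_keys=False
        )
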