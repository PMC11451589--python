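import numpy as np
import pytest
from hypothesis import settings

from kirannot.database import GeneDefinition
from kirannot.synth import PlantSpec, make_synthetic_assembly, make_toy_database

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_fixture(tmp_path_factory):
    """Seeded 2-gene / 3-allele fixture database with one cDNA-only allele
    per gene; the generator certifies every planted variant's class."""
    out = tmp_path_factory.mktemp("toydb")
    return make_toy_database(out, seed=11, n_genes=2, alleles_per_gene=3, include_cdna=True)


@pytest.fixture(scope="session")
def toy_db(toy_fixture):
    return toy_fixture.db


@pytest.fixture(scope="session")
def planted(toy_db):
    """Assembly with six planted copies exercising the tricky cases:
    minus strand, head truncation, novel core variant, cDNA-form allele."""
    plants = [
        PlantSpec("KIRTOY1*001"),
        PlantSpec("KIRTOY1*002", strand="-"),
        PlantSpec("KIRTOY2*002"),
        PlantSpec("KIRTOY1*001", truncate_head=150),
        PlantSpec("KIRTOY2*001", novel_effects=("nonsense",)),
        PlantSpec("KIRTOY2*003"),
    ]
    contigs, truth = make_synthetic_assembly(toy_db, plants, seed=7)
    return contigs, truth


@pytest.fixture(scope="session")
def mini_gene():
    """Hand-built two-exon gene where every consequence class is reachable.

    Layout (0-based): 5'UTR [0,20) with a functional interval [2,6),
    exon1 [20,32) = ATG AAA CCC GGG, intron [32,52),
    exon2 [52,64) = TTT CTC GAT TAA, 3'UTR [64,84).
    """
    utr5 = "TTTTTCCCCCAAAAAGGGGG"
    exon1 = "ATGAAACCCGGG"
    intron = "GTAAGTCCCCCAAAGGGTAG"
    exon2 = "TTTCTCGATTAA"
    utr3 = "CCCCCGGGGGAAAAATTTTT"
    seq = utr5 + exon1 + intron + exon2 + utr3
    gene = GeneDefinition(
        name="KIRMINI",
        wildtype_allele="KIRMINI*001",
        wildtype_seq=seq,
        exons=[(20, 32), (52, 64)],
        functional_utr=[(2, 6)],
    )
    gene.validate()
    return gene


@pytest.fixture()
def rng():
    return np.random.default_rng(20240822)
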