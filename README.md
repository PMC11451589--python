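# kirannot

Functionally-aware annotation of KIR gene copies in phased genome assemblies.

The killer-cell immunoglobulin-like receptor (KIR) locus on chromosome 19 is
one of the most polymorphic and structurally variable regions of the human
genome: ~17 genes (two of them pseudogenes), extensive copy-number variation,
and haplotypes carrying anywhere from 8 to 14 gene copies. Annotating a
haplotype-resolved assembly therefore cannot rely on a fixed reference
structure. `kirannot` locates every KIR gene copy in an assembly, calls its
variants against the gene's designated wildtype allele, classifies each
variant as functionally relevant (**core**: missense, nonsense, frameshift,
start-loss, and expression-relevant UTR changes) or **silent** (synonymous,
intronic, other UTR), and assigns the closest database allele by a
core-variant-first distance — so that the reported allele reflects the
biology of the encoded protein rather than raw sequence similarity.

## The scoring scheme

For each gene, the *core-position index* `P` is the union of wildtype
positions touched by any database allele's core variants (each base of a
deletion counts independently; an insertion counts through its anchor
position). A candidate allele *a* is scored against an assembly gene copy
*c* as

```
score(a, c) = h(a, c) / |P|  +  n(c)
```

where `h` is the Hamming distance between the nucleotide states implied by
the two variant sets over the positions of `P`, and `n` is the number of
*novel* core variants — core variants of the copy whose footprint lies
entirely outside `P`. Ties are broken by the Jaccard distance between the
silent-variant sets, then by the numeric allele suffix. An allele whose core
variants fully agree with the copy's scores exactly `0.0`, no matter how
many silent or intronic differences separate the two sequences.

## Pipeline

1. **Locus discovery** — the full allele set is mapped onto the assembly
   (builtin deterministic k-mer seed-and-extend mapper, or minimap2 when
   requested); overlapping same-strand mappings are consolidated into
   candidate regions, keeping clipped mappings as evidence of structural
   variation.
2. **Gene identification** — each region is assigned the most prevalent
   gene among its mappings; the gene's wildtype is aligned back against the
   flanked region to set precise bounds.
3. **Variant calling** — semi-global alignment (free end gaps on the
   assembly extraction only; affine gaps) of the wildtype against the
   extracted copy; variants are left-aligned and classified by
   mutate–splice–translate against the gene's exon table.
4. **Clipping repair** — prefix/suffix deletions trigger a re-extraction
   with outward-shifted bounds; the less complex variant set wins.
5. **Allele calling** — every database allele of the gene is scored as
   above; the call plus the top five closest alleles are reported.

Databases are accepted either in the repository's fixture dialect (FASTA of
alleles plus a `*.genes.tsv` sidecar with exon/UTR annotations) or as an
EMBL/IMGT-style flat-file release. Alleles known only in cDNA form are given
a genomic sequence by splicing their exons onto the nearest genomic
backbone.

## Worked example

`kirannot` ships a deterministic generator of toy KIR-like databases and
synthetic assemblies with known truth, so the full pipeline can be exercised
without downloading anything:

```python
import pathlib
from kirannot.synth import make_toy_database, make_synthetic_assembly, PlantSpec

fx = make_toy_database(pathlib.Path("db"), seed=1, n_genes=2, alleles_per_gene=3)
contigs, truth = make_synthetic_assembly(
    fx.db,
    [PlantSpec("KIRTOY1*002"),
     PlantSpec("KIRTOY2*003", strand="-"),
     PlantSpec("KIRTOY2*001", novel_effects=("missense",))],
    seed=3, out_dir="asm")
```

```console
$ kirannot annotate asm/assembly.fa --db db/toy_db.fa --out out/run
INFO kirannot.pipeline: mapped 9 allele hits
INFO kirannot.pipeline: consolidated into 3 candidate regions
annotated 3 gene copies; reports at out/run.tsv / out/run.yaml

$ cat out/run.tsv
contig	gene	allele_call	start	end	strand	core_score	n_missing_core	n_novel_core	n_novel_silent
contig_1	KIRTOY1	KIRTOY1*002	2001	4107	+	0	0	0	0
contig_1	KIRTOY2	KIRTOY2*003	6108	8124	-	0	0	0	0
contig_1	KIRTOY2	KIRTOY2*001	10125	12141	+	1	0	1	0
```

All three planted copies are recovered at their exact 1-based coordinates.
The first two calls score `0.0`: their core variants agree perfectly with
the planted alleles. The third copy carries a planted *novel* missense
variant absent from every database allele, so its best score is `1.0`
(`0/|P|` agreement at known core positions plus one novel core variant) and
the summary reports `n_novel_core = 1`. The companion `out/run.yaml` lists,
per copy, every called variant with its consequence (e.g. `1670 G>T`,
missense, core) and the score breakdown for the five closest alleles.

## Scope

`kirannot` annotates assemblies against a known allele database. It does not
phase haplotypes, assess assembly quality, model splice-site disruption, or
evaluate compound effects of co-occurring frameshifts (each variant is
classified independently). See `docs/methods.md` for the model, parameter
defaults, and known limitations.
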