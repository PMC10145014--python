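"""Gene models, functional-region derivation and HF classification.

The host annotation is read from GFF3 into per-gene models (first mRNA per
gene; transcript isoforms are not resolved). From the gene models the
pipeline derives seven region categories — gene, exon, CDS, intron,
promoter, downstream, intergenic — as per-scaffold interval sets. The
categories are deliberately NOT mutually exclusive: a fragment can lie in
the CDS of one gene and the promoter of its neighbour at the same time, so
classification is multi-label and each category is counted independently.

Promoter and downstream extents are configurable flanks (defaults 2,000 bp
upstream and 1,000 bp downstream of the gene, strand-aware, clipped to the
scaffold); every report written by the pipeline echoes the values used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval, ScaffoldLengths, merge_overlapping

logger = logging.getLogger(__name__)

CATEGORIES = ("gene", "exon", "CDS", "intron", "promoter", "downstream", "intergenic")
DEFAULT_PROMOTER_LEN = 2000
DEFAULT_DOWNSTREAM_LEN = 1000


@dataclass
class GeneModel:
    """One protein-coding gene: span, exons and CDS in 0-based half-open coords."""

    gene_id: str
    gene_name: str
    scaffold: str
    strand: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def introns(self) -> list[tuple[int, int]]:
        """Span minus exon union, as (start, end) pairs."""
        ex = merge_overlapping([(e.start, e.end) for e in self.exons])
        out: list[tuple[int, int]] = []
        cursor = self.span.start
        for s, e in ex:
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < self.span.end:
            out.append((cursor, self.span.end))
        return out


class GFF3ParseError(ValueError):
    pass


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModels.

    GFF3 1-based inclusive coordinates become 0-based half-open. A gene
    without exon children gets its span as a single exon. Features whose
    Parent cannot be resolved are skipped with a warning; a feature whose
    end precedes its start is a parse error.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GFF3ParseError(f"cannot parse GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.end < gene.start:
            raise GFF3ParseError(f"gene {gene.id}: end < start")
        span = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        name = gene.attributes.get("Name", [gene.id])[0]
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        exon_parent = mrnas[0] if mrnas else gene
        exons = []
        cds = []
        for feat in db.children(exon_parent, featuretype="exon", order_by="start"):
            if feat.end < feat.start:
                raise GFF3ParseError(f"exon under {gene.id}: end < start")
            exons.append(GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand))
        for feat in db.children(exon_parent, featuretype="CDS", order_by="start"):
            if feat.end < feat.start:
                raise GFF3ParseError(f"CDS under {gene.id}: end < start")
            cds.append(GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand))
        if not exons:
            exons = [span]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                gene_name=name,
                scaffold=gene.seqid,
                strand=gene.strand,
                span=span,
                exons=exons,
                cds=cds,
            )
        )

    # orphan mRNA/exon/CDS features (unresolvable Parent) are reported, not fatal
    known_parents = {g.gene_id for g in genes}
    for ft in ("mRNA",):
        for feat in db.features_of_type(ft):
            parents = feat.attributes.get("Parent", [])
            if parents and parents[0] not in known_parents:
                warnings.warn(
                    f"skipping {ft} {feat.id}: unresolved Parent {parents[0]}",
                    stacklevel=2,
                )
    return genes


@dataclass
class RegionIndex:
    """Per-scaffold, per-category interval sets plus base-count totals."""

    trees: dict[str, dict[str, IntervalTree]]
    category_base_counts: dict[str, int]
    genome_length: int
    scaffold_lengths: ScaffoldLengths
    genes: list[GeneModel]
    footprints: dict[str, IntervalTree]  # promoter+span+downstream, payload gene_id
    promoter_len: int
    downstream_len: int

    def categories(self) -> tuple[str, ...]:
        return CATEGORIES


def _flank(gene: GeneModel, promoter_len: int, downstream_len: int, scaffold_len: int):
    """Strand-aware promoter/downstream (start, end) pairs, clipped; may be empty."""
    if gene.strand == "-":
        prom = (gene.span.end, min(scaffold_len, gene.span.end + promoter_len))
        down = (max(0, gene.span.start - downstream_len), gene.span.start)
    else:
        prom = (max(0, gene.span.start - promoter_len), gene.span.start)
        down = (gene.span.end, min(scaffold_len, gene.span.end + downstream_len))
    return (prom if prom[0] < prom[1] else None, down if down[0] < down[1] else None)


def derive_regions(
    genes: Sequence[GeneModel],
    scaffold_lengths: ScaffoldLengths,
    promoter_len: int = DEFAULT_PROMOTER_LEN,
    downstream_len: int = DEFAULT_DOWNSTREAM_LEN,
) -> RegionIndex:
    """Build the category interval index and per-category base totals.

    Base counts are computed on the per-category unions, so overlapping
    genes are not double-counted within a category. Intergenic is the
    complement of the union of gene spans; every base of every scaffold
    therefore belongs to at least one category.
    """
    if promoter_len < 0 or downstream_len < 0:
        raise ValueError("flank lengths must be >= 0")
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {
        sc: {cat: [] for cat in CATEGORIES} for sc in scaffold_lengths
    }
    for gene in genes:
        if gene.scaffold not in scaffold_lengths:
            raise ValueError(f"gene {gene.gene_id} on unknown scaffold {gene.scaffold}")
        sc = raw[gene.scaffold]
        sc["gene"].append((gene.span.start, gene.span.end))
        sc["exon"].extend((e.start, e.end) for e in gene.exons)
        sc["CDS"].extend((c.start, c.end) for c in gene.cds)
        sc["intron"].extend(gene.introns())
        prom, down = _flank(
            gene, promoter_len, downstream_len, scaffold_lengths[gene.scaffold]
        )
        if prom:
            sc["promoter"].append(prom)
        if down:
            sc["downstream"].append(down)

    trees: dict[str, dict[str, IntervalTree]] = {}
    base_counts = {cat: 0 for cat in CATEGORIES}
    footprints: dict[str, IntervalTree] = {}
    for scaffold, cats in raw.items():
        slen = scaffold_lengths[scaffold]
        # intergenic = complement of gene-span union
        gene_union = merge_overlapping(cats["gene"])
        inter: list[tuple[int, int]] = []
        cursor = 0
        for s, e in gene_union:
            if s > cursor:
                inter.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < slen:
            inter.append((cursor, slen))
        cats["intergenic"] = inter
        trees[scaffold] = {}
        for cat in CATEGORIES:
            merged = merge_overlapping(cats[cat])
            trees[scaffold][cat] = IntervalTree.from_tuples(merged) if merged else IntervalTree()
            base_counts[cat] += sum(e - s for s, e in merged)
        footprints[scaffold] = IntervalTree()

    for gene in genes:
        prom, down = _flank(
            gene, promoter_len, downstream_len, scaffold_lengths[gene.scaffold]
        )
        lo = min(x[0] for x in (prom, (gene.span.start, gene.span.end), down) if x)
        hi = max(x[1] for x in (prom, (gene.span.start, gene.span.end), down) if x)
        footprints[gene.scaffold][lo:hi] = gene.gene_id

    return RegionIndex(
        trees=trees,
        category_base_counts=base_counts,
        genome_length=scaffold_lengths.genome_length,
        scaffold_lengths=scaffold_lengths,
        genes=list(genes),
        footprints=footprints,
        promoter_len=promoter_len,
        downstream_len=downstream_len,
    )


OverlapCriterion = Literal["any", "half"]


def classify_hf(
    hf_interval: GenomicInterval,
    index: RegionIndex,
    criterion: OverlapCriterion = "any",
) -> set[str]:
    """Region categories overlapped by an HF.

    ``any``: membership requires >= 1 overlapping base (the default);
    ``half``: requires the overlap to cover >= 50% of the HF's length.
    Always non-empty, because intergenic complements the gene spans.
    """
    if hf_interval.seq_id not in index.trees:
        raise ValueError(f"unknown scaffold {hf_interval.seq_id}")
    need = 1 if criterion == "any" else (hf_interval.length() + 1) // 2
    cats: set[str] = set()
    for cat, tree in index.trees[hf_interval.seq_id].items():
        ov = 0
        for hit in tree.overlap(hf_interval.start, hf_interval.end):
            ov += min(hit.end, hf_interval.end) - max(hit.begin, hf_interval.start)
            if ov >= need:
                cats.add(cat)
                break
    return cats


def assign_genes(hf_interval: GenomicInterval, index: RegionIndex) -> list[str]:
    """Gene ids whose extended footprint (promoter+span+downstream) overlaps the HF.

    Ties to multiple genes are all kept, sorted for determinism.
    """
    if hf_interval.seq_id not in index.footprints:
        raise ValueError(f"unknown scaffold {hf_interval.seq_id}")
    hits = index.footprints[hf_interval.seq_id].overlap(
        hf_interval.start, hf_interval.end
    )
    return sorted({h.data for h in hits})


def write_classification(
    hfs, index: RegionIndex, path, criterion: OverlapCriterion = "any",
    header: str | None = None,
) -> None:
    """Per-HF classification TSV: HF id, categories, assigned genes."""
    name_of = {g.gene_id: g.gene_name for g in index.genes}
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("hf_id\tscaffold\tstart\tend\tcategories\tgene_ids\tgene_names\n")
        for hf in hfs:
            cats = ",".join(sorted(classify_hf(hf.interval, index, criterion)))
            gids = assign_genes(hf.interval, index)
            fh.write(
                f"{hf.hf_id}\t{hf.interval.seq_id}\t{hf.interval.start}\t"
                f"{hf.interval.end}\t{cats}\t{','.join(gids)}\t"
                f"{','.join(name_of.get(g, g) for g in gids)}\n"
            )
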