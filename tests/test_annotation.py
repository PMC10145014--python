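"""GFF3 parsing, region derivation and HF classification vs per-base oracles."""

import numpy as np
import pytest

from hfscan.annotation import (
    CATEGORIES,
    GFF3ParseError,
    classify_hf,
    derive_regions,
    read_gff3,
)
from hfscan.intervals import GenomicInterval, ScaffoldLengths
from hfscan.synthetic_data import (
    generate_gene_annotation,
    generate_host_genome,
    scaffold_lengths_of,
    write_gff3,
)

MINIMAL_GFF = """##gff-version 3
sc1\tsrc\tgene\t1001\t3000\t.\t+\t.\tID=g1;Name=toy gene
sc1\tsrc\tmRNA\t1001\t3000\t.\t+\t.\tID=g1.t1;Parent=g1
sc1\tsrc\texon\t1001\t1500\t.\t+\t.\tID=g1.t1.e1;Parent=g1.t1
sc1\tsrc\texon\t2001\t3000\t.\t+\t.\tID=g1.t1.e2;Parent=g1.t1
sc1\tsrc\tCDS\t1101\t1500\t.\t+\t0\tID=g1.t1.c1;Parent=g1.t1
sc1\tsrc\tCDS\t2001\t2900\t.\t+\t0\tID=g1.t1.c2;Parent=g1.t1
"""


@pytest.fixture
def toy_gene(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(MINIMAL_GFF)
    return read_gff3(p)


def test_minimal_gene_parses_with_single_intron(toy_gene):
    (g,) = toy_gene
    assert g.gene_id == "g1" and g.gene_name == "toy gene"
    assert (g.span.start, g.span.end) == (1000, 3000)
    assert [(e.start, e.end) for e in g.exons] == [(1000, 1500), (2000, 3000)]
    assert [(c.start, c.end) for c in g.cds] == [(1100, 1500), (2000, 2900)]
    assert g.introns() == [(1500, 2000)]


def test_end_before_start_is_parse_error(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("##gff-version 3\nsc1\tsrc\tgene\t500\t100\t.\t+\t.\tID=g1\n")
    with pytest.raises((GFF3ParseError, ValueError)):
        read_gff3(p)


def test_minus_strand_promoter_is_upstream_of_high_coordinate(toy_gene, tmp_path):
    p = tmp_path / "minus.gff3"
    p.write_text(MINIMAL_GFF.replace("\t+\t", "\t-\t"))
    (g,) = read_gff3(p)
    lengths = ScaffoldLengths({"sc1": 10_000})
    index = derive_regions([g], lengths, promoter_len=500, downstream_len=200)
    tree = index.trees["sc1"]["promoter"]
    assert sorted((h.begin, h.end) for h in tree) == [(3000, 3500)]
    assert sorted((h.begin, h.end) for h in index.trees["sc1"]["downstream"]) == [
        (800, 1000)
    ]


def test_plus_strand_promoter_arithmetic(toy_gene):
    lengths = ScaffoldLengths({"sc1": 10_000})
    index = derive_regions(toy_gene, lengths, promoter_len=500, downstream_len=200)
    assert sorted((h.begin, h.end) for h in index.trees["sc1"]["promoter"]) == [
        (500, 1000)
    ]


def test_promoter_clipped_at_scaffold_start(tmp_path):
    p = tmp_path / "edge.gff3"
    p.write_text(
        "##gff-version 3\nsc1\tsrc\tgene\t1\t400\t.\t+\t.\tID=g1;Name=edge\n"
    )
    genes = read_gff3(p)
    index = derive_regions(genes, ScaffoldLengths({"sc1": 1000}), 2000, 1000)
    assert len(index.trees["sc1"]["promoter"]) == 0  # clipped to empty
    # gene without exon children gets its span as a single exon
    assert [(e.start, e.end) for e in genes[0].exons] == [(0, 400)]


def test_unknown_scaffold_rejected(toy_gene):
    with pytest.raises(ValueError, match="unknown scaffold"):
        derive_regions(toy_gene, ScaffoldLengths({"other": 1000}))


def per_base_category_arrays(genes, lengths, promoter_len, downstream_len):
    """Independent oracle: boolean membership array per category per scaffold."""
    arrays = {
        sc: {cat: np.zeros(lengths[sc], dtype=bool) for cat in CATEGORIES}
        for sc in lengths
    }
    for g in genes:
        a = arrays[g.scaffold]
        a["gene"][g.span.start : g.span.end] = True
        for e in g.exons:
            a["exon"][e.start : e.end] = True
        for c in g.cds:
            a["CDS"][c.start : c.end] = True
        ex = np.zeros(lengths[g.scaffold], dtype=bool)
        for e in g.exons:
            ex[e.start : e.end] = True
        span = np.zeros_like(ex)
        span[g.span.start : g.span.end] = True
        a["intron"] |= span & ~ex
        if g.strand == "-":
            a["promoter"][g.span.end : g.span.end + promoter_len] = True
            a["downstream"][max(0, g.span.start - downstream_len) : g.span.start] = True
        else:
            a["promoter"][max(0, g.span.start - promoter_len) : g.span.start] = True
            a["downstream"][g.span.end : g.span.end + downstream_len] = True
    for sc in lengths:
        gene_any = np.zeros(lengths[sc], dtype=bool)
        for g in genes:
            if g.scaffold == sc:
                gene_any[g.span.start : g.span.end] = True
        arrays[sc]["intergenic"] = ~gene_any
    return arrays


@pytest.mark.parametrize("seed", range(3))
def test_region_base_counts_match_per_base_oracle(seed):
    genome = generate_host_genome(2, [30_000, 20_000], seed=seed)
    genes = generate_gene_annotation(genome, n_genes=12, gene_length_range=(800, 2500), seed=seed)
    lengths = scaffold_lengths_of(genome)
    index = derive_regions(genes, lengths, promoter_len=800, downstream_len=300)
    arrays = per_base_category_arrays(genes, lengths, 800, 300)
    for cat in CATEGORIES:
        oracle = sum(int(arrays[sc][cat].sum()) for sc in lengths)
        assert index.category_base_counts[cat] == oracle
    # every base belongs to at least one category
    for sc in lengths:
        union = np.zeros(lengths[sc], dtype=bool)
        for cat in CATEGORIES:
            union |= arrays[sc][cat]
        assert union.all()


@pytest.mark.parametrize("seed", range(3))
def test_classification_matches_per_base_oracle(seed):
    rng = np.random.default_rng(seed + 100)
    genome = generate_host_genome(2, [30_000, 20_000], seed=seed)
    genes = generate_gene_annotation(genome, n_genes=12, gene_length_range=(800, 2500), seed=seed)
    lengths = scaffold_lengths_of(genome)
    index = derive_regions(genes, lengths, promoter_len=800, downstream_len=300)
    arrays = per_base_category_arrays(genes, lengths, 800, 300)
    for _ in range(50):
        sc = list(lengths)[rng.integers(0, 2)]
        length = int(rng.integers(33, 278))
        s = int(rng.integers(0, lengths[sc] - length))
        hf = GenomicInterval(sc, s, s + length)
        expected = {
            cat for cat in CATEGORIES if arrays[sc][cat][s : s + length].any()
        }
        got = classify_hf(hf, index)
        assert got == expected
        assert got  # never empty


def test_classification_in_and_around_the_toy_gene(toy_gene):
    lengths = ScaffoldLengths({"sc1": 10_000})
    index = derive_regions(toy_gene, lengths, promoter_len=500, downstream_len=200)
    inside_cds = classify_hf(GenomicInterval("sc1", 1150, 1250), index)
    assert inside_cds == {"gene", "exon", "CDS"}
    junction = classify_hf(GenomicInterval("sc1", 1450, 1600), index)
    assert junction == {"gene", "exon", "CDS", "intron"}
    desert = classify_hf(GenomicInterval("sc1", 8000, 8100), index)
    assert desert == {"intergenic"}
    with pytest.raises(ValueError, match="unknown scaffold"):
        classify_hf(GenomicInterval("nope", 0, 10), index)


def test_half_overlap_criterion_is_stricter(toy_gene):
    lengths = ScaffoldLengths({"sc1": 10_000})
    index = derive_regions(toy_gene, lengths, 500, 200)
    # 10 of 100 bases in the gene: member under 'any', not under 'half'
    hf = GenomicInterval("sc1", 910, 1010)
    assert "gene" in classify_hf(hf, index, "any")
    assert "gene" not in classify_hf(hf, index, "half")


def test_cds_within_exon_within_gene_base_counts():
    genome = generate_host_genome(1, [50_000], seed=5)
    genes = generate_gene_annotation(genome, n_genes=8, gene_length_range=(1000, 3000), seed=5)
    index = derive_regions(genes, scaffold_lengths_of(genome))
    c = index.category_base_counts
    assert c["CDS"] <= c["exon"] <= c["gene"]


def test_gff3_roundtrip_through_writer(tmp_path):
    genome = generate_host_genome(2, [30_000, 20_000], seed=6)
    genes = generate_gene_annotation(genome, n_genes=10, gene_length_range=(800, 2500), seed=6)
    p = tmp_path / "rt.gff3"
    write_gff3(genes, p)
    back = read_gff3(p)
    assert len(back) == len(genes)
    for a, b in zip(sorted(genes, key=lambda g: g.gene_id),
                    sorted(back, key=lambda g: g.gene_id)):
        assert (a.scaffold, a.strand, a.span.start, a.span.end) == (
            b.scaffold, b.strand, b.span.start, b.span.end
        )
        assert [(e.start, e.end) for e in a.exons] == [(e.start, e.end) for e in b.exons]
        assert [(c.start, c.end) for c in a.cds] == [(c.start, c.end) for c in b.cds]
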