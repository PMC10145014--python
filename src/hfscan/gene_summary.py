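"""Gene-level summaries of host HFs: hot spots, coverage ratios, matrices.

An HF is assigned to every gene whose extended footprint (promoter + span +
downstream) it overlaps, so a fragment straddling two neighbouring genes is
counted for both. Length ratios use the gene span (introns included) as the
denominator and the union of span-clipped HF bases as the numerator, so
overlapping HFs are never double-counted and the ratio stays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .annotation import GeneModel, RegionIndex, assign_genes
from .hf_host import HostHF
from .hf_virus import VirusHF
from .intervals import GenomicInterval, total_covered


@dataclass
class GeneHFSummary:
    gene_id: str
    gene_name: str
    scaffold: str
    n_hfs: int
    virus_ids: frozenset[str]
    hf_ids: list[str]
    covered_fraction: float
    virus_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_virus_species(self) -> int:
        return len(self.virus_ids)


def hf_length_ratio(gene: GeneModel, hfs: Sequence[HostHF]) -> float:
    """Union of HF bases clipped to the gene span, over the span length."""
    span = gene.span
    clipped = []
    for hf in hfs:
        if hf.interval.seq_id != span.seq_id:
            continue
        s = max(hf.interval.start, span.start)
        e = min(hf.interval.end, span.end)
        if s < e:
            clipped.append((s, e))
    return total_covered(clipped) / span.length()


def virus_gene_ratio(virus_gene: GenomicInterval, virus_hfs: Sequence[VirusHF]) -> float:
    """Mirror of hf_length_ratio on viral coordinates."""
    clipped = []
    for hf in virus_hfs:
        if hf.interval.seq_id != virus_gene.seq_id:
            continue
        s = max(hf.interval.start, virus_gene.start)
        e = min(hf.interval.end, virus_gene.end)
        if s < e:
            clipped.append((s, e))
    return total_covered(clipped) / virus_gene.length()


def summarize_genes(
    hfs: Sequence[HostHF], genes: Sequence[GeneModel], index: RegionIndex
) -> list[GeneHFSummary]:
    """One summary per gene with at least one assigned HF.

    An HF overlapping k gene footprints contributes to all k summaries.
    Virus counts per gene count HFs supported by each viral accession
    (an HF with several supporting viruses increments each).
    """
    by_gene: dict[str, list[HostHF]] = {}
    for hf in hfs:
        for gid in assign_genes(hf.interval, index):
            by_gene.setdefault(gid, []).append(hf)
    gene_of = {g.gene_id: g for g in genes}
    out: list[GeneHFSummary] = []
    for gid in sorted(by_gene):
        gene = gene_of[gid]
        assigned = by_gene[gid]
        virus_counts: dict[str, int] = {}
        viruses: set[str] = set()
        for hf in assigned:
            for v in hf.virus_ids:
                virus_counts[v] = virus_counts.get(v, 0) + 1
                viruses.add(v)
        out.append(
            GeneHFSummary(
                gene_id=gid,
                gene_name=gene.gene_name,
                scaffold=gene.scaffold,
                n_hfs=len(assigned),
                virus_ids=frozenset(viruses),
                hf_ids=[hf.hf_id for hf in assigned],
                covered_fraction=hf_length_ratio(gene, assigned),
                virus_counts=virus_counts,
            )
        )
    return out


def hotspot_ranking(summaries: Sequence[GeneHFSummary], n: int) -> list[GeneHFSummary]:
    """Top-n genes by HF count; ties by covered fraction, then gene id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        summaries, key=lambda s: (-s.n_hfs, -s.covered_fraction, s.gene_id)
    )
    return ranked[:n]


def gene_virus_matrix(summaries: Sequence[GeneHFSummary]) -> pd.DataFrame:
    """Gene-by-virus HF-count matrix; presence is count > 0.

    Row sums equal per-gene (gene, virus)-incidence totals; column sums are
    the per-virus totals over these genes.
    """
    if not summaries:
        return pd.DataFrame()
    viruses = sorted({v for s in summaries for v in s.virus_counts})
    data = {
        s.gene_id: [s.virus_counts.get(v, 0) for v in viruses] for s in summaries
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=viruses).sort_index()


def top_confidence_hfs(hfs: Sequence[HostHF], n: int) -> list[HostHF]:
    """Highest-confidence HFs: longest first, then best bit score, then position."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        hfs,
        key=lambda h: (
            -h.length,
            -h.best_bit_score,
            h.interval.seq_id,
            h.interval.start,
        ),
    )
    return ranked[:n]


def write_gene_summaries(
    summaries: Sequence[GeneHFSummary], path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            "gene_id\tgene_name\tscaffold\tn_hfs\tn_virus_species\t"
            "covered_fraction\tvirus_ids\thf_ids\n"
        )
        for s in summaries:
            fh.write(
                f"{s.gene_id}\t{s.gene_name}\t{s.scaffold}\t{s.n_hfs}\t"
                f"{s.n_virus_species}\t{s.covered_fraction:.4f}\t"
                f"{','.join(sorted(s.virus_ids))}\t{','.join(s.hf_ids)}\n"
            )


def write_matrix(matrix: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", index_label="gene_id")


def write_top_confidence(
    hfs: Sequence[HostHF], index: RegionIndex, path, n: int = 5,
    header: str | None = None,
) -> None:
    """Top-confidence table: scaffold, HF length, host gene(s), virus accession(s)."""
    name_of = {g.gene_id: g.gene_name for g in index.genes}
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("hf_id\tscaffold\tstart\tend\tlength\tbit_score\thost_genes\tviruses\n")
        for hf in top_confidence_hfs(hfs, n):
            gids = assign_genes(hf.interval, index)
            fh.write(
                f"{hf.hf_id}\t{hf.interval.seq_id}\t{hf.interval.start}\t"
                f"{hf.interval.end}\t{hf.length}\t{hf.best_bit_score:g}\t"
                f"{','.join(name_of.get(g, g) for g in gids)}\t"
                f"{','.join(sorted(hf.virus_ids))}\n"
            )
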