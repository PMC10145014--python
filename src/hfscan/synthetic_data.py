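"""Synthetic genomes, annotations and alignment tables with ground truth.

The generator builds every input the pipeline consumes — a multi-scaffold
host genome, a GFF3 gene annotation, a set of viral genomes, and a
BLAST-style tabular alignment file — around a list of *planted* viral
homologous fragments whose host and virus coordinates are known exactly.

Three placement models control the statistical structure of the planted
fragments:

* ``uniform``   — per-base uniform positions across the genome;
* ``gene_biased`` — a configurable fraction (default 0.8) of fragments land
  inside gene spans;
* ``clustered``  — fragments are placed in pairs separated by a gap drawn
  from a configurable range (default 100–900 bp), so nearby-neighbour bins
  are enriched.

Mutation is substitution-only (no indels), which keeps coordinate ground
truth exact. Simulated E-values come from a declared monotone map from
(length, identity) to E — a bit-score-like s = 2*matches - 3*mismatches
with E = K*m*n*2^(-s) — chosen only so that planted fragments fall below
and decoys above the detection cutoff controllably; they are labelled
synthetic in every emitted file header and are not Karlin–Altschul
calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .alignment_io import AlignmentRecord, write_blast_tab
from .annotation import GeneModel
from .intervals import GenomicInterval, ScaffoldLengths

PlacementModel = Literal["uniform", "gene_biased", "clustered"]

BASES = np.array(list("ACGT"))
DEFAULT_FRAGMENT_LENGTH_RANGE = (33, 277)
DEFAULT_SUBSTITUTION_RATE = 0.05
DEFAULT_GENE_FRACTION = 0.8
DEFAULT_CLUSTER_GAP_RANGE = (100, 900)
DEFAULT_EVALUE_K = 0.1
DEFAULT_CUTOFF = 1e-5

# desk-scale preset: full pipeline in seconds
PRESET_N_SCAFFOLDS = 5
PRESET_SCAFFOLD_LENGTH = 200_000
PRESET_N_GENES = 60
PRESET_N_VIRUSES = 8
PRESET_VIRUS_LENGTH = 50_000
PRESET_N_INSERTIONS = 40


@dataclass
class PlantedHF:
    """Ground truth for one planted fragment."""

    host_location: GenomicInterval
    virus_id: str
    virus_location: GenomicInterval
    identity: float
    planted_category: str
    detectable: bool
    placement_model: str
    evalue: float
    n_substitutions: int


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def generate_host_genome(
    n_scaffolds: int = PRESET_N_SCAFFOLDS,
    lengths: Sequence[int] | None = None,
    mean_length: int = PRESET_SCAFFOLD_LENGTH,
    seed: int = 0,
) -> dict[str, str]:
    """I.i.d. uniform-base scaffolds, deterministic under the seed.

    Explicit ``lengths`` override the default of equal ``mean_length``
    scaffolds.
    """
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = [mean_length] * n_scaffolds
    if len(lengths) != n_scaffolds:
        raise ValueError("lengths must match n_scaffolds")
    return {
        f"scaffold_{i + 1}": _random_seq(int(L), rng)
        for i, L in enumerate(lengths)
    }


def generate_viral_genomes(
    n_viruses: int = PRESET_N_VIRUSES,
    length_range: tuple[int, int] = (30_000, PRESET_VIRUS_LENGTH),
    seed: int = 0,
) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    return {
        f"virus_{i + 1}": _random_seq(int(rng.integers(lo, hi + 1)), rng)
        for i in range(n_viruses)
    }


def scaffold_lengths_of(genome: dict[str, str]) -> ScaffoldLengths:
    return ScaffoldLengths({k: len(v) for k, v in genome.items()})


def generate_gene_annotation(
    genome: dict[str, str],
    n_genes: int = PRESET_N_GENES,
    gene_length_range: tuple[int, int] = (2_000, 8_000),
    exons_per_gene_range: tuple[int, int] = (2, 5),
    seed: int = 0,
    max_retries: int = 10_000,
) -> list[GeneModel]:
    """Non-overlapping genes on random strands with exon/CDS structure.

    Each gene's length is partitioned into alternating exon/intron pieces;
    CDS equals the exon chain with short UTR trims at the two ends. Raises
    when the requested genes cannot be packed into the genome.
    """
    rng = np.random.default_rng(seed)
    lengths = scaffold_lengths_of(genome)
    scaffolds = sorted(lengths)
    slens = np.array([lengths[s] for s in scaffolds], dtype=float)
    probs = slens / slens.sum()
    occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}

    genes: list[GeneModel] = []
    for gi in range(n_genes):
        placed = False
        for _ in range(max_retries):
            glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            ci = rng.choice(len(scaffolds), p=probs)
            sc = scaffolds[ci]
            cap = lengths[sc] - glen
            if cap <= 0:
                continue
            start = int(rng.integers(0, cap + 1))
            end = start + glen
            if any(s < end and start < e for s, e in occupied[sc]):
                continue
            occupied[sc].append((start, end))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"cannot place gene {gi + 1}/{n_genes}: genome too crowded"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
        n_pieces = 2 * n_exons - 1
        weights = rng.random(n_pieces) + 0.2
        piece_lens = np.maximum(1, (weights / weights.sum() * glen).astype(int))
        piece_lens[-1] += glen - piece_lens.sum()
        exons: list[GenomicInterval] = []
        pos = start
        for pi, plen in enumerate(piece_lens):
            if pi % 2 == 0:
                exons.append(GenomicInterval(sc, pos, pos + int(plen), strand))
            pos += int(plen)
        # CDS = exons with UTR trims confined to the terminal exons
        utr5 = int(rng.integers(0, min(30, exons[0].length() - 1) + 1))
        utr3 = int(rng.integers(0, min(30, exons[-1].length() - 1) + 1))
        cds: list[GenomicInterval] = []
        for ei, ex in enumerate(exons):
            s, e = ex.start, ex.end
            if ei == 0:
                s += utr5
            if ei == len(exons) - 1:
                e -= utr3
            if s < e:
                cds.append(GenomicInterval(sc, s, e, strand))
        gene_id = f"gene_{gi + 1:04d}"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=f"synthetic gene {gi + 1}",
                scaffold=sc,
                strand=strand,
                span=GenomicInterval(sc, start, end, strand),
                exons=exons,
                cds=cds,
            )
        )
    genes.sort(key=lambda g: (g.scaffold, g.span.start))
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Emit the gene models as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = g.span.start + 1, g.span.end
            fh.write(
                f"{g.scaffold}\tsynthetic\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_name}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.scaffold}\tsynthetic\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tsynthetic\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, c in enumerate(g.cds, 1):
                fh.write(
                    f"{g.scaffold}\tsynthetic\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{g.strand}\t0\tID={mrna}.cds{i};Parent={mrna}\n"
                )


def simulated_evalue(
    length: int,
    identity: float,
    m: float,
    n: float,
    k: float = DEFAULT_EVALUE_K,
) -> float:
    """Monotone synthetic E-value: E = K*m*n*2^(-s), s = 2*matches - 3*mismatches."""
    matches = round(length * identity / 100.0)
    mismatches = length - matches
    s = 2 * matches - 3 * mismatches
    log2_e = math.log2(k) + math.log2(m) + math.log2(n) - s
    if log2_e < -1000:
        return 0.0
    return 2.0 ** log2_e


def _mutate(fragment: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Apply point substitutions at the given per-base rate; no indels."""
    n_sub = int(rng.binomial(len(fragment), rate))
    if n_sub == 0:
        return fragment, 0
    pos = rng.choice(len(fragment), size=n_sub, replace=False)
    seq = list(fragment)
    for p in pos:
        alternatives = [b for b in "ACGT" if b != seq[p]]
        seq[p] = alternatives[rng.integers(0, 3)]
    return "".join(seq), n_sub


def _overlaps_any(start: int, end: int, occupied: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in occupied)


def plant_homologies(
    host: dict[str, str],
    viruses: dict[str, str],
    genes: Sequence[GeneModel],
    n_insertions: int = PRESET_N_INSERTIONS,
    placement_model: PlacementModel = "uniform",
    fragment_length_range: tuple[int, int] = DEFAULT_FRAGMENT_LENGTH_RANGE,
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE,
    seed: int = 0,
    gene_fraction: float = DEFAULT_GENE_FRACTION,
    cluster_gap_range: tuple[int, int] = DEFAULT_CLUSTER_GAP_RANGE,
    cutoff: float = DEFAULT_CUTOFF,
    max_retries: int = 10_000,
    apply_to_host: bool = True,
) -> tuple[dict[str, str], list[PlantedHF]]:
    """Copy mutated viral subsequences into the host genome; return truth.

    Planted fragments never overlap each other (collisions are resampled;
    an unresolvable collision after ``max_retries`` attempts is an error),
    so each detectable fragment corresponds to exactly one host HF.

    ``apply_to_host=False`` skips the sequence editing and returns the host
    unchanged with the same truth list (identical placements, identities and
    E-values under the same seed) — useful for placement-level simulation
    studies that never read the sequence.
    """
    if not (0 <= substitution_rate <= 0.3):
        raise ValueError("substitution_rate must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    lengths = scaffold_lengths_of(host)
    scaffolds = sorted(lengths)
    slens = np.array([lengths[s] for s in scaffolds], dtype=float)
    probs = slens / slens.sum()
    virus_ids = sorted(viruses)
    m_total = float(sum(len(v) for v in viruses.values()))
    n_total = float(lengths.genome_length)
    occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}
    host_seqs = {k: list(v) for k, v in host.items()} if apply_to_host else None
    gene_list = [g for g in genes if g.span.length() >= fragment_length_range[0]]

    def uniform_site(flen: int) -> tuple[str, int]:
        for _ in range(max_retries):
            ci = rng.choice(len(scaffolds), p=probs)
            sc = scaffolds[ci]
            cap = lengths[sc] - flen
            if cap < 0:
                continue
            start = int(rng.integers(0, cap + 1))
            if not _overlaps_any(start, start + flen, occupied[sc]):
                return sc, start
        raise ValueError("placement collision: could not find a free uniform site")

    def gene_site(flen: int) -> tuple[str, int]:
        for _ in range(max_retries):
            g = gene_list[rng.integers(0, len(gene_list))]
            cap = g.span.end - flen
            if cap < g.span.start:
                continue
            start = int(rng.integers(g.span.start, cap + 1))
            if not _overlaps_any(start, start + flen, occupied[g.scaffold]):
                return g.scaffold, start
        raise ValueError("placement collision: could not find a free in-gene site")

    flo, fhi = fragment_length_range
    planned: list[tuple[str, int, int, str]] = []  # scaffold, start, length, label
    if placement_model == "clustered":
        i = 0
        while i < n_insertions:
            if i + 1 < n_insertions:
                l1 = int(rng.integers(flo, fhi + 1))
                l2 = int(rng.integers(flo, fhi + 1))
                gap = int(rng.integers(cluster_gap_range[0], cluster_gap_range[1] + 1))
                placed = False
                for _ in range(max_retries):
                    ci = rng.choice(len(scaffolds), p=probs)
                    sc = scaffolds[ci]
                    total_span = l1 + gap + l2
                    cap = lengths[sc] - total_span
                    if cap < 0:
                        continue
                    s1 = int(rng.integers(0, cap + 1))
                    s2 = s1 + l1 + gap
                    if not _overlaps_any(s1, s1 + l1, occupied[sc]) and not _overlaps_any(
                        s2, s2 + l2, occupied[sc]
                    ):
                        occupied[sc].append((s1, s1 + l1))
                        occupied[sc].append((s2, s2 + l2))
                        planned.append((sc, s1, l1, "pair"))
                        planned.append((sc, s2, l2, "pair"))
                        placed = True
                        break
                if not placed:
                    raise ValueError("placement collision in clustered model")
                i += 2
            else:
                l1 = int(rng.integers(flo, fhi + 1))
                sc, s = uniform_site(l1)
                occupied[sc].append((s, s + l1))
                planned.append((sc, s, l1, "any"))
                i += 1
    else:
        for _ in range(n_insertions):
            flen = int(rng.integers(flo, fhi + 1))
            if placement_model == "gene_biased" and rng.random() < gene_fraction:
                sc, s = gene_site(flen)
                label = "gene"
            elif placement_model in ("gene_biased", "uniform"):
                sc, s = uniform_site(flen)
                label = "any"
            else:
                raise ValueError(f"unknown placement model {placement_model!r}")
            occupied[sc].append((s, s + flen))
            planned.append((sc, s, flen, label))

    truth: list[PlantedHF] = []
    for sc, start, flen, label in planned:
        vid = virus_ids[rng.integers(0, len(virus_ids))]
        vcap = len(viruses[vid]) - flen
        vstart = int(rng.integers(0, vcap + 1))
        fragment = viruses[vid][vstart : vstart + flen]
        mutated, n_sub = _mutate(fragment, substitution_rate, rng)
        if host_seqs is not None:
            host_seqs[sc][start : start + flen] = list(mutated)
        identity = 100.0 * (flen - n_sub) / flen
        evalue = simulated_evalue(flen, identity, m_total, n_total)
        truth.append(
            PlantedHF(
                host_location=GenomicInterval(sc, start, start + flen, "+"),
                virus_id=vid,
                virus_location=GenomicInterval(vid, vstart, vstart + flen, "+"),
                identity=identity,
                planted_category=label,
                detectable=evalue <= cutoff,
                placement_model=placement_model,
                evalue=evalue,
                n_substitutions=n_sub,
            )
        )
    truth.sort(key=lambda t: (t.host_location.seq_id, t.host_location.start))
    if host_seqs is None:
        return dict(host), truth
    return {k: "".join(v) for k, v in host_seqs.items()}, truth


def emit_alignment_table(
    truth: Sequence[PlantedHF],
    host_lengths: ScaffoldLengths,
    viruses: dict[str, str],
    n_decoys: int = 20,
    tie_scenarios: int = 2,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
    k: float = DEFAULT_EVALUE_K,
) -> list[AlignmentRecord]:
    """Alignment rows for the detectable truth, plus decoys and tie groups.

    Decoys are short, low-identity rows whose synthetic E-value exceeds the
    cutoff by construction. Each tie scenario duplicates one detectable
    row's host coordinates under a second virus at the identical (minimum)
    E-value, exercising tie retention. Row order is a deterministic shuffle
    of the seed.
    """
    rng = np.random.default_rng(seed)
    virus_ids = sorted(viruses)
    m_total = float(sum(len(v) for v in viruses.values()))
    n_total = float(host_lengths.genome_length)
    rows: list[AlignmentRecord] = []

    detectable = [t for t in truth if t.detectable]
    for t in detectable:
        flen = t.host_location.length()
        minus = rng.random() < 0.5
        s_lo, s_hi = t.host_location.start + 1, t.host_location.end
        matches = flen - t.n_substitutions
        bit = float(2 * matches - 3 * t.n_substitutions)
        rows.append(
            AlignmentRecord(
                query_id=t.virus_id,
                subject_id=t.host_location.seq_id,
                pct_identity=round(t.identity, 2),
                aln_length=flen,
                mismatches=t.n_substitutions,
                gap_opens=0,
                q_start=t.virus_location.start + 1,
                q_end=t.virus_location.end,
                s_start=s_hi if minus else s_lo,
                s_end=s_lo if minus else s_hi,
                evalue=t.evalue,
                bit_score=bit,
            )
        )

    for i in range(min(tie_scenarios, len(detectable))):
        t = detectable[i]
        base = rows[i]
        other = virus_ids[(virus_ids.index(t.virus_id) + 1) % len(virus_ids)]
        flen = t.host_location.length()
        qcap = len(viruses[other]) - flen
        qs = int(rng.integers(0, max(qcap, 0) + 1))
        rows.append(
            AlignmentRecord(
                query_id=other,
                subject_id=base.subject_id,
                pct_identity=base.pct_identity,
                aln_length=flen,
                mismatches=base.mismatches,
                gap_opens=0,
                q_start=qs + 1,
                q_end=qs + flen,
                s_start=base.s_start,
                s_end=base.s_end,
                evalue=base.evalue,
                bit_score=base.bit_score,
            )
        )

    scaffolds = sorted(host_lengths)
    for _ in range(n_decoys):
        flen = int(rng.integers(15, 29))
        mismatches = max(3, int(round(flen * 0.25)))
        matches = flen - mismatches
        identity = 100.0 * matches / flen
        evalue = simulated_evalue(flen, identity, m_total, n_total, k)
        while evalue <= cutoff and flen > 5:  # guard: decoys stay above cutoff
            flen -= 2
            mismatches = max(3, int(round(flen * 0.25)))
            matches = flen - mismatches
            identity = 100.0 * matches / flen
            evalue = simulated_evalue(flen, identity, m_total, n_total, k)
        vid = virus_ids[rng.integers(0, len(virus_ids))]
        sc = scaffolds[rng.integers(0, len(scaffolds))]
        s = int(rng.integers(0, host_lengths[sc] - flen + 1))
        qs = int(rng.integers(0, len(viruses[vid]) - flen + 1))
        rows.append(
            AlignmentRecord(
                query_id=vid,
                subject_id=sc,
                pct_identity=round(identity, 2),
                aln_length=flen,
                mismatches=mismatches,
                gap_opens=0,
                q_start=qs + 1,
                q_end=qs + flen,
                s_start=s + 1,
                s_end=s + flen,
                evalue=evalue,
                bit_score=float(2 * matches - 3 * mismatches),
            )
        )

    order = rng.permutation(len(rows))
    return [rows[i] for i in order]


@dataclass
class SyntheticBundle:
    """Everything one pipeline run needs, plus the planted ground truth."""

    host: dict[str, str]
    scaffold_lengths: ScaffoldLengths
    genes: list[GeneModel]
    viruses: dict[str, str]
    truth: list[PlantedHF]
    records: list  # AlignmentRecord
    params: dict = field(default_factory=dict)


def desk_preset(
    seed: int = 0,
    placement_model: PlacementModel = "uniform",
    n_scaffolds: int = PRESET_N_SCAFFOLDS,
    scaffold_length: int = PRESET_SCAFFOLD_LENGTH,
    n_genes: int = PRESET_N_GENES,
    n_viruses: int = PRESET_N_VIRUSES,
    virus_length: int = PRESET_VIRUS_LENGTH,
    n_insertions: int = PRESET_N_INSERTIONS,
    n_decoys: int = 20,
    tie_scenarios: int = 2,
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE,
    cutoff: float = DEFAULT_CUTOFF,
) -> SyntheticBundle:
    """Desk-scale bundle: 5 x 200 kb scaffolds, 60 genes, 8 viruses, 40 insertions."""
    seed = int(seed)
    host = generate_host_genome(n_scaffolds, [scaffold_length] * n_scaffolds, seed=seed)
    genes = generate_gene_annotation(host, n_genes, seed=seed + 1)
    viruses = generate_viral_genomes(
        n_viruses, (virus_length * 3 // 5, virus_length), seed=seed + 2
    )
    host2, truth = plant_homologies(
        host,
        viruses,
        genes,
        n_insertions=n_insertions,
        placement_model=placement_model,
        substitution_rate=substitution_rate,
        seed=seed + 3,
        cutoff=cutoff,
    )
    lengths = scaffold_lengths_of(host2)
    records = emit_alignment_table(
        truth, lengths, viruses,
        n_decoys=n_decoys, tie_scenarios=tie_scenarios, seed=seed + 4, cutoff=cutoff,
    )
    return SyntheticBundle(
        host=host2,
        scaffold_lengths=lengths,
        genes=genes,
        viruses=viruses,
        truth=truth,
        records=records,
        params={
            "seed": seed,
            "placement_model": placement_model,
            "n_scaffolds": n_scaffolds,
            "scaffold_length": scaffold_length,
            "n_genes": n_genes,
            "n_viruses": n_viruses,
            "n_insertions": n_insertions,
            "n_decoys": n_decoys,
            "tie_scenarios": tie_scenarios,
            "substitution_rate": substitution_rate,
            "cutoff": cutoff,
        },
    )


def write_truth(truth: Sequence[PlantedHF], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            "scaffold\tstart\tend\tvirus_id\tvirus_start\tvirus_end\tidentity\t"
            "category\tdetectable\tplacement_model\tevalue\tn_substitutions\n"
        )
        for t in truth:
            fh.write(
                f"{t.host_location.seq_id}\t{t.host_location.start}\t"
                f"{t.host_location.end}\t{t.virus_id}\t{t.virus_location.start}\t"
                f"{t.virus_location.end}\t{t.identity:.2f}\t{t.planted_category}\t"
                f"{int(t.detectable)}\t{t.placement_model}\t{t.evalue:.3g}\t"
                f"{t.n_substitutions}\n"
            )


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write the bundle as plain-text files; returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "host_fasta": os.path.join(outdir, "host.fasta"),
        "scaffold_lengths": os.path.join(outdir, "scaffolds.tsv"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "virus_fasta": os.path.join(outdir, "viruses.fasta"),
        "alignments": os.path.join(outdir, "alignments.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_fasta(bundle.host, paths["host_fasta"])
    bundle.scaffold_lengths.to_tsv(paths["scaffold_lengths"])
    write_gff3(bundle.genes, paths["gff3"])
    write_fasta(bundle.viruses, paths["virus_fasta"])
    write_blast_tab(
        bundle.records,
        paths["alignments"],
        header="synthetic alignment table; E-values are simulated, not calibrated",
    )
    write_truth(bundle.truth, paths["truth"], header="synthetic planted-fragment truth")
    return paths
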