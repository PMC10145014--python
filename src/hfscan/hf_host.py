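"""Host-side homologous-fragment (HF) identification.

Alignment rows are filtered at an E-value cutoff (default 1e-5), grouped by
"same host fragment", and within each group only the rows at the group's
minimum E-value are retained (ties all kept). Each surviving group becomes
one host HF. A viral fragment hitting several distinct host loci yields one
HF per locus; several viral fragments hitting the same host locus collapse
to a single HF carrying every tied minimum-E-value alignment.

"Same fragment" is not uniquely defined for jittered alignment endpoints, so
the grouping policy is explicit: the default links host intervals on the
same scaffold whose reciprocal overlap is at least ``min_reciprocal_overlap``
(single linkage); an ``exact`` policy groups identical coordinates only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .alignment_io import AlignmentRecord, to_interval
from .intervals import GenomicInterval, union_span

logger = logging.getLogger(__name__)

OverlapPolicy = Literal["reciprocal", "exact"]
DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_MIN_RECIPROCAL_OVERLAP = 0.8


@dataclass
class HostHF:
    """A retained homologous fragment on a host scaffold."""

    hf_id: str
    interval: GenomicInterval
    supporting_alignments: list[AlignmentRecord]
    best_evalue: float
    best_bit_score: float
    virus_ids: frozenset[str]

    @property
    def length(self) -> int:
        return self.interval.length()


def filter_by_evalue(
    records: Sequence[AlignmentRecord], cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> list[AlignmentRecord]:
    """Keep records with evalue <= cutoff, preserving input order."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return [r for r in records if r.evalue <= cutoff]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _linked(
    a: GenomicInterval,
    b: GenomicInterval,
    policy: OverlapPolicy,
    min_reciprocal_overlap: float,
) -> bool:
    if policy == "exact":
        return (a.seq_id, a.start, a.end) == (b.seq_id, b.start, b.end)
    return a.reciprocal_overlap(b) >= min_reciprocal_overlap


def group_by_host_fragment(
    records: Sequence[AlignmentRecord],
    overlap_policy: OverlapPolicy = "reciprocal",
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
) -> list[list[AlignmentRecord]]:
    """Partition records into same-host-fragment groups (single linkage).

    Every record appears in exactly one group. Groups are ordered by the
    leftmost member interval (scaffold, start, end).
    """
    if overlap_policy not in ("reciprocal", "exact"):
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")
    n = len(records)
    ivs = [to_interval(r, "host") for r in records]
    order = sorted(range(n), key=lambda i: (ivs[i].seq_id, ivs[i].start, ivs[i].end))
    uf = _UnionFind(n)
    # sweep: only records whose intervals can still overlap need comparing
    active: list[int] = []
    for idx in order:
        iv = ivs[idx]
        active = [
            j for j in active if ivs[j].seq_id == iv.seq_id and ivs[j].end > iv.start
        ]
        for j in active:
            if _linked(iv, ivs[j], overlap_policy, min_reciprocal_overlap):
                uf.union(idx, j)
        active.append(idx)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    keyed = sorted(
        groups.values(),
        key=lambda g: min((ivs[i].seq_id, ivs[i].start, ivs[i].end) for i in g),
    )
    return [[records[i] for i in g] for g in keyed]


def select_min_evalue(group: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """All records at the group's minimum E-value (ties kept)."""
    if not group:
        raise ValueError("empty group")
    emin = min(r.evalue for r in group)
    return [r for r in group if r.evalue == emin]


@dataclass
class FilterAudit:
    """Per-stage counts so the reduction from raw rows to HFs is auditable."""

    n_input: int = 0
    n_after_cutoff: int = 0
    n_groups: int = 0
    n_hfs: int = 0
    extra: dict = field(default_factory=dict)


def identify_host_hfs(
    records: Sequence[AlignmentRecord],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    overlap_policy: OverlapPolicy = "reciprocal",
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
    audit: FilterAudit | None = None,
) -> list[HostHF]:
    """Full host-side procedure: cutoff -> group -> per-group min-E retention.

    The HF interval is that of the minimum-E-value record; when several
    records tie at the minimum, the union span of the tied records. Output
    is sorted by (scaffold, start, end) and HF ids are assigned in that
    order.
    """
    kept = filter_by_evalue(records, cutoff)
    groups = group_by_host_fragment(kept, overlap_policy, min_reciprocal_overlap)
    hfs: list[HostHF] = []
    for group in groups:
        best = select_min_evalue(group)
        if len(best) == 1:
            interval = to_interval(best[0], "host")
        else:
            interval = union_span([to_interval(r, "host") for r in best])
        hfs.append(
            HostHF(
                hf_id="",
                interval=interval,
                supporting_alignments=best,
                best_evalue=min(r.evalue for r in best),
                best_bit_score=max(r.bit_score for r in best),
                virus_ids=frozenset(r.query_id for r in best),
            )
        )
    hfs.sort(key=lambda h: (h.interval.seq_id, h.interval.start, h.interval.end))
    for i, hf in enumerate(hfs, 1):
        hf.hf_id = f"HF{i:04d}"
    if audit is not None:
        audit.n_input = len(records)
        audit.n_after_cutoff = len(kept)
        audit.n_groups = len(groups)
        audit.n_hfs = len(hfs)
    logger.info(
        "host HF identification: %d rows -> %d after cutoff -> %d groups -> %d HFs",
        len(records), len(kept), len(groups), len(hfs),
    )
    return hfs


def read_host_provenance(path) -> list[HostHF]:
    """Reconstruct HFs from a provenance TSV written by write_host_provenance.

    The supporting alignment rows themselves are not stored in the TSV, so
    the returned HFs carry empty ``supporting_alignments``; every derived
    field (interval, best E-value, best bit score, virus ids) is restored.
    """
    hfs: list[HostHF] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("hf_id\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            hfs.append(
                HostHF(
                    hf_id=parts[0],
                    interval=GenomicInterval(parts[1], int(parts[2]), int(parts[3]), parts[4]),
                    supporting_alignments=[],
                    best_evalue=float(parts[6]),
                    best_bit_score=float(parts[7]),
                    virus_ids=frozenset(parts[9].split(",")) if parts[9] else frozenset(),
                )
            )
    return hfs


def write_host_bed(hfs: Iterable[HostHF], path, header: str | None = None) -> None:
    """BED6: scaffold, start, end, HF id, best bit score, strand."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for hf in hfs:
            fh.write(
                f"{hf.interval.seq_id}\t{hf.interval.start}\t{hf.interval.end}\t"
                f"{hf.hf_id}\t{hf.best_bit_score:g}\t{hf.interval.strand}\n"
            )


def write_host_provenance(hfs: Iterable[HostHF], path, header: str | None = None) -> None:
    """TSV linking each HF to its supporting alignments."""
    cols = (
        "hf_id", "scaffold", "start", "end", "strand", "length",
        "best_evalue", "best_bit_score", "n_support", "virus_ids",
        "support_query_coords",
    )
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for hf in hfs:
            coords = ",".join(
                f"{r.query_id}:{r.q_start}-{r.q_end}" for r in hf.supporting_alignments
            )
            fh.write(
                f"{hf.hf_id}\t{hf.interval.seq_id}\t{hf.interval.start}\t"
                f"{hf.interval.end}\t{hf.interval.strand}\t{hf.length}\t"
                f"{hf.best_evalue:.3g}\t{hf.best_bit_score:g}\t"
                f"{len(hf.supporting_alignments)}\t"
                f"{','.join(sorted(hf.virus_ids))}\t{coords}\n"
            )
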