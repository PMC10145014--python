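"""Virus-side homologous-fragment identification.

The virus-side procedure mirrors the host side up to minimum-E-value
retention, but operates on query (viral) coordinates, then merges fragments
on the same viral genome whose breakpoints lie within a small gap (default
10 bp) and removes exact-coordinate duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignment_io import AlignmentRecord, to_interval
from .hf_host import (
    DEFAULT_EVALUE_CUTOFF,
    DEFAULT_MIN_RECIPROCAL_OVERLAP,
    FilterAudit,
    OverlapPolicy,
    _linked,
    _UnionFind,
    filter_by_evalue,
    select_min_evalue,
)
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_MERGE_GAP = 10


@dataclass
class VirusHF:
    """A merged homologous fragment on a viral genome."""

    hf_id: str
    interval: GenomicInterval
    virus_id: str
    merged_from: list[GenomicInterval]
    best_evalue: float

    @property
    def length(self) -> int:
        return self.interval.length()


def group_by_virus_fragment(
    records: Sequence[AlignmentRecord],
    overlap_policy: OverlapPolicy = "reciprocal",
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
) -> list[list[AlignmentRecord]]:
    """Same single-linkage grouping as the host side, on query coordinates."""
    n = len(records)
    ivs = [to_interval(r, "virus") for r in records]
    order = sorted(range(n), key=lambda i: (ivs[i].seq_id, ivs[i].start, ivs[i].end))
    uf = _UnionFind(n)
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


def select_virus_min_evalue(
    records: Sequence[AlignmentRecord],
    overlap_policy: OverlapPolicy = "reciprocal",
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
) -> list[AlignmentRecord]:
    """Per viral-fragment group, keep every record at the group minimum E."""
    out: list[AlignmentRecord] = []
    for group in group_by_virus_fragment(records, overlap_policy, min_reciprocal_overlap):
        out.extend(select_min_evalue(group))
    return out


def merge_adjacent(
    intervals: Sequence[GenomicInterval], gap_threshold: int = DEFAULT_MERGE_GAP
) -> list[GenomicInterval]:
    """Union intervals on one viral sequence whose gap is <= gap_threshold.

    Gap is ``next.start - current.end`` in half-open coordinates, so touching
    intervals have gap 0 and overlapping intervals always merge. The result
    is sorted with pairwise gaps strictly greater than the threshold; the
    operation is idempotent and insensitive to input order.
    """
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be >= 0")
    if not intervals:
        return []
    seq_ids = {iv.seq_id for iv in intervals}
    if len(seq_ids) > 1:
        raise ValueError(f"merge_adjacent requires one sequence, got {sorted(seq_ids)}")
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start - last.end <= gap_threshold:
            merged[-1] = GenomicInterval(
                last.seq_id, last.start, max(last.end, iv.end), "."
            )
        else:
            merged.append(iv)
    return merged


def dedup(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse exact-coordinate duplicates; output sorted."""
    seen = {(iv.seq_id, iv.start, iv.end): iv for iv in intervals}
    return [seen[k] for k in sorted(seen)]


def identify_virus_hfs(
    records: Sequence[AlignmentRecord],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    gap_threshold: int = DEFAULT_MERGE_GAP,
    overlap_policy: OverlapPolicy = "reciprocal",
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
    audit: FilterAudit | None = None,
) -> list[VirusHF]:
    """Full virus-side procedure: cutoff -> min-E per fragment -> merge -> dedup."""
    kept = filter_by_evalue(records, cutoff)
    selected = select_virus_min_evalue(kept, overlap_policy, min_reciprocal_overlap)

    by_virus: dict[str, list[AlignmentRecord]] = {}
    for rec in selected:
        by_virus.setdefault(rec.query_id, []).append(rec)

    hfs: list[VirusHF] = []
    for virus_id in sorted(by_virus):
        recs = by_virus[virus_id]
        pre = [to_interval(r, "virus") for r in recs]
        merged = merge_adjacent(pre, gap_threshold)
        for m in dedup(merged):
            contributing = [
                (iv, r) for iv, r in zip(pre, recs)
                if iv.start >= m.start and iv.end <= m.end
            ]
            hfs.append(
                VirusHF(
                    hf_id="",
                    interval=m,
                    virus_id=virus_id,
                    merged_from=dedup([iv for iv, _ in contributing]),
                    best_evalue=min(r.evalue for _, r in contributing),
                )
            )
    hfs.sort(key=lambda h: (h.virus_id, h.interval.start, h.interval.end))
    for i, hf in enumerate(hfs, 1):
        hf.hf_id = f"VHF{i:04d}"
    if audit is not None:
        audit.n_input = len(records)
        audit.n_after_cutoff = len(kept)
        audit.n_groups = len(selected)
        audit.n_hfs = len(hfs)
        audit.extra["n_after_min_evalue"] = len(selected)
    logger.info(
        "virus HF identification: %d rows -> %d after cutoff -> %d after min-E -> %d HFs",
        len(records), len(kept), len(selected), len(hfs),
    )
    return hfs


def write_virus_bed(hfs: Iterable[VirusHF], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for hf in hfs:
            fh.write(
                f"{hf.interval.seq_id}\t{hf.interval.start}\t{hf.interval.end}\t"
                f"{hf.hf_id}\t0\t.\n"
            )


def write_virus_counts(
    hfs: Sequence[VirusHF], path, virus_names: dict[str, str] | None = None,
    header: str | None = None,
) -> None:
    """Per-virus HF-count table (accession, number of HFs, name)."""
    counts: dict[str, int] = {}
    for hf in hfs:
        counts[hf.virus_id] = counts.get(hf.virus_id, 0) + 1
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("virus_accession\tn_hfs\tvirus_name\n")
        for virus_id in sorted(counts, key=lambda v: (-counts[v], v)):
            name = (virus_names or {}).get(virus_id, virus_id)
            fh.write(f"{virus_id}\t{counts[virus_id]}\t{name}\n")
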