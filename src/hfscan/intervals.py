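"""Core genomic-interval primitives shared by every pipeline stage.

All internal coordinates are 0-based half-open on both the host and the
virus side; conversion to/from the 1-based inclusive conventions of BLAST
tabular and GFF3 happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named sequence.

    Parameters
    ----------
    seq_id
        Scaffold or viral sequence identifier.
    start, end
        0-based half-open coordinates, ``0 <= start < end``.
    strand
        '+', '-' or '.' (unstranded). Strand is carried for provenance but
        ignored by all distribution analyses.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Overlap fraction relative to the *longer* of the two intervals.

        This is the conservative reading of reciprocal overlap: the returned
        value is >= t iff the overlap is >= t of each interval's length.
        """
        ov = self.overlap_length(other)
        if ov == 0:
            return 0.0
        return ov / max(self.length(), other.length())

    def gap_to(self, other: "GenomicInterval") -> int:
        """Signed gap ``other.start - self.end`` (negative when overlapping)."""
        if self.seq_id != other.seq_id:
            raise ValueError("gap undefined across sequences")
        return other.start - self.end


def union_span(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Smallest interval covering all inputs (must share one seq_id)."""
    if not intervals:
        raise ValueError("empty interval list")
    seq_ids = {iv.seq_id for iv in intervals}
    if len(seq_ids) > 1:
        raise ValueError(f"intervals span multiple sequences: {sorted(seq_ids)}")
    return GenomicInterval(
        intervals[0].seq_id,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
        intervals[0].strand if len({iv.strand for iv in intervals}) == 1 else ".",
    )


def merge_overlapping(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/touching (start, end) half-open pairs; returns sorted."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_covered(intervals: Iterable[tuple[int, int]]) -> int:
    """Number of bases covered by the union of (start, end) pairs."""
    return sum(e - s for s, e in merge_overlapping(intervals))


@dataclass
class ScaffoldLengths:
    """Lengths of host scaffolds; the denominator of every uniform null."""

    lengths: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, seq_id: str) -> int:
        return self.lengths[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.lengths

    def __iter__(self):
        return iter(self.lengths)

    def items(self):
        return self.lengths.items()

    @property
    def genome_length(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def from_tsv(cls, path) -> "ScaffoldLengths":
        """Read a two-column (seq_id, length) TSV, '#' comments allowed."""
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected two tab-separated columns"
                    )
                lengths[parts[0]] = int(parts[1])
        return cls(lengths)

    @classmethod
    def from_fasta(cls, path) -> "ScaffoldLengths":
        from Bio import SeqIO

        return cls({rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for seq_id, length in self.lengths.items():
                fh.write(f"{seq_id}\t{length}\n")
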