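"""Reading and normalising 12-column BLAST tabular alignment output.

Both the plain tabular dialect (``-outfmt 6``) and the commented dialect
(``-outfmt 7``, lines starting with ``#``) are accepted. The query is the
viral sequence and the subject is a host scaffold; a subject start greater
than the subject end encodes a minus-strand hit, which is normalised to a
forward-strand interval with a strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .intervals import GenomicInterval

BLAST_COLUMNS = (
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
)


class BlastParseError(ValueError):
    """Raised when a tabular alignment line cannot be parsed."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One row of 12-column tabular output (1-based inclusive coordinates)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError("q_start > q_end violates the nucleotide-query convention")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not (0 < self.pct_identity <= 100):
            raise ValueError("pct_identity must lie in (0, 100]")

    @property
    def subject_strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    def to_line(self) -> str:
        return "\t".join(
            (
                self.query_id,
                self.subject_id,
                format_float(self.pct_identity),
                str(self.aln_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                format_evalue(self.evalue),
                format_float(self.bit_score),
            )
        )


def format_float(x: float) -> str:
    return f"{x:g}"


def format_evalue(e: float) -> str:
    if e == 0:
        return "0.0"
    return f"{e:.3g}"


def _parse_line(line: str, lineno: int) -> AlignmentRecord:
    fields = line.split("\t")
    if len(fields) != 12:
        raise BlastParseError(
            f"line {lineno}: expected 12 tab-separated fields, got {len(fields)}"
        )
    try:
        return AlignmentRecord(
            query_id=fields[0],
            subject_id=fields[1],
            pct_identity=float(fields[2]),
            aln_length=int(fields[3]),
            mismatches=int(fields[4]),
            gap_opens=int(fields[5]),
            q_start=int(fields[6]),
            q_end=int(fields[7]),
            s_start=int(fields[8]),
            s_end=int(fields[9]),
            evalue=float(fields[10]),
            bit_score=float(fields[11]),
        )
    except ValueError as exc:
        raise BlastParseError(f"line {lineno}: {exc}") from exc


def read_blast_tab(path) -> list[AlignmentRecord]:
    """Read tabular alignments in file order, skipping '#' comment lines.

    An empty file yields an empty list. A line with the wrong number of
    fields or a non-numeric numeric field raises :class:`BlastParseError`
    naming the offending line number.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            records.append(_parse_line(line, lineno))
    return records


def write_blast_tab(records: Iterable[AlignmentRecord], path, header: str | None = None) -> None:
    """Write records back to 12-column text (round-trips through the reader)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def to_interval(record: AlignmentRecord, side: Literal["host", "virus"]) -> GenomicInterval:
    """Oriented 0-based half-open interval for one side of an alignment.

    Host side uses subject coordinates with min/max ordering and the strand
    implied by the subject coordinate order; virus side uses the query
    coordinates, always '+'.
    """
    if side == "host":
        lo, hi = sorted((record.s_start, record.s_end))
        return GenomicInterval(record.subject_id, lo - 1, hi, record.subject_strand)
    if side == "virus":
        return GenomicInterval(record.query_id, record.q_start - 1, record.q_end, "+")
    raise ValueError(f"side must be 'host' or 'virus', got {side!r}")
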