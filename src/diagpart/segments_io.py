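"""Reading and writing lastZ-dialect segment files.

A *segment file* is the hand-off between the seeding/filtering stage of a
pairwise aligner and its gapped-extension stage: one whitespace-delimited
record per HSP (high-scoring segment pair), carrying the target interval,
the query interval, the strand and the ungapped score.  On disk the dialect
uses origin-1 closed intervals; internally everything is 0-based half-open,
and the conversion happens only here, at the I/O boundary.

Reverse-strand records keep their query coordinates in the
reverse-complement frame of the query sequence (the convention of the
ecosystem these files come from); :func:`diagonal_key` maps them back to the
forward frame when computing anti-diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

__all__ = [
    "Segment",
    "AnchorPoint",
    "SegmentParseError",
    "read_segments",
    "write_segments",
    "anchor_of",
    "diagonal_key",
    "estimate_line_count",
]

FORWARD = "+"
REVERSE = "-"
_STRANDS = (FORWARD, REVERSE)


class SegmentParseError(ValueError):
    """Raised for a malformed segment-file row; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True, order=True)
class Segment:
    """One HSP: equal-length ungapped intervals on target and query.

    Coordinates are 0-based half-open.  For ``strand == '-'`` the query
    interval lives in the reverse-complement frame of the query sequence.
    """

    target_name: str
    target_start: int
    target_end: int
    query_name: str
    query_start: int
    query_end: int
    strand: str
    score: int

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if not (self.target_start < self.target_end):
            raise ValueError("target interval must be non-empty (start < end)")
        if not (self.query_start < self.query_end):
            raise ValueError("query interval must be non-empty (start < end)")
        if (self.target_end - self.target_start) != (self.query_end - self.query_start):
            raise ValueError("HSP intervals must have equal length (ungapped)")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def length(self) -> int:
        return self.target_end - self.target_start


@dataclass(frozen=True)
class AnchorPoint:
    """The single point on an HSP from which gapped extension starts."""

    target_pos: int
    query_pos: int
    strand: str


def anchor_of(segment: Segment) -> AnchorPoint:
    """Midpoint anchor of an HSP (floor of the interval midpoints).

    The production pipeline does not know where the downstream aligner will
    place its (optimal) anchor, so the HSP is reduced to the midpoint of its
    two intervals and partitioned on that assumption.
    """
    return AnchorPoint(
        target_pos=(segment.target_start + segment.target_end) // 2,
        query_pos=(segment.query_start + segment.query_end) // 2,
        strand=segment.strand,
    )


def diagonal_key(anchor: AnchorPoint, query_length: int | None = None) -> int:
    """Integer key constant along the anchor's gap-free extension path.

    Forward anchors extend along the main diagonal, where
    ``target_pos - query_pos`` is constant.  Reverse anchors carry query
    coordinates in the reverse-complement frame; mapped to the forward frame
    (``q_fwd = query_length - 1 - q_rc``) their extension follows the
    anti-diagonal, where ``target_pos + q_fwd`` is constant.
    """
    if anchor.strand == FORWARD:
        return anchor.target_pos - anchor.query_pos
    if query_length is None:
        raise ValueError("query_length is required for reverse-strand anchors")
    return anchor.target_pos + (query_length - 1 - anchor.query_pos)


def read_segments(source: IO[str] | Iterable[str]) -> list[Segment]:
    """Parse a segment file into Segments (input order preserved).

    ``source`` is any iterable of lines.  On-disk intervals are origin-1
    closed; returned Segments are 0-based half-open.  Blank lines are
    ignored.  Malformed rows raise :class:`SegmentParseError` with the
    1-based line number.
    """
    out: list[Segment] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 8:
            raise SegmentParseError(lineno, f"expected 8 fields, got {len(fields)}")
        name1, s1, e1, name2, s2, e2, strand, score = fields
        try:
            ts, te, qs, qe, sc = int(s1), int(e1), int(s2), int(e2), int(score)
        except ValueError:
            raise SegmentParseError(lineno, "non-numeric coordinate or score") from None
        if strand not in _STRANDS:
            raise SegmentParseError(lineno, f"unknown strand symbol {strand!r}")
        if ts > te or qs > qe:
            raise SegmentParseError(lineno, "start > end")
        try:
            seg = Segment(name1, ts - 1, te, name2, qs - 1, qe, strand, sc)
        except ValueError as exc:
            raise SegmentParseError(lineno, str(exc)) from None
        out.append(seg)
    return out


def write_segments(segments: Sequence[Segment], sink: IO[str]) -> int:
    """Write Segments in the on-disk dialect (origin-1 closed); returns the count."""
    n = 0
    for seg in segments:
        sink.write(
            f"{seg.target_name}\t{seg.target_start + 1}\t{seg.target_end}\t"
            f"{seg.query_name}\t{seg.query_start + 1}\t{seg.query_end}\t"
            f"{seg.strand}\t{seg.score}\n"
        )
        n += 1
    return n


def estimate_line_count(file_size: int, sample_line_size: int) -> int:
    """Estimate the number of records in a segment file from its byte size.

    Dividing the file size by the byte length of a single sampled line gives
    a close approximation of the record count without reading the whole
    file; it is exact when every line has the sampled length.
    """
    if sample_line_size <= 0:
        raise ValueError("sample_line_size must be positive")
    if file_size < 0:
        raise ValueError("file_size must be non-negative")
    return file_size // sample_line_size
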