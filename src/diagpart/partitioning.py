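"""Diagonal partitioning of segment files, with a row-wise baseline.

The gapped-extension stage of a pairwise aligner processes one segment file
per task; a file with a disproportionate number of HSPs dominates the wall
clock while every other worker idles (tail latency).  Splitting files
bounds per-task work, but anchors on the same alignment are *dependent*:
extending one suppresses the others, and placing them in different files
makes each file re-extend the shared region, producing straddling
alignments (duplicates, overlaps, and extra alignments from divergent
equal-scoring paths).

Dependent anchors lie along the extension diagonal, so partitioning by
diagonal key — rather than by position ("row-wise") — keeps them together.
This module implements both schemes, the dynamic upper-quartile work
threshold, and the straddle accounting used to compare the schemes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .segments_io import FORWARD, REVERSE, Segment, anchor_of, diagonal_key

__all__ = [
    "Partition",
    "StraddleReport",
    "partition_diagonal",
    "partition_rowwise",
    "dynamic_max_size",
    "straddle_report",
]


@dataclass(frozen=True)
class Partition:
    """A band of Segments destined for one independent segment file.

    ``strand`` is '+' or '-' for diagonal partitions and None for row-wise
    chunks (which ignore strand).  ``key_range`` is the (min, max) diagonal
    key of the members, or None for row-wise chunks.
    """

    id: int
    strand: str | None
    segments: tuple[Segment, ...]
    key_range: tuple[int, int] | None


@dataclass(frozen=True)
class StraddleReport:
    """Accounting of straddling alignments in a partitioned run.

    duplicates: exact-coordinate repeats within the partitioned output.
    overlaps:   unordered pairs of partitioned alignments from *different*
                partitions intersecting on both sequences with equal strand.
    extras:     partitioned alignments absent from the reference output.
    missing:    reference alignments absent from the partitioned output.
    inflation:  |partitioned| / max(|reference|, 1).
    """

    duplicates: int
    overlaps: int
    extras: int
    missing: int
    inflation: float

    @property
    def straddle_sum(self) -> int:
        return self.duplicates + self.overlaps + self.extras

    @property
    def clean(self) -> bool:
        """True when the two outputs are identical record for record.

        With all four counts at zero the partitioned output is a set equal
        to the reference set, so inflation is exactly 1.0 — or 0.0 in the
        degenerate case of two empty outputs.
        """
        return (
            self.duplicates == 0
            and self.overlaps == 0
            and self.extras == 0
            and self.missing == 0
            and self.inflation in (0.0, 1.0)
        )


def _keyed(segments: Sequence[Segment], query_lengths: Mapping[str, int] | None):
    """(key, anchor, input index) triples; resolves reverse-frame keys."""
    out = []
    for idx, seg in enumerate(segments):
        a = anchor_of(seg)
        if seg.strand == REVERSE:
            if query_lengths is None or seg.query_name not in query_lengths:
                raise ValueError(
                    "query_lengths mapping is required for reverse-strand segments"
                )
            key = diagonal_key(a, query_lengths[seg.query_name])
        else:
            key = diagonal_key(a)
        out.append((key, a, idx))
    return out


def partition_diagonal(
    segments: Sequence[Segment],
    max_segments: int,
    query_lengths: Mapping[str, int] | None = None,
) -> list[Partition]:
    """Split segments into diagonal bands of at most ``max_segments`` members.

    Segments are grouped by strand; within a strand they are ordered by
    (diagonal key, anchor target position, input order) and whole diagonals
    are packed greedily, in key order, into partitions of at most
    ``max_segments`` members.  A diagonal is never split across partitions:
    a single key whose population exceeds the bound forms one oversized
    partition on its own.

    ``query_lengths`` maps query names to sequence lengths and is required
    only when reverse-strand segments are present (their anti-diagonal key
    depends on the query length).
    """
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    partitions: list[Partition] = []
    pid = 0
    for strand in (FORWARD, REVERSE):
        strand_segs = [s for s in segments if s.strand == strand]
        if not strand_segs:
            continue
        keyed = _keyed(strand_segs, query_lengths)
        keyed.sort(key=lambda t: (t[0], t[1].target_pos, t[2]))
        # group into whole diagonals, preserving key order
        groups: list[tuple[int, list[Segment]]] = []
        for key, _a, idx in keyed:
            if groups and groups[-1][0] == key:
                groups[-1][1].append(strand_segs[idx])
            else:
                groups.append((key, [strand_segs[idx]]))
        # greedy packing of consecutive whole-diagonal groups
        cur: list[Segment] = []
        cur_keys: list[int] = []

        def flush() -> None:
            nonlocal pid, cur, cur_keys
            if cur:
                partitions.append(
                    Partition(pid, strand, tuple(cur), (min(cur_keys), max(cur_keys)))
                )
                pid += 1
                cur, cur_keys = [], []

        for key, members in groups:
            if len(members) > max_segments:
                # oversized-diagonal exception: one partition for this key
                flush()
                cur, cur_keys = list(members), [key]
                flush()
            elif len(cur) + len(members) <= max_segments:
                cur.extend(members)
                cur_keys.append(key)
            else:
                flush()
                cur, cur_keys = list(members), [key]
        flush()
    return partitions


def partition_rowwise(segments: Sequence[Segment], max_segments: int) -> list[Partition]:
    """Naive baseline: sort by position and chunk, ignoring diagonals and strand."""
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    order = sorted(
        range(len(segments)),
        key=lambda i: (segments[i].target_start, segments[i].query_start, i),
    )
    partitions = []
    for pid, start in enumerate(range(0, len(order), max_segments)):
        chunk = tuple(segments[i] for i in order[start : start + max_segments])
        partitions.append(Partition(pid, None, chunk, None))
    return partitions


def dynamic_max_size(history: Sequence[int], default_bound: int) -> int:
    """Choose the per-partition segment bound from previously seen file sizes.

    The bound is the nearest-rank upper quartile — the ceil(0.75·n)-th
    smallest — of the record counts of segment files generated so far
    (before partitioning).  With no history the ``default_bound`` is used.
    Because every stage writes its files to a shared directory, the history
    can be recovered by listing that directory; no inter-process
    communication is needed.
    """
    if default_bound < 1:
        raise ValueError("default_bound must be >= 1")
    if any(h <= 0 for h in history):
        raise ValueError("history counts must be positive")
    if not history:
        return default_bound
    ranked = sorted(history)
    rank = math.ceil(0.75 * len(ranked))  # 1-based nearest rank
    return ranked[rank - 1]


def _identity(aln) -> tuple:
    return (aln.target_name, aln.query_name, aln.strand, tuple(aln.blocks))


def _envelope(aln) -> tuple[int, int, int, int]:
    blocks = list(aln.blocks)
    return (
        min(b[0] for b in blocks),
        max(b[1] for b in blocks),
        min(b[2] for b in blocks),
        max(b[3] for b in blocks),
    )


def straddle_report(
    reference_alignments: Sequence,
    partitioned_alignments: Sequence[Sequence],
) -> StraddleReport:
    """Compare a partitioned run's merged output with the unpartitioned run.

    ``partitioned_alignments`` is grouped by partition (one inner sequence
    per partition) so that overlapping pairs can be restricted to
    alignments from *different* partitions.  Alignments are compared by
    their coordinate identity (names, strand, block list); overlap means
    the alignments' coordinate envelopes intersect on both the target and
    the query with matching strand.
    """
    flat = [a for group in partitioned_alignments for a in group]
    ref_ids = {_identity(a) for a in reference_alignments}

    counts: dict[tuple, int] = {}
    for a in flat:
        key = _identity(a)
        counts[key] = counts.get(key, 0) + 1
    duplicates = sum(c - 1 for c in counts.values() if c > 1)

    overlaps = 0
    groups = [list(g) for g in partitioned_alignments]
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            for a in groups[gi]:
                ea = _envelope(a)
                for b in groups[gj]:
                    if (
                        a.strand == b.strand
                        and a.target_name == b.target_name
                        and a.query_name == b.query_name
                    ):
                        eb = _envelope(b)
                        if ea[0] < eb[1] and eb[0] < ea[1] and ea[2] < eb[3] and eb[2] < ea[3]:
                            overlaps += 1

    extras = sum(1 for a in flat if _identity(a) not in ref_ids)
    part_ids = {_identity(a) for a in flat}
    missing = sum(1 for a in reference_alignments if _identity(a) not in part_ids)
    inflation = len(flat) / max(len(reference_alignments), 1)
    return StraddleReport(duplicates, overlaps, extras, missing, inflation)
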