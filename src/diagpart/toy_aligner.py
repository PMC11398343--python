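"""A small exact seed-filter-extend aligner with anchor-dependency semantics.

This aligner exists to *measure* partitioning correctness, not to compete
with production aligners.  It reproduces the three behaviours that make
naive partitioning of segment files unsafe:

* anchors are extended in descending HSP-score order, and an anchor whose
  exact cell is crossed by an earlier alignment's traceback is suppressed
  (never extended) — so anchors are *dependent*;
* each anchor is extended forward and backward with *different* DP
  tie-break preferences, so independently re-extended anchors can follow
  different, equally scoring paths;
* extensions run on the full sequences regardless of which partition the
  anchor came from, so splitting dependent anchors across partitions
  yields duplicate, overlapping, or extra ("straddling") alignments.

Pipeline: :func:`find_seeds` (exact k-mer matches, both strands) ->
:func:`ungapped_extend` (x-drop diagonal extension to HSPs/Segments) ->
a partitioner -> :func:`gapped_extend` per partition (y-drop DP) ->
:func:`align` merges everything and reports straddling against an
unpartitioned reference run.

Coordinate frames follow the segment-file convention: reverse-strand
segments and alignments carry query coordinates in the reverse-complement
frame of the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from ._ydrop import ydrop_extend
from .partitioning import (
    Partition,
    StraddleReport,
    partition_diagonal,
    partition_rowwise,
    straddle_report,
)
from .scoring import ScoringScheme, encode, hoxd70, revcomp
from .segments_io import FORWARD, REVERSE, AnchorPoint, Segment, anchor_of

__all__ = [
    "Seed",
    "Alignment",
    "AlignResult",
    "find_seeds",
    "ungapped_extend",
    "gapped_extend",
    "align",
    "coverage",
]


class Seed(NamedTuple):
    """An exact k-mer co-occurrence; query position is in the strand frame."""

    target_pos: int
    query_pos: int
    strand: str
    k: int


@dataclass(frozen=True)
class Alignment:
    """A gapped local alignment as ordered ungapped blocks.

    Blocks are (target_start, target_end, query_start, query_end), 0-based
    half-open, increasing on both sequences in the strand frame.  ``path``
    is the ordered aligned base pairs of the traceback; ``dp_cells`` is the
    number of DP cells touched while producing this alignment (a work
    measure, not part of the alignment's identity).
    """

    target_name: str
    query_name: str
    strand: str
    blocks: tuple[tuple[int, int, int, int], ...]
    score: int
    path: tuple[tuple[int, int], ...] = field(repr=False, default=())
    dp_cells: int = field(compare=False, default=0)

    @property
    def identity_key(self) -> tuple:
        return (self.target_name, self.query_name, self.strand, self.blocks)


def find_seeds(target: str, query: str, k: int = 12) -> list[Seed]:
    """All exact k-word matches between target and query, both strands.

    Words containing N never match.  Reverse-strand seeds report the query
    position in the reverse-complement frame.  Deterministic order:
    forward seeds first, by (query_pos, target_pos), then reverse seeds.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    target = target.upper()
    index: dict[str, list[int]] = {}
    for i in range(0, len(target) - k + 1):
        word = target[i : i + k]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    seeds: list[Seed] = []
    for strand, qseq in ((FORWARD, query.upper()), (REVERSE, revcomp(query).upper())):
        for j in range(0, len(qseq) - k + 1):
            word = qseq[j : j + k]
            if "N" in word:
                continue
            for i in index.get(word, ()):
                seeds.append(Seed(i, j, strand, k))
    return seeds


def _xdrop_on_diagonal(
    scores: np.ndarray, seed_lo: int, seed_hi: int, x_drop: int
) -> tuple[int, int, int]:
    """Extend [seed_lo, seed_hi) along a per-position score vector.

    Returns the trimmed (lo, hi, score) of the maximal-scoring run found by
    x-drop extension right of seed_hi and left of seed_lo.
    """
    base = int(scores[seed_lo:seed_hi].sum())
    hi = seed_hi
    right_gain = 0
    tail = scores[seed_hi:]
    if tail.size:
        cum = np.cumsum(tail)
        run_max = np.maximum.accumulate(cum)
        dropped = run_max - cum > x_drop
        stop = int(np.argmax(dropped)) if dropped.any() else tail.size
        if stop > 0:
            prefix = cum[:stop]
            best = int(prefix.max())
            if best > 0:
                hi = seed_hi + int(np.argmax(prefix)) + 1
                right_gain = best
    lo = seed_lo
    left_gain = 0
    head = scores[:seed_lo][::-1]
    if head.size:
        cum = np.cumsum(head)
        run_max = np.maximum.accumulate(cum)
        dropped = run_max - cum > x_drop
        stop = int(np.argmax(dropped)) if dropped.any() else head.size
        if stop > 0:
            prefix = cum[:stop]
            best = int(prefix.max())
            if best > 0:
                lo = seed_lo - (int(np.argmax(prefix)) + 1)
                left_gain = best
    return lo, hi, base + right_gain + left_gain


def ungapped_extend(
    seeds: Sequence[Seed],
    target: str,
    query: str,
    scheme: ScoringScheme | None = None,
    target_name: str = "target",
    query_name: str = "query",
) -> list[Segment]:
    """X-drop extension of seeds along their diagonals into HSP Segments.

    Each seed is extended in both directions until the running score drops
    ``x_drop`` below its maximum, trimmed to the best-scoring span, and
    kept when the span scores at least ``hsp_threshold``.  Seeds falling
    inside a span already explored on the same diagonal are skipped, and
    identical resulting segments are deduplicated (first occurrence wins).
    """
    scheme = scheme or hoxd70()
    t_arr = encode(target)
    frames = {FORWARD: encode(query), REVERSE: encode(revcomp(query))}
    order = sorted(
        range(len(seeds)),
        key=lambda i: (
            seeds[i].strand,
            seeds[i].target_pos - seeds[i].query_pos,
            seeds[i].target_pos,
        ),
    )
    out: list[Segment] = []
    seen: set[tuple] = set()
    last_span: tuple[str, int, int, int] | None = None  # (strand, diag, lo, hi)
    for idx in order:
        seed = seeds[idx]
        q_arr = frames[seed.strand]
        d = seed.target_pos - seed.query_pos
        if (
            last_span is not None
            and last_span[0] == seed.strand
            and last_span[1] == d
            and seed.target_pos >= last_span[2]
            and seed.target_pos + seed.k <= last_span[3]
        ):
            continue
        p0 = max(0, d)
        p1 = min(len(t_arr), len(q_arr) + d)
        if p1 - p0 < seed.k:
            continue
        scores = scheme.matrix[t_arr[p0:p1], q_arr[p0 - d : p1 - d]]
        lo, hi, score = _xdrop_on_diagonal(
            scores, seed.target_pos - p0, seed.target_pos + seed.k - p0, scheme.x_drop
        )
        lo += p0
        hi += p0
        last_span = (seed.strand, d, lo, hi)
        if score < scheme.hsp_threshold:
            continue
        seg = Segment(
            target_name, lo, hi, query_name, lo - d, hi - d, seed.strand, score
        )
        if seg not in seen:
            seen.add(seg)
            out.append(seg)
    return out


def _pairs_to_blocks(pairs: Sequence[tuple[int, int]]):
    blocks = []
    for t, q in pairs:
        if blocks and t == blocks[-1][1] and q == blocks[-1][3]:
            blocks[-1][1] += 1
            blocks[-1][3] += 1
        else:
            blocks.append([t, t + 1, q, q + 1])
    return tuple(tuple(b) for b in blocks)


def gapped_extend(
    segments: Sequence[Segment],
    target: str,
    query: str,
    scheme: ScoringScheme | None = None,
) -> list[Alignment]:
    """Y-drop gapped extension of segment anchors, with suppression.

    Anchors (segment midpoints) are processed in descending HSP score (ties:
    input order).  Each pending anchor is extended backward then forward by
    banded y-drop DP; forward extension breaks score ties preferring
    diagonal, then a gap in the query, then a gap in the target, and the
    backward extension uses the opposite gap preference.  After each
    alignment, any pending anchor of the same strand whose exact cell lies
    on the traceback path is suppressed.  An alignment identical to one
    already produced in this call is not emitted twice.
    """
    scheme = scheme or hoxd70()
    t_arr = encode(target)
    frames = {FORWARD: encode(query), REVERSE: encode(revcomp(query))}
    order = sorted(range(len(segments)), key=lambda i: (-segments[i].score, i))
    anchors: list[AnchorPoint] = [anchor_of(s) for s in segments]
    for s, a in zip(segments, anchors):
        if not (0 <= a.target_pos < len(t_arr)) or not (
            0 <= a.query_pos < len(frames[s.strand])
        ):
            raise ValueError(f"anchor of {s} lies outside the sequences")

    suppressed = [False] * len(segments)
    emitted: set[tuple] = set()
    covered: dict[str, set[tuple[int, int]]] = {FORWARD: set(), REVERSE: set()}
    out: list[Alignment] = []

    for idx in order:
        if suppressed[idx]:
            continue
        seg = segments[idx]
        a = anchors[idx]
        q_arr = frames[seg.strand]
        ta, qa = a.target_pos, a.query_pos

        back = ydrop_extend(
            t_arr[:ta][::-1],
            q_arr[:qa][::-1],
            scheme.matrix,
            scheme.gap_open,
            scheme.gap_extend,
            scheme.y_drop,
            prefer_horizontal=True,
        )
        fwd = ydrop_extend(
            t_arr[ta:],
            q_arr[qa:],
            scheme.matrix,
            scheme.gap_open,
            scheme.gap_extend,
            scheme.y_drop,
            prefer_horizontal=False,
        )
        pairs = [(ta - 1 - i, qa - 1 - j) for i, j in reversed(back.pairs)]
        pairs += [(ta + i, qa + j) for i, j in fwd.pairs]
        cells = back.cells + fwd.cells
        if not pairs:
            suppressed[idx] = True
            continue

        pair_set = set(pairs)
        covered[seg.strand] |= pair_set
        for jdx in order:
            if not suppressed[jdx] and jdx != idx:
                other = anchors[jdx]
                if (
                    segments[jdx].strand == seg.strand
                    and (other.target_pos, other.query_pos) in covered[seg.strand]
                ):
                    suppressed[jdx] = True
        suppressed[idx] = True

        aln = Alignment(
            target_name=seg.target_name,
            query_name=seg.query_name,
            strand=seg.strand,
            blocks=_pairs_to_blocks(pairs),
            score=back.score + fwd.score,
            path=tuple(pairs),
            dp_cells=cells,
        )
        if aln.identity_key in emitted:
            continue
        emitted.add(aln.identity_key)
        out.append(aln)
    return out


@dataclass
class AlignResult:
    """End-to-end harness output: per-partition alignments plus accounting."""

    segments: list[Segment]
    partitions: list[Partition]
    partitioned: list[list[Alignment]]
    reference: list[Alignment]
    report: StraddleReport

    @property
    def alignments(self) -> list[Alignment]:
        return [a for group in self.partitioned for a in group]

    @property
    def work_partitioned(self) -> int:
        return sum(a.dp_cells for a in self.alignments)

    @property
    def work_reference(self) -> int:
        return sum(a.dp_cells for a in self.reference)


def align(
    target: str,
    query: str,
    scheme: ScoringScheme | None = None,
    partitioner: str = "diagonal",
    max_segments: int | None = None,
    k: int = 12,
    target_name: str = "target",
    query_name: str = "query",
) -> AlignResult:
    """Seed, filter, partition, extend, and report straddling alignments.

    ``partitioner`` is 'diagonal', 'rowwise', or 'none' (single partition).
    The straddle report compares the merged per-partition output against a
    single unpartitioned run on the identical segment set.
    """
    scheme = scheme or hoxd70()
    seeds = find_seeds(target, query, k=k)
    segments = ungapped_extend(
        seeds, target, query, scheme, target_name=target_name, query_name=query_name
    )

    if partitioner == "none":
        partitions = (
            [Partition(0, None, tuple(segments), None)] if segments else []
        )
    elif partitioner == "diagonal":
        if max_segments is None:
            raise ValueError("max_segments is required for the diagonal partitioner")
        partitions = partition_diagonal(
            segments, max_segments, query_lengths={query_name: len(query)}
        )
    elif partitioner == "rowwise":
        if max_segments is None:
            raise ValueError("max_segments is required for the rowwise partitioner")
        partitions = partition_rowwise(segments, max_segments)
    else:
        raise ValueError(f"unknown partitioner {partitioner!r}")

    reference = gapped_extend(segments, target, query, scheme)
    partitioned = [
        gapped_extend(list(p.segments), target, query, scheme) for p in partitions
    ]
    report = straddle_report(reference, partitioned)
    return AlignResult(segments, partitions, partitioned, reference, report)


def _merged_length(intervals: list[tuple[int, int]], core: tuple[int, int]) -> int:
    s, e = core
    clipped = sorted(
        (max(a, s), min(b, e)) for a, b in intervals if min(b, e) > max(a, s)
    )
    total = 0
    cur_s: int | None = None
    cur_e = 0
    for a, b in clipped:
        if cur_s is None or a > cur_e:
            if cur_s is not None:
                total += cur_e - cur_s
            cur_s, cur_e = a, b
        else:
            cur_e = max(cur_e, b)
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def coverage(
    alignments: Sequence[Alignment],
    target_core: tuple[int, int],
    query_core: tuple[int, int],
    query_length: int | None = None,
) -> tuple[float, float]:
    """Fraction of each homologous core covered by at least one block.

    Each alignment contributes the interval it spans on each sequence (its
    coordinate envelope, as alignment intervals are counted in practice
    when merging aligner output); overlapping intervals are merged before
    counting, and only positions inside the core intervals (0-based
    half-open; flanks excluded) are counted.  Reverse-strand alignments
    carry query coordinates in the reverse-complement frame;
    ``query_length`` is required to map them back when present.
    """
    for name, core in (("target", target_core), ("query", query_core)):
        if core[1] <= core[0]:
            raise ValueError(f"empty {name} core interval")
    t_iv: list[tuple[int, int]] = []
    q_iv: list[tuple[int, int]] = []
    for aln in alignments:
        ts = min(b[0] for b in aln.blocks)
        te = max(b[1] for b in aln.blocks)
        qs = min(b[2] for b in aln.blocks)
        qe = max(b[3] for b in aln.blocks)
        t_iv.append((ts, te))
        if aln.strand == REVERSE:
            if query_length is None:
                raise ValueError(
                    "query_length is required with reverse-strand alignments"
                )
            q_iv.append((query_length - qe, query_length - qs))
        else:
            q_iv.append((qs, qe))
    t_frac = _merged_length(t_iv, target_core) / (target_core[1] - target_core[0])
    q_frac = _merged_length(q_iv, query_core) / (query_core[1] - query_core[0])
    return t_frac, q_frac
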