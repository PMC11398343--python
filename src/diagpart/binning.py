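"""LPT packing of whole chromosomes into similarly sized bins.

To run several aligner instances in parallel, each instance is handed a
pair of bins, where a bin is a set of *whole* chromosomes of roughly equal
total length.  Chromosomes are never split: splitting would create
straddling alignments at the cut and would require lifting alignment
coordinates back afterwards.  Bins are built with the classic
longest-processing-time-first (LPT) heuristic, whose makespan is within
(4/3 - 1/(3m)) of optimal for m bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, NamedTuple, Sequence

__all__ = [
    "Chromosome",
    "Bin",
    "lpt_bins",
    "bins_for_target_size",
    "pair_bins",
    "read_chromosome_lengths",
]


class Chromosome(NamedTuple):
    name: str
    length: int


@dataclass(frozen=True)
class Bin:
    id: int
    members: tuple[Chromosome, ...]
    load: int


def lpt_bins(chromosomes: Sequence[Chromosome], n_bins: int) -> list[Bin]:
    """Assign chromosomes to ``n_bins`` bins, longest first, least-loaded bin first.

    Ties in length keep input order; ties in load go to the lowest bin id.
    Deterministic for identical input.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not chromosomes:
        raise ValueError("chromosomes must be non-empty")
    for c in chromosomes:
        if c.length <= 0:
            raise ValueError(f"chromosome {c.name!r} has non-positive length")
    order = sorted(range(len(chromosomes)), key=lambda i: (-chromosomes[i].length, i))
    loads = [0] * n_bins
    members: list[list[Chromosome]] = [[] for _ in range(n_bins)]
    for i in order:
        b = loads.index(min(loads))  # first minimum -> lowest bin id
        members[b].append(chromosomes[i])
        loads[b] += chromosomes[i].length
    return [Bin(b, tuple(members[b]), loads[b]) for b in range(n_bins)]


def bins_for_target_size(
    chromosomes: Sequence[Chromosome], target_bin_size: int
) -> list[Bin]:
    """LPT binning with the bin count derived from a target bases-per-bin.

    ``n_bins = max(1, ceil(total / target_bin_size))``; with the production
    default of ~200 Mbp per bin, a 600 Mbp genome yields 3 bins.  A single
    chromosome longer than the target simply occupies an oversized bin.
    """
    if target_bin_size <= 0:
        raise ValueError("target_bin_size must be positive")
    total = sum(c.length for c in chromosomes)
    n_bins = max(1, math.ceil(total / target_bin_size))
    return lpt_bins(chromosomes, n_bins)


def pair_bins(target_bins: Sequence[Bin], query_bins: Sequence[Bin]) -> list[tuple[Bin, Bin]]:
    """Full cross product of target and query bins, ordered by (target id, query id)."""
    if not target_bins or not query_bins:
        raise ValueError("both bin collections must be non-empty")
    return [
        (t, q)
        for t in sorted(target_bins, key=lambda b: b.id)
        for q in sorted(query_bins, key=lambda b: b.id)
    ]


def read_chromosome_lengths(source: IO[str] | Iterable[str]) -> list[Chromosome]:
    """Parse a two-column name/length table (FASTA-index style; extra columns ignored)."""
    out = []
    seen = set()
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected at least 2 columns")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric length") from None
        if name in seen:
            raise ValueError(f"line {lineno}: duplicate chromosome name {name!r}")
        seen.add(name)
        out.append(Chromosome(name, length))
    return out
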