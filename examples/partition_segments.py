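"""Partition a segment file along extension diagonals.

Builds a small collection of HSP records (two diagonal clusters plus a
reverse-strand hit), partitions it with the diagonal scheme and the naive
row-wise baseline, and shows the dynamic upper-quartile bound.  Each
printed partition corresponds to one segment file the gapped-extension
stage would process independently; the key range shows the diagonal band
it covers.
"""

import io

from diagpart import (
    Segment,
    dynamic_max_size,
    partition_diagonal,
    partition_rowwise,
    write_segments,
)

# two forward homologies on nearby diagonals, plus one reverse-strand hit
segments = [
    Segment("chr1", 100 + i * 30, 120 + i * 30, "chrA", 100 + i * 30, 120 + i * 30, "+", 900 - i)
    for i in range(6)
] + [
    Segment("chr1", 400 + i * 25, 415 + i * 25, "chrA", 150 + i * 25, 165 + i * 25, "+", 700 - i)
    for i in range(4)
] + [
    Segment("chr1", 700, 730, "chrA", 300, 330, "-", 500),
]

for name, parts in (
    ("diagonal", partition_diagonal(segments, 4, query_lengths={"chrA": 5000})),
    ("row-wise", partition_rowwise(segments, 4)),
):
    print(f"{name} partitioning, K=4 -> {len(parts)} partitions")
    for p in parts:
        keys = f"keys {p.key_range[0]}..{p.key_range[1]}" if p.key_range else "position chunk"
        print(f"  partition {p.id}: {len(p.segments)} segments, strand {p.strand or 'mixed'}, {keys}")

# one partition serialized as an independent segment file
buf = io.StringIO()
write_segments(partition_diagonal(segments, 4, query_lengths={"chrA": 5000})[0].segments, buf)
print("\nfirst partition as a segment file (origin-1 closed):")
print(buf.getvalue().rstrip())

# the dynamic bound: upper quartile of previously seen segment-file sizes
history = [3200, 4100, 150, 98_000, 5200, 2700, 4400]
print("\nrecord counts of files seen so far:", history)
print("dynamic max-segments bound (nearest-rank upper quartile):",
      dynamic_max_size(history, default_bound=15_000))
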