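# Methods

## Segment files, anchors, and diagonal keys

A segment file row is one HSP: equal-length ungapped intervals on target
and query, a strand, and an ungapped score. On disk the dialect is
origin-1 closed, with reverse-strand query coordinates written in the
reverse-complement frame of the query (the convention of the aligner
ecosystem these files are exchanged with); internally everything is
0-based half-open and conversion happens only at the I/O boundary.

The partitioner does not know where the downstream aligner will place its
(optimal) anchor on an HSP, so each HSP is reduced to the **floor midpoint**
of its two intervals. Floor (rather than round-half-up or ceiling) is an
arbitrary but fixed integer rule; any consistent choice moves anchors by at
most one cell and never changes which diagonal neighbourhood they fall in.

The diagonal key of a forward anchor is `t − q`, constant along a gap-free
forward extension. Reverse anchors are first mapped to the forward frame
(`q_fwd = L − 1 − q_rc`, with `L` the query length), where their gap-free
extension follows the anti-diagonal `t + q_fwd = const`. This is why
reverse-strand partitioning needs a query-length table and forward
partitioning does not.

Record counts of existing files are estimated as
`⌊file size / byte length of the first line⌋`. The estimate is exact when
lines are uniform and within a few percent otherwise, which is all the
dynamic threshold needs; it avoids reading files that can hold millions of
records.

## Partitioning

Within each strand, anchors are sorted by (key, anchor target position,
input order) and whole diagonals are packed greedily, in key order, into
partitions of at most `K` members. Two deliberate asymmetries:

* **A diagonal is never split.** Anchors sharing a key are the most likely
  to be dependent, so a single key whose population exceeds `K` forms one
  oversized partition instead of being divided.
* **Greedy, not balanced.** First-fit packing in key order is deterministic
  and order-stable, and keeps each partition a contiguous key band, so the
  key ranges of two same-strand partitions never interleave.

The row-wise baseline sorts by (target start, query start) and chunks into
runs of `K`, ignoring strand and diagonals — the naive splitting strategy
the diagonal scheme replaces.

The dynamic bound is the nearest-rank upper quartile (the `⌈0.75·n⌉`-th
smallest) of the record counts of previously generated, pre-partitioning
segment files. Nearest-rank avoids interpolation, is integer-valued, and
returns the constant itself on a constant history. With no history a
configurable default (15,000, a value appropriate for large, closely
related genome pairs) is used. Because every stage writes its files into a
shared directory, the history is recovered by listing that directory; no
coordination channel exists between partitioning processes.

## Chromosome binning

Bins are built with longest-processing-time-first: chromosomes in
descending length order, each to the currently least-loaded bin. Ties in
length keep input order and ties in load go to the lowest bin id, making
the assignment deterministic. The bin count is either explicit or
`max(1, ⌈total/target⌉)` for a target bases-per-bin (around 200 Mbp in
production use). Chromosomes are never split, so a chromosome longer than
the target simply occupies an oversized bin; the cost of the alternative
would be straddling alignments at the cut and coordinate lifting
afterwards. The suite verifies the classic `4/3 − 1/(3m)` makespan
guarantee against a branch-and-bound optimum on all instances small enough
to solve exactly.

## The toy aligner

The aligner is deliberately small but exact, and reproduces the anchor
dependency semantics that partitioning must respect:

* **Seeding**: exact k-mer matches (default k = 12), both strands, `N`
  never matches. Spaced or transition seeds are out of scope.
* **Ungapped stage**: x-drop extension along the seed's diagonal, trimmed
  to the maximal-scoring span, kept at `hsp_threshold` or above,
  deduplicated per diagonal. Seeds falling inside an already-explored span
  on their diagonal are skipped — they cannot produce a different trimmed
  span.
* **Gapped stage**: anchors processed in descending HSP score (ties by
  input order). Each anchor is extended backward then forward by banded
  y-drop dynamic programming with affine gaps. After each alignment, any
  pending same-strand anchor whose exact cell lies on the traceback path
  is suppressed. The suppression test is the exact cell; a tolerance would
  also be defensible, but the exact rule is the strictest consistent
  reading and makes the mechanism tests sharp. Within one run an alignment
  identical to one already emitted is not emitted again, so a single run
  never contains duplicates (re-extensions from off-path anchors converge
  to the same optimal path).
* **Tie-breaks**: forward extension prefers diagonal, then a gap character
  in the query (consuming target), then a gap in the target; backward
  extension swaps the two gap preferences. The concrete orders are a fixed
  choice; what matters — and what the tests exercise — is that the two
  directions differ, so the same ambiguous indel region traversed from
  different anchors can legitimately yield different, equally scoring
  paths. This is the mechanism behind "additional" straddling alignments.

Scoring defaults are the published HOXD70 substitution matrix with gap
open 400 and extend 30 (a length-g gap costs 400 + 30g), x-drop 910 and
HSP threshold 3000. The y-drop default is 3000: large enough to carry
extension across the panel's 1–5 nt indels (worst cost 550) and across
local mismatch runs, while keeping the live DP band — roughly
`2·y_drop/gap_extend` columns — proportionate to the kilobase sequences
this aligner targets. The band is otherwise unrestricted within the y-drop
frontier. The DP is exact: on small instances with unbounded y-drop it
reproduces a brute-force Gotoh extension cell for cell, which the suite
checks exhaustively.

**Coverage** is computed from per-alignment coordinate envelopes (the
interval an alignment spans on each sequence), merged across alignments
and clipped to the homologous core. This matches how alignment intervals
are merged in practice when measuring what fraction of a sequence an
aligner recovered: a short deletion inside an alignment does not puncture
coverage. Per-matched-base counting would cap coverage below 1 by exactly
the deleted bases (~1.5% at the panel's indel rate) even for a perfect
alignment.

## The simulator

One pair is built as: uniform-random ancestral core of the requested
length; substitutions at the requested percent per position (replacement
uniform over the three alternatives); then indels at 1% per ancestral
position, sizes uniform on 1–5, insertion and deletion equally likely;
then four independent uniform-random 1 kb flanks. Substitutions are applied
before indels on the ancestral frame, so the event log (which aligned
positions were substituted) is exact and `realized_divergence` needs no
alignment. The indel process runs at its fixed rate even at 0% divergence,
as the two processes are independent; `indel_rate=0` switches it off.

The full panel crosses lengths {1, 2, 5, 10} kb with divergences 0–40% in
1% steps — 164 pairs — with per-pair seeds spawned deterministically from
one master seed (numpy PCG64 throughout, so panels are bit-reproducible
across platforms).

What the generator emulates: point divergence, short indels, and unrelated
flanking context, i.e. the regime that stresses seeding sensitivity and
gapped extension across small gaps. What it does not emulate: repeats and
low-complexity sequence, large structural events, GC/composition bias, and
multiple interleaved homologies per region. Tests passing on this panel
therefore say nothing about repeat-driven straddling or masking policy on
real genomes — and, importantly, single-pair inputs contain essentially
*one* dependency chain (see below).

## Problem sizes

The suite and the acceptance script run at desk scale, as the package's
own study conditions: the partition-equivalence oracle and the straddle
comparison use the 82 panel pairs of 1–2 kb; conservation is checked on
1,000 random segment collections; LPT on 200 instances of ≤10 chromosomes
and ≤4 bins (the exactly solvable range); the threshold on 1,000 random
histories; calibration on 30 replicates at 10 kb, where the binomial
standard error (~0.12 points at 20% divergence) sits comfortably inside
the 0.5-point acceptance band. The whole suite runs in well under a minute
of aligner time plus the panel runs (a few minutes total).

## Known limitations, and one deliberate red result

* The diagonal-vs-row-wise **straddle dominance comparison does not favour
  diagonal partitioning at desk scale**, and the corresponding acceptance
  test is intentionally left failing rather than weakened. The reason is
  structural. A single simulated pair yields one dependency chain whose
  anchors drift across ~#indels adjacent diagonal keys. At any `K` small
  enough to split at all, *both* schemes cut that one chain into
  `⌈n/K⌉`-ish groups, and every group independently re-extends the shared
  region — each split costs the same straddles under either scheme.
  Diagonal partitioning ends slightly *worse* in total (e.g. 282 vs 240
  summed over the ≤2 kb panel at K = 4) because whole-diagonal packing
  leaves slack (more partitions) and key order scrambles chain contiguity.
  The production-scale advantage of diagonal bands arises when a segment
  file holds many interleaved chains: position-order chunking then cuts
  nearly every chain, while a wide diagonal band cuts only the few whose
  key drift crosses a band edge. Desk-scale single-pair inputs cannot
  produce that regime. What the suite *does* establish is the mechanism
  (split dependent anchors → duplicated/overlapping output; co-partitioned
  → suppressed) and the safety property (an unsplit partition reproduces
  the unpartitioned output exactly on every panel pair).
* Per-partition extension work in the toy increases as `K` decreases
  (re-extension dominates), whereas the production aligner also gains from
  keeping its quadratic bookkeeping structures small — that data structure
  is not modelled here, so no work-reduction trend is asserted.
* The toy aligner is not a production aligner: exact seeds only, no
  chaining/netting, no scoring inference, and no attempt at bit-parity
  with any existing tool.
* The dynamic threshold is validated as a quartile computation; whether
  the resulting bound is runtime-optimal on real hardware is outside what
  desk-scale inputs can measure.
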