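# diagpart

Load-balancing machinery for the CPU-bound gapped-extension stage of
pairwise whole-genome alignment, together with the oracles needed to prove
it safe: a small exact seed–filter–extend aligner and a sequence-divergence
simulator.

## The problem

Sensitive pairwise genome aligners hand off work between two stages: a fast
seeding/filtering stage emits *segment files* — text files of HSP (high-
scoring segment pair) coordinate records — and a slow gapped-extension
stage processes one file per task. Segment files vary enormously in size,
so one overloaded task can dominate the wall clock while every other worker
idles (tail latency). Splitting files bounds per-task work, but HSP anchors
on the same alignment are *dependent*: extending one suppresses the others.
Putting dependent anchors in different files makes each file re-extend the
shared region, producing **straddling alignments** — duplicates, overlaps,
and additional alignments from different, equally scoring extension paths.

Because gap-free extension moves along dot-plot diagonals, dependent
anchors cluster around a common diagonal. This package partitions segment
files along those diagonals:

* each HSP is reduced to its **anchor**, the floor midpoint of its target
  and query intervals;
* a forward anchor gets the diagonal key `t − q`; a reverse anchor, with
  query coordinates mapped back from the reverse-complement frame, gets the
  anti-diagonal key `t + (L − 1 − q)`;
* within each strand, whole diagonals are packed greedily in key order into
  partitions of at most `K` anchors (a single over-populated diagonal forms
  one oversized partition rather than being split);
* `K` can be chosen dynamically as the nearest-rank **upper quartile** of
  the record counts of segment files generated so far, estimated from file
  sizes alone (`⌊file size / size of one line⌋`) by listing a shared
  directory — no inter-process communication.

For running several aligner instances in parallel, whole chromosomes are
packed into similar-sized bins with the classic **LPT**
(longest-processing-time-first) heuristic, whose makespan is within
`4/3 − 1/(3m)` of optimal for `m` bins. Chromosomes are never split: a cut
would create straddling alignments and force coordinate lifting.

The toy aligner exists to *measure* all of this end to end. It reproduces
the semantics that make naive partitioning unsafe — anchors processed in
descending HSP score, suppression of anchors crossed by an earlier
traceback, and different DP tie-break preferences for forward and backward
y-drop extension — so partitioned and unpartitioned runs can be compared
record for record. The simulator generates the benchmark panel the oracles
run on: homologous cores of 1–10 kb at 0–40% divergence, 1% indels of
1–5 nt, and 1 kb random flanks.

## Worked example

Two dependent anchors on one homology (`examples/straddling_demo.py`):

```
same partition:      1 alignment(s)
  target 0..300, score 28641
separate partitions: 2 alignment(s)
  target 0..300, score 28641
  target 0..300, score 28641

straddle report vs the unpartitioned run: duplicates=1 overlaps=1 extras=0 inflation=2.0
```

Together, the first extension crosses the second anchor, which is then
suppressed — one alignment. Split across partitions, both anchors are
extended independently and the same region is reported twice: the output
doubles (`inflation=2.0`) with one exact duplicate and one overlapping
pair.

Sensitivity over the simulated panel (`examples/simulate_and_align.py`):

```
divergence  realized  segments  alignments  core coverage
        0%     0.00%         7           1         1.000
       20%    20.21%         4           1         0.999
       30%    29.51%         5           1         0.996
       40%    40.06%         0           0         0.000
```

`realized` is the simulator's own event-log divergence (no alignment
involved); `core coverage` is the fraction of the homologous core inside
at least one alignment, flanks excluded. Coverage stays near-complete
until the exact-k-mer seeding stage runs out of signal.

Other examples: `examples/partition_segments.py` (diagonal vs row-wise
partitions and the dynamic bound), `examples/bin_chromosomes.py` (LPT bins
of the human chromosome set at ~200 Mbp per bin).

A thin CLI wraps the same functions:

```
diagpart partition --segments hits.seg --scheme diagonal --max-segments auto --out-dir parts/
diagpart bin --lengths genome.fai --target-bp 200000000
diagpart toy-align --target t.fa --query q.fa --partitioner diagonal --max-segments 8
diagpart simulate-panel --seed 1 --out-dir panel/
```

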